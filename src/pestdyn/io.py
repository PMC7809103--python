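"""Readers and writers: trajectory CSV, scenario YAML, matrix CSV.

All files are plain diff-able text.  Floating values are written as
shortest-round-trip decimal text, so every write/read round-trip is
lossless bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .dynamics import Trajectory
from .estimation import DensityExperiment
from .parameters import (CompetitionMatrix, ParasitoidParameters,
                         ScenarioConfig, SeasonCalendar, SpeciesParameters)

__all__ = [
    "SchemaError", "write_trajectory", "read_trajectory",
    "scenario_to_dict", "scenario_from_dict", "save_scenario",
    "load_scenario", "matrix_to_csv", "matrix_from_csv",
    "write_experiment", "read_experiment",
]


class SchemaError(ValueError):
    """A file does not conform to the expected column schema."""


_STOCK_TAGS = ("N", "P", "G", "L", "R", "D")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write one row per time step: time, season label, then per-species
    stocks and flows (``N_<sp>, P_<sp>, G_<sp>, L_<sp>, R_<sp>, D_<sp>``)."""
    df = traj.to_frame()
    df.to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    """Lossless inverse of :func:`write_trajectory`.

    The generating config and event log are not stored in the CSV, so the
    returned trajectory carries ``config=None`` and no events.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: file is empty")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    for col in ("time_months", "season"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    species = tuple(c[2:] for c in df.columns if c.startswith("N_"))
    if not species:
        raise SchemaError(f"{path}: no N_<species> stock columns found")
    for tag in _STOCK_TAGS:
        for sid in species:
            if f"{tag}_{sid}" not in df.columns:
                raise SchemaError(
                    f"{path}: missing required column '{tag}_{sid}'")
    arrays = {tag: df[[f"{tag}_{s}" for s in species]].to_numpy(dtype=float)
              for tag in _STOCK_TAGS}
    return Trajectory(
        times=df["time_months"].to_numpy(dtype=float), species_order=species,
        N=arrays["N"], P=arrays["P"], G=arrays["G"], L=arrays["L"],
        R=arrays["R"], D=arrays["D"],
        season_labels=[str(s) for s in df["season"]], config=None)


# --------------------------------------------------------------------------
# Scenario YAML

def scenario_to_dict(config: ScenarioConfig) -> dict:
    """Plain-data snapshot of a scenario; sufficient to re-run it exactly."""
    return {
        "species": [dataclasses.asdict(sp) for sp in config.species],
        "matrix": {
            "species_order": list(config.matrix.species_order),
            "a": [[float(v) for v in row] for row in config.matrix.a],
        },
        "calendar": {
            **dataclasses.asdict(config.calendar),
            "cropping_blocks": [list(b) for b in
                                config.calendar.cropping_blocks],
        },
        "parasitoid": dataclasses.asdict(config.parasitoid),
        "dt": config.dt,
        "horizon": config.horizon,
        "initial_pest_stocks": dict(config.initial_pest_stocks),
        "initial_parasitoid_stocks": dict(config.initial_parasitoid_stocks),
        "reference_density_crop": config.reference_density_crop,
        "reference_density_wild": config.reference_density_wild,
        "parasitism_model": config.parasitism_model,
        "competition_units": config.competition_units,
    }


def scenario_from_dict(d: Mapping) -> ScenarioConfig:
    cal = dict(d["calendar"])
    cal["cropping_blocks"] = tuple(tuple(b) for b in cal["cropping_blocks"])
    return ScenarioConfig(
        species=tuple(SpeciesParameters(**sp) for sp in d["species"]),
        matrix=CompetitionMatrix(tuple(d["matrix"]["species_order"]),
                                 np.asarray(d["matrix"]["a"], dtype=float)),
        calendar=SeasonCalendar(**cal),
        parasitoid=ParasitoidParameters(**d["parasitoid"]),
        dt=d["dt"], horizon=d["horizon"],
        initial_pest_stocks=dict(d["initial_pest_stocks"]),
        initial_parasitoid_stocks=dict(d["initial_parasitoid_stocks"]),
        reference_density_crop=d["reference_density_crop"],
        reference_density_wild=d["reference_density_wild"],
        parasitism_model=d["parasitism_model"],
        competition_units=d["competition_units"],
    )


def save_scenario(config: ScenarioConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(scenario_to_dict(config), sort_keys=False))


def load_scenario(path) -> ScenarioConfig:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, Mapping):
        raise SchemaError(f"{path}: not a scenario mapping")
    return scenario_from_dict(d)


# --------------------------------------------------------------------------
# Matrix CSV (labelled: header row and first column carry species ids)

def matrix_to_csv(matrix: CompetitionMatrix, path) -> None:
    df = pd.DataFrame(matrix.a, index=list(matrix.species_order),
                      columns=list(matrix.species_order))
    df.index.name = "affected"
    df.to_csv(path)


def matrix_from_csv(path) -> CompetitionMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise SchemaError(
            f"{path}: row labels {list(df.index)} != column labels "
            f"{list(df.columns)}")
    return CompetitionMatrix(tuple(df.columns),
                             df.to_numpy(dtype=float))


# --------------------------------------------------------------------------
# Density-experiment CSV

def write_experiment(experiment: DensityExperiment, path) -> None:
    experiment.data.to_csv(path, index=False)


def read_experiment(path, species: tuple[str, ...]) -> DensityExperiment:
    path = Path(path)
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: file is empty")
    exp = DensityExperiment(tuple(species),
                            pd.read_csv(path, float_precision="round_trip"))
    problems = exp.violations()
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return exp
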