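"""Synthetic data generators.

Everything the pipeline needs to be exercised without external data is
generated here: density-dependent survival experiments with a known
interaction matrix (emulating the statistical structure of the laboratory
experiments the published coefficients were fitted from), analytic
trajectory fixtures with known peaks/lags for the metrics, and jittered
parameter ensembles for robustness runs.  All generators are pure functions
of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .estimation import DensityExperiment
from .parameters import (CompetitionMatrix, ScenarioConfig,
                         SpeciesParameters, canonical_subset)

__all__ = [
    "ExperimentDesign", "generate_density_experiment",
    "generate_trajectory_fixture", "perturb_parameters",
]

# Default arena densities (larvae per replicate arena) and response noise for
# emulated survival experiments: a small factorial with counts of tens to a
# couple hundred larvae and count-scale Gaussian noise.
DEFAULT_DENSITY_LEVELS = (0.0, 50.0, 100.0, 200.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design of a density-dependent survival experiment."""

    species: tuple[str, ...]
    density_levels: tuple[float, ...] = DEFAULT_DENSITY_LEVELS
    replicates: int = 3
    noise_sd: float = 5.0
    seed: int = 0

    def violations(self) -> list[str]:
        out = []
        if len(set(self.density_levels)) < 2:
            out.append("design: need >= 2 distinct density levels")
        if self.replicates < 1:
            out.append("design: replicates must be >= 1")
        if self.noise_sd < 0:
            out.append("design: noise_sd must be >= 0")
        if any(d < 0 for d in self.density_levels):
            out.append("design: density levels must be >= 0")
        return out


def generate_density_experiment(true_matrix: CompetitionMatrix,
                                design: ExperimentDesign) -> DensityExperiment:
    """Survival table generated from the equilibrium interaction law.

    For every focal species, density cell and replicate, the survived count
    is ``N_i + sum_{j != i} a_ij N_j`` plus Gaussian noise, truncated at 0 —
    the additive-error linear model the multiple regression assumes.
    """
    problems = design.violations()
    if problems:
        raise ValueError("; ".join(problems))
    order = canonical_subset(design.species)
    if set(order) != set(true_matrix.species_order):
        raise ValueError(
            f"matrix species {true_matrix.species_order} do not match the "
            f"design species {order}")
    matrix = true_matrix.reorder(order)

    rng = np.random.default_rng(design.seed)
    records = []
    rep_id = 0
    for i, focal in enumerate(order):
        for cell in product(design.density_levels, repeat=len(order)):
            dens = np.asarray(cell, dtype=float)
            expected = float(matrix.a[i] @ dens)  # N_i + sum a_ij N_j
            for _ in range(design.replicates):
                rep_id += 1
                noise = rng.normal(0.0, design.noise_sd) if design.noise_sd \
                    else 0.0
                rec = {"focal": focal,
                       "survived": max(0.0, expected + noise),
                       "replicate": rep_id}
                rec.update({f"N_{s}": dens[j] for j, s in enumerate(order)})
                records.append(rec)
    cols = ["focal"] + [f"N_{s}" for s in order] + ["survived", "replicate"]
    return DensityExperiment(order, pd.DataFrame.from_records(records)[cols])


def _fixture_trajectory(times, species, N, P, G=None) -> Trajectory:
    times = np.asarray(times, dtype=float)
    z = np.zeros((len(times), len(species)))
    return Trajectory(
        times=times, species_order=tuple(species),
        N=np.asarray(N, dtype=float), P=np.asarray(P, dtype=float),
        G=z if G is None else np.asarray(G, dtype=float),
        L=z.copy(), R=z.copy(), D=z.copy(),
        season_labels=["fixture"] * len(times), config=None)


def generate_trajectory_fixture(kind: str, params: dict | None = None,
                                seed: int | None = None) -> Trajectory:
    """Analytic trajectory-shaped fixtures with known ground truth.

    Kinds
    -----
    ``logistic``
        Closed-form logistic host, no parasitoids.  Params: ``r``, ``K``,
        ``n0``, ``dt``, ``horizon``.
    ``sine_pair``
        Host and guild sinusoids with a known guild lag.  Params:
        ``amplitude``, ``period``, ``lag``, ``dt``, ``horizon``.
    ``circle``
        One exactly closed loop in the (host, guild) plane.  Params:
        ``center``, ``radius``, ``n_points``.
    ``flat``
        Constant (default zero) stocks.  Params: ``value``, ``dt``,
        ``horizon``.
    """
    p = dict(params or {})
    sp = (p.pop("species", "Cp"),)
    if kind == "logistic":
        r, K, n0 = p.get("r", 0.83), p.get("K", 62_500.0), p.get("n0", 156.25)
        dt, horizon = p.get("dt", 0.25), p.get("horizon", 24.0)
        t = np.arange(int(round(horizon / dt)) + 1) * dt
        N = K / (1.0 + (K - n0) / n0 * np.exp(-r * t))
        return _fixture_trajectory(t, sp, N[:, None], np.zeros((len(t), 1)))
    if kind == "sine_pair":
        A, period = p.get("amplitude", 1000.0), p.get("period", 6.0)
        lag, dt = p.get("lag", 0.5), p.get("dt", 0.25)
        horizon = p.get("horizon", 24.0)
        t = np.arange(int(round(horizon / dt)) + 1) * dt
        w = 2.0 * np.pi / period
        N = A * (1.0 + np.sin(w * t))
        P = A * (1.0 + np.sin(w * (t - lag)))
        return _fixture_trajectory(t, sp, N[:, None], P[:, None])
    if kind == "circle":
        cx, cy = p.get("center", (2000.0, 2000.0))
        radius, n = p.get("radius", 500.0), p.get("n_points", 97)
        theta = np.linspace(0.0, 2.0 * np.pi, n)
        t = np.linspace(0.0, 12.0, n)
        N = cx + radius * np.cos(theta)
        P = cy + radius * np.sin(theta)
        return _fixture_trajectory(t, sp, N[:, None], P[:, None])
    if kind == "flat":
        value, dt = p.get("value", 0.0), p.get("dt", 0.25)
        horizon = p.get("horizon", 24.0)
        t = np.arange(int(round(horizon / dt)) + 1) * dt
        c = np.full((len(t), 1), float(value))
        return _fixture_trajectory(t, sp, c, c.copy())
    raise ValueError(f"unknown fixture kind {kind!r}")


def perturb_parameters(config: ScenarioConfig, relative_sd: float, n: int,
                       seed: int = 0) -> list[ScenarioConfig]:
    """Ensemble of scenarios with jittered biology.

    Growth rates, crop parasitism fractions and off-diagonal competition
    coefficients are multiplied by independent lognormal factors
    ``exp(relative_sd * z)``, ``z ~ N(0, 1)``; the ensemble is reproducible
    from the seed.
    """
    if relative_sd < 0:
        raise ValueError("relative_sd must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    m = len(config.species)
    for _ in range(n):
        species = tuple(
        replace(sp,
                growth_rate=min(1.0, sp.growth_rate *
                                float(np.exp(relative_sd * rng.standard_normal()))),
                parasitism_fraction_crop=min(
                    0.999, sp.parasitism_fraction_crop *
                    float(np.exp(relative_sd * rng.standard_normal()))))
            for sp in config.species)
        factors = np.exp(relative_sd * rng.standard_normal((m, m)))
        a = config.matrix.a * factors
        np.fill_diagonal(a, 1.0)
        out.append(replace(config, species=species,
                           matrix=CompetitionMatrix(config.matrix.species_order,
                                                    a)))
    return out
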