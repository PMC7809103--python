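"""Competition-coefficient estimation from density experiments.

At equilibrium the survived-larvae counts satisfy the linear system
``K_i = N_i + sum_{j != i} a_ij N_j``; rearranged, ``K_i_obs - N_i`` is a
linear function of the competitor densities with slopes a_ij and no
intercept.  Each focal species' coefficients are therefore estimated by
intercept-free ordinary least squares of the transformed response on the
competitor densities, exactly the multiple-regression structure the
coefficients were originally fitted with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .parameters import CompetitionMatrix, canonical_subset

__all__ = [
    "DensityExperiment", "EstimationResult", "RankDeficientDesignError",
    "SingularSystemError", "equilibrium_residual", "solve_equilibrium",
    "estimate_coefficients",
]


class RankDeficientDesignError(ValueError):
    """Competitor densities are collinear; coefficients are not identifiable."""


class SingularSystemError(np.linalg.LinAlgError):
    """The interaction system matrix is singular."""


@dataclass(frozen=True)
class DensityExperiment:
    """Replicate table of competitor densities vs. survived larvae.

    ``data`` columns: ``focal`` (species id), one ``N_<sp>`` column per
    species (densities per replicate arena; the focal's own column is its
    initial density), ``survived`` (the response) and ``replicate``.
    """

    species: tuple[str, ...]
    data: pd.DataFrame

    def violations(self) -> list[str]:
        out = []
        required = {"focal", "survived", "replicate"} | {
            f"N_{s}" for s in self.species}
        missing = required - set(self.data.columns)
        if missing:
            out.append(f"missing columns: {sorted(missing)}")
            return out
        bad_focal = set(self.data["focal"]) - set(self.species)
        if bad_focal:
            out.append(f"focal species outside the species set: "
                       f"{sorted(bad_focal)}")
        dens = self.data[[f"N_{s}" for s in self.species]]
        if (dens.to_numpy() < 0).any():
            out.append("densities must be >= 0")
        if (self.data["survived"].to_numpy() < 0).any():
            out.append("survived_larvae must be >= 0")
        return out


@dataclass(frozen=True)
class EstimationResult:
    matrix: CompetitionMatrix
    standard_errors: dict[tuple[str, str], float]
    residual_summary: dict[str, float]          # focal -> residual std. dev.
    condition_numbers: dict[str, float]         # focal -> design cond. number
    negative_flags: tuple[tuple[str, str], ...] = field(default=())


def equilibrium_residual(N: np.ndarray, matrix: CompetitionMatrix,
                         K: np.ndarray) -> np.ndarray:
    """Residual ``K_i - N_i - sum_{j != i} a_ij N_j`` of the equilibrium
    system; the zero vector iff (N, K) satisfy it exactly."""
    N = np.asarray(N, dtype=float)
    K = np.asarray(K, dtype=float)
    m = len(matrix.species_order)
    if N.shape != (m,) or K.shape != (m,):
        raise ValueError(
            f"dimension mismatch: matrix is {m}x{m}, N has shape {N.shape}, "
            f"K has shape {K.shape}")
    return K - matrix.a @ N


def solve_equilibrium(matrix: CompetitionMatrix, K: np.ndarray) -> np.ndarray:
    """Solve the linear equilibrium system for the species abundances N.

    Warns if any component is negative (no feasible coexistence at these
    capacities); raises :class:`SingularSystemError` if the system matrix is
    singular.
    """
    K = np.asarray(K, dtype=float)
    a = matrix.a
    if np.linalg.cond(a) > 1e12:
        raise SingularSystemError(
            "interaction matrix is singular or near-singular "
            f"(condition number {np.linalg.cond(a):.3g})")
    N = np.linalg.solve(a, K)
    if np.any(N < 0):
        neg = [s for s, v in zip(matrix.species_order, N) if v < 0]
        warnings.warn(
            f"equilibrium is infeasible: negative abundance for {neg}",
            RuntimeWarning, stacklevel=2)
    return N


def estimate_coefficients(experiment: DensityExperiment) -> EstimationResult:
    """Estimate the interaction matrix by per-focal multiple regression.

    For each focal species i the response ``survived - N_i`` is regressed
    without intercept on the competitor densities N_j; slopes are the a_ij.
    Negative estimates are retained but flagged.  Raises
    :class:`RankDeficientDesignError` when a focal design is collinear.
    """
    problems = experiment.violations()
    if problems:
        raise ValueError("invalid experiment: " + "; ".join(problems))

    order = canonical_subset(experiment.species)
    m = len(order)
    a = np.eye(m)
    ses: dict[tuple[str, str], float] = {}
    resid: dict[str, float] = {}
    conds: dict[str, float] = {}
    flags: list[tuple[str, str]] = []

    for i, focal in enumerate(order):
        competitors = [s for s in order if s != focal]
        if not competitors:
            continue
        rows = experiment.data[experiment.data["focal"] == focal]
        X = rows[[f"N_{s}" for s in competitors]].to_numpy(dtype=float)
        y = rows["survived"].to_numpy(dtype=float) - \
            rows[f"N_{focal}"].to_numpy(dtype=float)
        if len(rows) < len(competitors) + 1 or \
                np.linalg.matrix_rank(X) < len(competitors):
            raise RankDeficientDesignError(
                f"focal {focal}: design with {len(rows)} rows is rank "
                f"deficient for {len(competitors)} competitor(s)")
        flat = [s for k, s in enumerate(competitors)
                if np.unique(X[:, k]).size < 2]
        if flat:
            raise RankDeficientDesignError(
                f"focal {focal}: no density variation for competitor(s) "
                f"{flat}; coefficients are confounded with the response "
                "level")
        fit = sm.OLS(y, X).fit()
        conds[focal] = float(np.linalg.cond(X))
        resid[focal] = float(np.sqrt(fit.scale))
        for s, est, se in zip(competitors, fit.params, fit.bse):
            a[i, order.index(s)] = est
            ses[(focal, s)] = float(se)
            if est < 0:
                flags.append((focal, s))

    return EstimationResult(
        matrix=CompetitionMatrix(order, a), standard_errors=ses,
        residual_summary=resid, condition_numbers=conds,
        negative_flags=tuple(flags))
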