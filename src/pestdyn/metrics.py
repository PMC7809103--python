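"""Result metrics: dominance shares, peaks, cross-system ratios, cycles and
the aggregated host-parasitoid phase portrait."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory

__all__ = [
    "ShareReport", "StockPeaks", "PeakSummary", "CycleSummary",
    "PhasePortrait", "dominance_shares", "peak_summary", "mean_total_pests",
    "cross_system_ratio", "detect_cycles", "phase_diagram",
]


@dataclass(frozen=True)
class ShareReport:
    """Per-species fractions of the summed pest stock.

    ``instantaneous`` is evaluated at ``eval_month``; ``averaged`` is the
    time-mean of the per-sample share over ``window``.  Shares in each
    report sum to 1.
    """

    instantaneous: dict[str, float]
    averaged: dict[str, float]
    eval_month: float
    window: tuple[float, float]


@dataclass(frozen=True)
class StockPeaks:
    max_value: float
    time_of_max: float
    interior_maxima: tuple[tuple[float, float], ...]  # (time, value)


@dataclass(frozen=True)
class PeakSummary:
    stocks: dict[str, StockPeaks]


@dataclass(frozen=True)
class CycleSummary:
    pest_peaks: tuple[tuple[float, float], ...]
    parasitoid_peaks: tuple[tuple[float, float], ...]
    lags: tuple[tuple[float, float], ...]  # (parasitoid peak time, lag)
    burn_in: float


@dataclass(frozen=True)
class PhasePortrait:
    """Aggregated (host total, parasitoid total) orbit.

    ``closure_gap`` is the distance between the first and last point of the
    final cycle; divided by the loop diameter it measures how closed the
    late-time orbit is (0 = perfectly closed loop).
    """

    times: np.ndarray
    host_total: np.ndarray
    parasitoid_total: np.ndarray
    closure_gap: float
    loop_diameter: float
    closure_gap_relative: float


def _interior_maxima(times: np.ndarray, x: np.ndarray):
    """Interior local maxima by sign change of the first difference."""
    d = np.diff(x)
    out = []
    for k in range(1, len(x) - 1):
        if d[k - 1] > 0 and d[k] < 0:
            out.append((float(times[k]), float(x[k])))
    return tuple(out)


def dominance_shares(traj: Trajectory, eval_month: float = 6.0,
                     window: tuple[float, float] | None = None) -> ShareReport:
    """Instantaneous and time-averaged pest dominance shares.

    The averaged share of species i is the mean over window samples of
    N_i(t)/sum_j N_j(t); samples with zero total are skipped.  Raises
    ``ValueError`` if the total pest stock is zero over the whole window.
    """
    if window is None:
        window = (eval_month, float(traj.times[-1]))
    lo, hi = window
    sel = (traj.times >= lo - 1e-9) & (traj.times <= hi + 1e-9)
    if not np.any(sel):
        raise ValueError(f"window {window} contains no samples")
    totals = traj.N[sel].sum(axis=1)
    if np.all(totals <= 0):
        raise ValueError("total pest stock is zero over the whole window")
    rows = traj.N[sel][totals > 0]
    averaged = rows / rows.sum(axis=1, keepdims=True)
    averaged = averaged.mean(axis=0)

    k = traj.at_time(eval_month)
    tot = traj.N[k].sum()
    inst = traj.N[k] / tot if tot > 0 else np.full(len(traj.species_order),
                                                  np.nan)
    return ShareReport(
        instantaneous=dict(zip(traj.species_order, map(float, inst))),
        averaged=dict(zip(traj.species_order, map(float, averaged))),
        eval_month=eval_month, window=(float(lo), float(hi)))


def peak_summary(traj: Trajectory) -> PeakSummary:
    """Maximum, its time, and interior local maxima for every stock."""
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    stocks: dict[str, StockPeaks] = {}
    for arr, tag in ((traj.N, "N"), (traj.P, "P")):
        for j, sid in enumerate(traj.species_order):
            x = arr[:, j]
            k = int(np.argmax(x))
            stocks[f"{tag}_{sid}"] = StockPeaks(
                max_value=float(x[k]), time_of_max=float(traj.times[k]),
                interior_maxima=_interior_maxima(traj.times, x))
    return PeakSummary(stocks)


def mean_total_pests(traj: Trajectory) -> float:
    """Time-mean of the summed pest stocks over the whole horizon."""
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    return float(traj.N.sum(axis=1).mean())


def cross_system_ratio(systems_a: list[Trajectory],
                       systems_b: list[Trajectory]) -> float:
    """100 x (mean average-total-pests over A) / (same over B), in percent."""
    if not systems_a or not systems_b:
        raise ValueError("both system lists must be non-empty")
    num = float(np.mean([mean_total_pests(t) for t in systems_a]))
    den = float(np.mean([mean_total_pests(t) for t in systems_b]))
    if den == 0:
        raise ValueError("zero denominator: systems B have no pests")
    return 100.0 * num / den


def detect_cycles(traj: Trajectory, pest_id: str,
                  burn_in: float = 4.0) -> CycleSummary:
    """Host and guild peak times after burn-in, and the lag of each guild
    peak behind the nearest preceding host peak.

    A positive lag on every guild peak is the signature of the parasitoid
    tracking its host through the cycle.  Guild peaks with no preceding host
    peak are omitted from the lag list.
    """
    j = traj.index_of(pest_id)
    sel = traj.times >= burn_in - 1e-9
    times = traj.times[sel]
    n_peaks = _interior_maxima(times, traj.N[sel, j])
    p_peaks = _interior_maxima(times, traj.P[sel, j])
    lags = []
    n_times = [t for t, _ in n_peaks]
    for tp, _ in p_peaks:
        prev = [tn for tn in n_times if tn < tp]
        if prev:
            lags.append((tp, float(tp - max(prev))))
    return CycleSummary(tuple(n_peaks), tuple(p_peaks), tuple(lags), burn_in)


def phase_diagram(traj: Trajectory,
                  cycle_window: float = 12.0) -> PhasePortrait:
    """Pool all pests and all guilds into one (host, parasitoid) orbit.

    The closure gap is measured on the final cycle: the points of the last
    ``cycle_window`` months.  The loop diameter is the maximum pairwise
    distance among those points; a flat orbit has diameter 0 and, by
    convention, relative gap 0.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    host = traj.N.sum(axis=1)
    para = traj.P.sum(axis=1)
    t_end = float(traj.times[-1])
    sel = traj.times >= t_end - cycle_window - 1e-9
    pts = np.column_stack([host[sel], para[sel]])
    gap = float(np.linalg.norm(pts[-1] - pts[0]))
    # max pairwise distance; the windows here are small (tens of points)
    diff = pts[:, None, :] - pts[None, :, :]
    diameter = float(np.sqrt((diff ** 2).sum(-1)).max())
    rel = gap / diameter if diameter > 0 else 0.0
    return PhasePortrait(times=traj.times, host_total=host,
                         parasitoid_total=para, closure_gap=gap,
                         loop_diameter=diameter, closure_gap_relative=rel)
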