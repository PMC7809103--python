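"""Stock-and-flow equations and the fixed-step integrator.

Each pest population N_i and its lumped parasitoid guild P_i are stocks.
Pest inflow is Lotka-Volterra competitive growth against a seasonally
switching carrying capacity; pest outflow is parasitism.  Parasitoid inflow
is emergence from parasitized hosts (5 parasitoids per host, 46% female, so
exactly 2.3 females per parasitized host); outflow is a constant fractional
decrease.  Integration is forward Euler at the model's native 0.25-month
step, with negative stocks clipped to zero and every clip logged, and a
one-off x0.10 pest carryover applied at each cropping -> non-cropping
boundary.

Two genuinely open structural choices are pluggable:

* ``PARASITISM_MODELS`` — the parasitism flow L_i.  The default
  ``"saturating"`` form ``phi_i(t) * N_i * P_i / (P_i + p_meet * N_i)``
  caps the per-capita host loss at the reference parasitism fraction
  phi_i(t) and lets a sufficiently large guild realize that fraction in
  full; a scarce guild parasitizes phi/p_meet hosts per female per month.
  The ``"bilinear"`` mass-action alternative
  ``phi_i(t) * p_meet * N_i * P_i / K(t)`` is also registered; note its
  per-capita parasitoid recruitment is bounded by 2.3*phi*p_meet per month,
  far below the 0.7/month guild decrease rate, so under it guilds decay
  monotonically and the host-parasitoid cycle never forms (see the methods
  note).

* ``competition_units`` on the scenario — how a_ij N_j enters the growth
  null-cline.  ``"fraction"`` (default) reads a_ij N_j as a dimensionless
  fraction of species i's effective capacity; ``"absolute"`` reads it in
  individuals, the literal textbook form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .parameters import ScenarioConfig, SeasonCalendar, validate_config

__all__ = [
    "SystemState", "FlowSet", "Trajectory", "SeasonTransitionError",
    "carrying_capacity", "active_parasitism_fraction", "growth_flow",
    "parasitism_flow", "parasitoid_flows", "step", "apply_season_transition",
    "simulate", "PARASITISM_MODELS",
]

_EPS = 1e-9


class SeasonTransitionError(RuntimeError):
    """Season carryover requested away from a cropping-season boundary."""


@dataclass(frozen=True)
class SystemState:
    """Pest and parasitoid stocks (individuals/ha) at time t (months)."""

    t: float
    N: np.ndarray
    P: np.ndarray
    carryover_applied: bool = False

    def __post_init__(self):
        object.__setattr__(self, "N", np.asarray(self.N, dtype=float))
        object.__setattr__(self, "P", np.asarray(self.P, dtype=float))


@dataclass(frozen=True)
class FlowSet:
    """Per-species flow rates (individuals/ha/month) at one instant."""

    pest_growth: np.ndarray        # G_i, may be negative (overshoot)
    pest_parasitism_loss: np.ndarray  # L_i >= 0
    parasitoid_inflow: np.ndarray  # R_i = emergence x sex ratio x L_i
    parasitoid_outflow: np.ndarray  # D_i = d_P x P_i


@dataclass
class Trajectory:
    """Time-indexed stocks and flows produced by :func:`simulate`."""

    times: np.ndarray                 # months, constant spacing dt
    species_order: tuple[str, ...]
    N: np.ndarray                     # shape (T, m)
    P: np.ndarray
    G: np.ndarray
    L: np.ndarray
    R: np.ndarray
    D: np.ndarray
    season_labels: list[str]
    config: ScenarioConfig | None = None
    events: list[dict] = field(default_factory=list)

    def index_of(self, species_id: str) -> int:
        return self.species_order.index(species_id)

    def at_time(self, t: float) -> int:
        """Index of the sample closest to month t."""
        return int(np.argmin(np.abs(self.times - t)))

    def to_frame(self):
        import pandas as pd
        data = {"time_months": self.times, "season": self.season_labels}
        for arr, tag in ((self.N, "N"), (self.P, "P"), (self.G, "G"),
                         (self.L, "L"), (self.R, "R"), (self.D, "D")):
            for j, sid in enumerate(self.species_order):
                data[f"{tag}_{sid}"] = arr[:, j]
        return pd.DataFrame(data)


# --------------------------------------------------------------------------
# Seasonal forcing

def carrying_capacity(t: float, calendar: SeasonCalendar) -> float:
    """Habitat capacity K(t): the crop capacity only once pests have entered
    the field (``pest_entry_delay`` months after planting), the wild-refuge
    capacity otherwise."""
    block = calendar.block_at(t)
    if block is not None:
        planting, _end = block
        if t >= planting + calendar.pest_entry_delay - _EPS:
            return calendar.capacity_crop
    return calendar.capacity_wild


def active_parasitism_fraction(t: float, species_id: str,
                               config: ScenarioConfig) -> float:
    """Reference parasitism fraction phi_i(t).

    Crop-level phi_i applies from ``parasitism_onset_delay`` months after
    each planting to the end of that block; the wild-habitat fraction applies
    throughout non-cropping periods; in between (the first generations of
    each block) parasitism is inactive.
    """
    cal = config.calendar
    block = cal.block_at(t)
    if block is None:
        return cal.parasitism_fraction_wild
    planting, _end = block
    if t >= planting + cal.parasitism_onset_delay - _EPS:
        return config.species_params(species_id).parasitism_fraction_crop
    return 0.0


def _phi_vector(t: float, config: ScenarioConfig) -> np.ndarray:
    return np.array([active_parasitism_fraction(t, sid, config)
                     for sid in config.species_ids])


# --------------------------------------------------------------------------
# Flows

def growth_flow(state: SystemState, config: ScenarioConfig,
                t: float | None = None) -> np.ndarray:
    """Competitive logistic growth rate G_i (individuals/ha/month)."""
    t = state.t if t is None else t
    K = carrying_capacity(t, config.calendar)
    N = state.N
    r = np.array([sp.growth_rate for sp in config.species])
    A_off = config.matrix.a - np.eye(len(N))
    if config.competition_units == "fraction":
        # a_ij N_j depresses a fraction of species i's capacity
        return r * N * (1.0 - N / K - A_off @ N)
    # literal absolute form: a_ij N_j in individuals
    return (r * N / K) * (K - N - A_off @ N)


def _parasitism_saturating(phi, p_meet, N, P, K):
    denom = P + p_meet * N
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, P / np.where(denom > 0, denom, 1.0), 0.0)
    return phi * N * frac


def _parasitism_bilinear(phi, p_meet, N, P, K):
    return phi * p_meet * N * P / K


PARASITISM_MODELS = {
    "saturating": _parasitism_saturating,
    "bilinear": _parasitism_bilinear,
}


def parasitism_flow(state: SystemState, config: ScenarioConfig,
                    t: float | None = None) -> np.ndarray:
    """Parasitism loss L_i (individuals/ha/month), always >= 0."""
    t = state.t if t is None else t
    phi = _phi_vector(t, config)
    K = carrying_capacity(t, config.calendar)
    model = PARASITISM_MODELS[config.parasitism_model]
    L = model(phi, config.parasitoid.meeting_probability, state.N, state.P, K)
    return np.maximum(L, 0.0)


def parasitoid_flows(state: SystemState, config: ScenarioConfig,
                     t: float | None = None,
                     L: np.ndarray | None = None):
    """Guild inflow R_i (emergence from parasitized hosts) and outflow D_i."""
    if L is None:
        L = parasitism_flow(state, config, t)
    pp = config.parasitoid
    R = pp.per_host_emergence * pp.sex_ratio * L
    D = pp.decrease_rate * state.P
    return R, D


def _flows(state: SystemState, config: ScenarioConfig) -> FlowSet:
    G = growth_flow(state, config)
    L = parasitism_flow(state, config)
    R, D = parasitoid_flows(state, config, L=L)
    return FlowSet(G, L, R, D)


# --------------------------------------------------------------------------
# Integration

def apply_season_transition(state: SystemState,
                            config: ScenarioConfig) -> SystemState:
    """Apply the end-of-season pest carryover (default x0.10) once.

    Only pests take the haircut; parasitoids decline through their own
    decrease rate.  Calling this off a cropping -> non-cropping boundary, or
    twice at the same boundary, raises :class:`SeasonTransitionError`.
    """
    boundaries = config.calendar.season_boundaries(config.horizon)
    if not any(abs(state.t - b) < 1e-6 for b in boundaries):
        raise SeasonTransitionError(
            f"t={state.t} is not a cropping->non-cropping boundary "
            f"(boundaries: {boundaries})")
    if state.carryover_applied:
        raise SeasonTransitionError(
            f"carryover already applied at t={state.t}")
    return replace(state, N=config.calendar.carryover_fraction * state.N,
                   carryover_applied=True)


def step(state: SystemState, config: ScenarioConfig):
    """One forward-Euler step.

    Returns ``(new_state, flows, events)`` where ``flows`` are the rates at
    the departing state and ``events`` logs clips to zero and season
    carryovers applied while crossing a boundary.
    """
    dt = config.dt
    flows = _flows(state, config)
    N_new = state.N + dt * (flows.pest_growth - flows.pest_parasitism_loss)
    P_new = state.P + dt * (flows.parasitoid_inflow - flows.parasitoid_outflow)
    t_new = state.t + dt

    events: list[dict] = []
    for tag, arr in (("pest", N_new), ("parasitoid", P_new)):
        neg = np.where(arr < 0)[0]
        for j in neg:
            events.append({"t": t_new, "event": "clip",
                           "stock": tag, "species": config.species_ids[j],
                           "value": float(arr[j])})
        np.maximum(arr, 0.0, out=arr)

    new_state = SystemState(t_new, N_new, P_new)
    for b in config.calendar.season_boundaries(config.horizon):
        if state.t + 1e-9 < b <= t_new + 1e-9:
            new_state = replace(
                apply_season_transition(replace(new_state, t=b), config),
                t=t_new)
            events.append({"t": b, "event": "carryover",
                           "fraction": config.calendar.carryover_fraction})
    return new_state, flows, events


def simulate(config: ScenarioConfig) -> Trajectory:
    """Integrate the scenario over its horizon.

    The trajectory records the state at every multiple of dt together with
    the flow rates evaluated at that state (the rates the integrator used to
    leave it; the final sample's flows are evaluated but unused).
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid scenario: " + "; ".join(violations))

    ids = config.species_ids
    m = len(ids)
    n_steps = config.n_steps()
    times = np.arange(n_steps + 1) * config.dt

    N = np.empty((n_steps + 1, m))
    P = np.empty((n_steps + 1, m))
    G = np.empty((n_steps + 1, m))
    L = np.empty((n_steps + 1, m))
    R = np.empty((n_steps + 1, m))
    D = np.empty((n_steps + 1, m))
    events: list[dict] = []

    state = SystemState(
        0.0,
        np.array([config.initial_pest_stocks[s] for s in ids]),
        np.array([config.initial_parasitoid_stocks[s] for s in ids]))

    for k in range(n_steps + 1):
        state = replace(state, t=float(times[k]))  # keep grid times exact
        N[k], P[k] = state.N, state.P
        flows = _flows(state, config)
        G[k], L[k] = flows.pest_growth, flows.pest_parasitism_loss
        R[k], D[k] = flows.parasitoid_inflow, flows.parasitoid_outflow
        if k < n_steps:
            state, _, ev = step(state, config)
            events.extend(ev)

    labels = ["cropping" if config.calendar.is_cropping(t) else "non-cropping"
              for t in times]
    return Trajectory(times=times, species_order=ids, N=N, P=P, G=G, L=L,
                      R=R, D=D, season_labels=labels, config=config,
                      events=events)
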