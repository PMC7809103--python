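"""Biological constants, competition matrices and scenario assembly.

The model describes four lepidopteran maize pests in Kenya — the stemborers
*Busseola fusca* (Bf), *Sesamia calamistis* (Sc) and *Chilo partellus* (Cp)
and the invasive fall armyworm *Spodoptera frugiperda* (Sf) — together with
the parasitoid guild attacking each of them.  Every numeric default in this
module is a published constant; :data:`PROVENANCE` records the source of each
one so the defaults are auditable.

Competition coefficients ``a_ij`` (the per-individual depressive effect of
species *j* on species *i*) were estimated separately for every 2-, 3- and
4-species combination, so lookup is keyed by the exact species subset, never
by pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SF", "BF", "SC", "CP", "CANONICAL_ORDER",
    "SpeciesParameters", "CompetitionMatrix", "SeasonCalendar",
    "ParasitoidParameters", "ScenarioConfig",
    "build_species_table", "build_competition_matrix", "build_scenario",
    "build_aggregate_scenario", "validate_config", "canonical_subset",
    "PROVENANCE", "WILD_PARASITISM_DEFAULT", "WILD_PARASITISM_ALTERNATE",
]

# Canonical species ids and internal ordering.  All I/O labels stocks by id,
# so this ordering never leaks into files.
SF = "Sf"
BF = "Bf"
SC = "Sc"
CP = "Cp"
CANONICAL_ORDER: tuple[str, ...] = (SF, BF, SC, CP)

DISPLAY_NAMES = {
    SF: "Spodoptera frugiperda",
    BF: "Busseola fusca",
    SC: "Sesamia calamistis",
    CP: "Chilo partellus",
}

# Monthly intrinsic growth rates r_i and cropping-season parasitism
# fractions phi_i of the four pests.
GROWTH_RATES = {CP: 0.83, BF: 0.80, SC: 0.80, SF: 0.70}
PARASITISM_FRACTIONS_CROP = {CP: 0.30, BF: 0.25, SC: 0.28, SF: 0.22}

# Wild-habitat (non-cropping season) parasitism fraction.  The printed source
# row is garbled ("0.055% was considered"); 0.05 matches the value column and
# is the default, 0.055 is kept as a named alternative preset.
WILD_PARASITISM_DEFAULT = 0.05
WILD_PARASITISM_ALTERNATE = 0.055

# Competition-coefficient grids, one per published species combination.  Each
# grid is stored exactly as printed: entry [row j][column i] is the effect of
# the acting species j on the affected species i ("j/i" layout).  The
# diagonal is the unit intraspecific effect.
_GRIDS: dict[frozenset, tuple[tuple[str, ...], tuple[tuple[float, ...], ...]]] = {
    frozenset({BF, SC}): ((BF, SC), ((1.0, 2.51e-4),
                                     (3.31e-4, 1.0))),
    frozenset({BF, CP}): ((BF, CP), ((1.0, 9.12e-5),
                                     (4.15e-4, 1.0))),
    frozenset({SC, CP}): ((SC, CP), ((1.0, 1.42e-4),
                                     (3.13e-4, 1.0))),
    frozenset({SF, BF}): ((SF, BF), ((1.0, 4.1e-4),
                                     (3.02e-4, 1.0))),
    frozenset({SF, SC}): ((SF, SC), ((1.0, 1.99e-4),
                                     (1.07e-4, 1.0))),
    frozenset({SF, CP}): ((SF, CP), ((1.0, 2.2e-4),
                                     (2.1e-4, 1.0))),
    frozenset({BF, SC, CP}): ((BF, SC, CP), ((1.0, 9.0e-5, 5.1e-5),
                                             (8.2e-5, 1.0, 1.02e-4),
                                             (3.5e-4, 2.01e-4, 1.0))),
    frozenset({SF, BF, SC}): ((SF, BF, SC), ((1.0, 3.02e-4, 3.1e-4),
                                             (9.7e-5, 1.0, 1.13e-4),
                                             (1.02e-4, 1.18e-5, 1.0))),
    frozenset({SF, BF, CP}): ((SF, BF, CP), ((1.0, 1.7e-4, 9.2e-5),
                                             (7.6e-5, 1.0, 5.7e-5),
                                             (1.91e-5, 3.09e-4, 1.0))),
    frozenset({SF, SC, CP}): ((SF, SC, CP), ((1.0, 5.0e-5, 8.7e-5),
                                             (2.51e-4, 1.0, 1.02e-4),
                                             (1.78e-4, 2.15e-4, 1.0))),
    frozenset({SF, BF, SC, CP}): (
        (SF, BF, SC, CP),
        ((1.0, 2.19e-4, 2.5e-4, 5.1e-5),
         (2.4e-4, 1.0, 2.07e-4, 2.3e-5),
         (2.2e-4, 3.04e-4, 1.0, 2.1e-5),
         (2.01e-4, 2.02e-4, 8.0e-5, 1.0))),
}


class UnknownSpeciesError(ValueError):
    """A species id outside the modelled four was requested."""


class UnknownCombinationError(ValueError):
    """No published coefficient block exists for the requested subset."""


@dataclass(frozen=True)
class SpeciesParameters:
    """Per-pest biological constants.

    ``growth_rate`` is the intrinsic monthly fractional increase r_i;
    ``parasitism_fraction_crop`` is the lumped-guild parasitism fraction
    phi_i that applies in the cropping season once parasitism is active.
    """

    species_id: str
    growth_rate: float
    parasitism_fraction_crop: float
    display_name: str = ""

    def violations(self) -> list[str]:
        out = []
        if not (0.0 < self.growth_rate <= 1.0):
            out.append(
                f"species {self.species_id}: growth_rate must satisfy "
                f"0 < r <= 1, got {self.growth_rate}")
        if not (0.0 <= self.parasitism_fraction_crop < 1.0):
            out.append(
                f"species {self.species_id}: parasitism_fraction_crop must "
                f"satisfy 0 <= phi < 1, got {self.parasitism_fraction_crop}")
        return out


@dataclass(frozen=True)
class CompetitionMatrix:
    """Interaction coefficients a_ij for an ordered species subset.

    ``a[i, j]`` is the per-individual effect of species ``species_order[j]``
    on species ``species_order[i]``; the diagonal is exactly 1.
    """

    species_order: tuple[str, ...]
    a: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))

    def coefficient(self, affected: str, acting: str) -> float:
        """Return a(affected <- acting)."""
        i = self.species_order.index(affected)
        j = self.species_order.index(acting)
        return float(self.a[i, j])

    def reorder(self, order: Sequence[str]) -> "CompetitionMatrix":
        idx = [self.species_order.index(s) for s in order]
        return CompetitionMatrix(tuple(order), self.a[np.ix_(idx, idx)])

    def violations(self) -> list[str]:
        out = []
        m = len(self.species_order)
        if self.a.shape != (m, m):
            out.append(
                f"matrix: dimension {self.a.shape} does not match the "
                f"{m} species in {self.species_order}")
            return out
        if not np.all(np.diag(self.a) == 1.0):
            out.append("matrix: diagonal entries must be exactly 1")
        off = self.a[~np.eye(m, dtype=bool)]
        if off.size and np.any(off < 0.0):
            out.append("matrix: off-diagonal coefficients must be >= 0")
        return out

    def __eq__(self, other):
        if not isinstance(other, CompetitionMatrix):
            return NotImplemented
        return (self.species_order == other.species_order
                and self.a.shape == other.a.shape
                and bool(np.all(self.a == other.a)))


@dataclass(frozen=True)
class SeasonCalendar:
    """Cropping-season timing and habitat capacities.

    Time is measured in months since the first planting (April 1).  Each year
    holds two 3-month cropping blocks (April–June, October–December); outside
    them pests persist on wild hosts at a much smaller capacity.  Pests reach
    the field only ``pest_entry_delay`` months after planting, and crop-level
    parasitism starts ``parasitism_onset_delay`` months after planting (the
    guild responds from the pest's second field generation onward).
    """

    start_month: str = "April"
    cropping_blocks: tuple[tuple[float, float], ...] = ((0.0, 3.0), (6.0, 9.0))
    year_length: float = 12.0
    capacity_crop: float = 62_500.0
    capacity_wild: float = 625.0
    carryover_fraction: float = 0.10
    pest_entry_delay: float = 0.0
    parasitism_onset_delay: float = 2.0
    parasitism_fraction_wild: float = WILD_PARASITISM_DEFAULT

    _EPS = 1e-9

    def block_at(self, t: float):
        """Return (planting, end) in absolute months if t is in a cropping
        block, else None.  Block intervals are half-open [start, end)."""
        ty = t % self.year_length
        year0 = t - ty
        for s, e in self.cropping_blocks:
            if s - self._EPS <= ty < e - self._EPS:
                return (year0 + s, year0 + e)
        return None

    def is_cropping(self, t: float) -> bool:
        return self.block_at(t) is not None

    def season_boundaries(self, horizon: float) -> list[float]:
        """Absolute times of every cropping -> non-cropping transition."""
        out = []
        year = 0.0
        while year < horizon + self._EPS:
            for _, e in self.cropping_blocks:
                b = year + e
                if b <= horizon + self._EPS:
                    out.append(b)
            year += self.year_length
        return sorted(out)

    def violations(self) -> list[str]:
        out = []
        blocks = sorted(self.cropping_blocks)
        for s, e in blocks:
            if not (0.0 <= s < e <= self.year_length):
                out.append(f"calendar: cropping block ({s}, {e}) does not fit "
                           "inside one year")
            if abs((e - s) - 3.0) > 1e-9:
                out.append(f"calendar: cropping block ({s}, {e}) is not a "
                           "3-month interval")
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if e1 > s2 + 1e-9:
                out.append("calendar: cropping blocks overlap")
        if not (0.0 < self.carryover_fraction <= 1.0):
            out.append("calendar: carryover_fraction must be in (0, 1], got "
                       f"{self.carryover_fraction}")
        if self.capacity_wild > self.capacity_crop:
            out.append("calendar: capacity_wild must not exceed capacity_crop")
        if min(self.capacity_wild, self.capacity_crop) <= 0:
            out.append("calendar: capacities must be positive")
        if self.pest_entry_delay < 0 or self.parasitism_onset_delay < 0:
            out.append("calendar: delays must be >= 0")
        if not (0.0 <= self.parasitism_fraction_wild < 1.0):
            out.append("calendar: parasitism_fraction_wild must be in [0, 1)")
        return out


@dataclass(frozen=True)
class ParasitoidParameters:
    """Lumped parasitoid-guild constants, shared by all four guilds."""

    per_host_emergence: float = 5.0
    sex_ratio: float = 0.46
    decrease_rate: float = 0.7
    meeting_probability: float = 0.035

    def violations(self) -> list[str]:
        out = []
        if self.per_host_emergence <= 0:
            out.append("parasitoid: per_host_emergence must be > 0")
        if not (0.0 < self.sex_ratio < 1.0):
            out.append("parasitoid: sex_ratio must be in (0, 1)")
        if not (0.0 < self.decrease_rate <= 1.0):
            out.append("parasitoid: decrease_rate must be in (0, 1]")
        if not (0.0 < self.meeting_probability < 1.0):
            out.append("parasitoid: meeting_probability must be in (0, 1)")
        return out


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully resolved simulation setup."""

    species: tuple[SpeciesParameters, ...]
    matrix: CompetitionMatrix
    calendar: SeasonCalendar = field(default_factory=SeasonCalendar)
    parasitoid: ParasitoidParameters = field(default_factory=ParasitoidParameters)
    dt: float = 0.25
    horizon: float = 24.0
    initial_pest_stocks: Mapping[str, float] = field(default_factory=dict)
    initial_parasitoid_stocks: Mapping[str, float] = field(default_factory=dict)
    reference_density_crop: float = 2.0
    reference_density_wild: float = 0.5
    # Pluggable model pieces (see pestdyn.dynamics for the registries).
    parasitism_model: str = "saturating"
    competition_units: str = "fraction"

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(sp.species_id for sp in self.species)

    def species_params(self, species_id: str) -> SpeciesParameters:
        for sp in self.species:
            if sp.species_id == species_id:
                return sp
        raise UnknownSpeciesError(f"species {species_id!r} not in scenario")

    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))


# --------------------------------------------------------------------------
# Builders

def build_species_table() -> list[SpeciesParameters]:
    """The four modelled pests with their published constants."""
    return [
        SpeciesParameters(sid, GROWTH_RATES[sid],
                          PARASITISM_FRACTIONS_CROP[sid], DISPLAY_NAMES[sid])
        for sid in CANONICAL_ORDER
    ]


def canonical_subset(species_set: Iterable[str]) -> tuple[str, ...]:
    """Validate ids and return them in canonical (Sf, Bf, Sc, Cp) order."""
    ids = set(species_set)
    unknown = ids - set(CANONICAL_ORDER)
    if unknown:
        raise UnknownSpeciesError(
            f"unknown species id(s) {sorted(unknown)}; known ids are "
            f"{list(CANONICAL_ORDER)}")
    if not ids:
        raise UnknownCombinationError("species set must not be empty")
    return tuple(s for s in CANONICAL_ORDER if s in ids)


def build_competition_matrix(species_set: Iterable[str]) -> CompetitionMatrix:
    """Published coefficient block for an exact species subset.

    The published coefficients are combination-specific: the same pair has
    different a_ij in 2-, 3- and 4-species systems, so the lookup never falls
    back to sub-blocks.  Singletons return the 1x1 identity.
    """
    order = canonical_subset(species_set)
    if len(order) == 1:
        return CompetitionMatrix(order, np.array([[1.0]]))
    key = frozenset(order)
    if key not in _GRIDS:
        raise UnknownCombinationError(
            f"no published coefficient block for combination {order}")
    grid_order, grid = _GRIDS[key]
    # The stored grids are [acting j][affected i]; a[i, j] is its transpose.
    a_grid = np.asarray(grid, dtype=float).T
    return CompetitionMatrix(tuple(grid_order), a_grid).reorder(order)


_SCALAR_OVERRIDES = {
    "dt", "horizon", "reference_density_crop", "reference_density_wild",
    "parasitism_model", "competition_units",
}
_NESTED_OVERRIDES = {"calendar", "parasitoid", "species", "matrix",
                     "initial_pest_stocks", "initial_parasitoid_stocks"}


def build_scenario(species_set: Iterable[str],
                   overrides: Mapping | None = None) -> ScenarioConfig:
    """Assemble a scenario from the published defaults.

    ``overrides`` replaces any field: scalars (``dt``, ``horizon``, ...),
    nested mappings for ``calendar``/``parasitoid`` fields, per-species
    parameter patches under ``species`` (``{"Cp": {"growth_rate": 0.9}}``),
    stock mappings, or a full ``matrix`` replacement (CompetitionMatrix or a
    nested ``{affected: {acting: value}}`` mapping).
    """
    order = canonical_subset(species_set)
    table = {sp.species_id: sp for sp in build_species_table()}
    matrix = build_competition_matrix(order)
    calendar = SeasonCalendar()
    parasitoid = ParasitoidParameters()
    overrides = dict(overrides or {})

    unknown = set(overrides) - _SCALAR_OVERRIDES - _NESTED_OVERRIDES
    if unknown:
        raise ValueError(f"unknown override key(s): {sorted(unknown)}")

    if "calendar" in overrides:
        calendar = replace(calendar, **overrides.pop("calendar"))
    if "parasitoid" in overrides:
        parasitoid = replace(parasitoid, **overrides.pop("parasitoid"))
    if "species" in overrides:
        for sid, patch in overrides.pop("species").items():
            if sid not in table:
                raise UnknownSpeciesError(f"unknown species id {sid!r}")
            table[sid] = replace(table[sid], **patch)
    if "matrix" in overrides:
        m = overrides.pop("matrix")
        if isinstance(m, CompetitionMatrix):
            matrix = m
        else:
            a = matrix.a.copy()
            for affected, row in m.items():
                for acting, val in row.items():
                    a[order.index(affected), order.index(acting)] = val
            matrix = CompetitionMatrix(order, a)

    calendar_violations = calendar.violations()
    if calendar_violations:
        raise ValueError("; ".join(calendar_violations))

    # Default initial stocks: half the wild reference-density load per
    # species, parasitoids seeded at 10% of their host stock.
    ref_wild = float(overrides.get("reference_density_wild", 0.5))
    n0 = ref_wild * calendar.capacity_wild / 2.0
    pest0 = {sid: n0 for sid in order}
    para0 = {sid: 0.1 * n0 for sid in order}
    pest0.update(overrides.pop("initial_pest_stocks", {}))
    para0.update(overrides.pop("initial_parasitoid_stocks", {}))

    config = ScenarioConfig(
        species=tuple(table[sid] for sid in order),
        matrix=matrix,
        calendar=calendar,
        parasitoid=parasitoid,
        initial_pest_stocks=pest0,
        initial_parasitoid_stocks=para0,
        **overrides,
    )
    violations = validate_config(config)
    if violations:
        raise ValueError("; ".join(violations))
    return config


def build_aggregate_scenario(overrides: Mapping | None = None) -> ScenarioConfig:
    """Two-stock validation scenario: all pests pooled into one host stock
    and all guilds into one parasitoid stock.

    The pooled pest carries the across-species mean growth and parasitism
    rates and the summed default initial stocks of the four species.
    """
    table = build_species_table()
    r_bar = sum(sp.growth_rate for sp in table) / len(table)
    phi_bar = sum(sp.parasitism_fraction_crop for sp in table) / len(table)
    pooled = SpeciesParameters("total", r_bar, phi_bar,
                               "pooled pests (validation)")
    calendar = SeasonCalendar()
    n0 = 4 * 0.5 * calendar.capacity_wild / 2.0
    base = dict(
        species=(pooled,),
        matrix=CompetitionMatrix(("total",), np.array([[1.0]])),
        calendar=calendar,
        initial_pest_stocks={"total": n0},
        initial_parasitoid_stocks={"total": 0.1 * n0},
    )
    base.update(overrides or {})
    config = ScenarioConfig(**base)
    violations = validate_config(config)
    if violations:
        raise ValueError("; ".join(violations))
    return config


def validate_config(config: ScenarioConfig) -> list[str]:
    """Return human-readable descriptions of every invariant violation.

    An empty list means the configuration is valid; violations are returned,
    never raised, so callers can report all of them at once.
    """
    out: list[str] = []
    for sp in config.species:
        out.extend(sp.violations())
    out.extend(config.matrix.violations())
    out.extend(config.calendar.violations())
    out.extend(config.parasitoid.violations())

    ids = config.species_ids
    if len(set(ids)) != len(ids):
        out.append("species: duplicate species ids")
    if config.matrix.species_order != ids:
        out.append(
            f"matrix: species_order {config.matrix.species_order} does not "
            f"match the scenario species {ids}")
    if not (config.dt > 0):
        out.append(f"dt: must be > 0, got {config.dt}")
    elif config.horizon <= 0 or not math.isclose(
            round(config.horizon / config.dt) * config.dt, config.horizon,
            rel_tol=0, abs_tol=1e-9):
        out.append(f"horizon: must be a positive multiple of dt, got "
                   f"horizon={config.horizon}, dt={config.dt}")
    for name, stocks in (("initial_pest_stocks", config.initial_pest_stocks),
                         ("initial_parasitoid_stocks",
                          config.initial_parasitoid_stocks)):
        missing = set(ids) - set(stocks)
        if missing:
            out.append(f"{name}: missing entries for {sorted(missing)}")
        bad = [s for s, v in stocks.items() if v < 0]
        if bad:
            out.append(f"{name}: negative stocks for {sorted(bad)}")
    if config.reference_density_crop <= 0 or config.reference_density_wild <= 0:
        out.append("reference densities must be positive")
    from . import dynamics  # local import: avoid a cycle at module load
    if config.parasitism_model not in dynamics.PARASITISM_MODELS:
        out.append(f"parasitism_model: unknown model "
                   f"{config.parasitism_model!r}; available: "
                   f"{sorted(dynamics.PARASITISM_MODELS)}")
    if config.competition_units not in ("fraction", "absolute"):
        out.append(f"competition_units: must be 'fraction' or 'absolute', "
                   f"got {config.competition_units!r}")
    return out


# --------------------------------------------------------------------------
# Provenance: every numeric default maps to the published table cell it came
# from.  A test asserts this map covers every default the builders emit.
PROVENANCE: dict[str, str] = {
    "growth_rate.Cp": "constants table: C. partellus reference fraction growth rate = 0.83",
    "growth_rate.Bf": "constants table: B. fusca reference fraction growth rate = 0.8",
    "growth_rate.Sc": "constants table: S. calamistis reference fraction growth rate = 0.8",
    "growth_rate.Sf": "constants table: S. frugiperda reference fraction growth rate = 0.7",
    "parasitism_fraction_crop.Cp": "constants table: C. partellus reference fractional parasitism rate = 0.3",
    "parasitism_fraction_crop.Bf": "constants table: B. fusca reference fractional parasitism rate = 0.25",
    "parasitism_fraction_crop.Sc": "constants table: S. calamistis reference fractional parasitism rate = 0.28",
    "parasitism_fraction_crop.Sf": "constants table: S. frugiperda reference fractional parasitism rate = 0.22",
    "calendar.capacity_crop": "constants table: carrying capacity of 1 ha of maize field = 62,500",
    "calendar.capacity_wild": "constants table: carrying capacity of 1 ha in non-cropping seasons = 625",
    "calendar.cropping_blocks": "assumptions: 3-month maize grown April-June and October-December",
    "calendar.year_length": "assumptions: two cropping and two non-cropping seasons per year",
    "calendar.carryover_fraction": "assumptions: only 10% of field pests survive on alternative hosts",
    "calendar.pest_entry_delay": "default 0: the crop capacity is available from planting (the 1-month 'first recorded' assumption is read as observational; see methods note); set to 1 to hold K at the wild level for the first month instead",
    "calendar.parasitism_onset_delay": "assumptions: parasitism recorded from the second pest generation, ~2 months after planting",
    "calendar.parasitism_fraction_wild": "constants table: wild-habitat parasitism fraction = 0.05 (printed row garbled; 0.055 kept as alternate preset)",
    "calendar.start_month": "assumptions: first planting in April",
    "parasitoid.per_host_emergence": "constants table: number of parasitoids per host = 5",
    "parasitoid.sex_ratio": "constants table: parasitoid sex ratio = 0.46",
    "parasitoid.decrease_rate": "constants table: parasitoid fractional decrease rate = 0.7",
    "parasitoid.meeting_probability": "constants table: host-parasitoid meeting probability = 3.5%",
    "dt": "constants table: time step = 0.25 month (weekly recording)",
    "horizon": "constants table: period of the simulation = 24 months",
    "reference_density_crop": "constants table: reference pest density = 2 per plant in maize field",
    "reference_density_wild": "constants table: reference pest density = 0.5 per plant in wild habitat",
    "matrix": "competition-coefficient table, combination-specific blocks (j/i layout: rows act on columns)",
    "initial_pest_stocks": "model choice: reference_density_wild x capacity_wild / 2 per species (documented in methods)",
    "initial_parasitoid_stocks": "model choice: 10% of the host's initial stock (documented in methods)",
}
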