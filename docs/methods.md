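# Methods

`pestdyn` is a stock-and-flow reconstruction of the population dynamics of
four lepidopteran maize pests in Kenya — the stemborers *Busseola fusca*
(Bf), *Sesamia calamistis* (Sc), *Chilo partellus* (Cp) and the invasive
fall armyworm *Spodoptera frugiperda* (Sf) — interacting with each other
through competition for the maize resource and each with its own lumped
parasitoid guild. This note records the model, its parameters, and the
design choices made where the formulation was genuinely open.

## State and flows

Each species contributes two stocks, pest density `N_i` and guild density
`P_i` (individuals/ha, continuous; "individuals" are treated as densities,
never rounded). Per month:

```
dN_i/dt = G_i - L_i          pest growth minus parasitism loss
dP_i/dt = R_i - D_i          guild emergence minus guild decrease
```

**Growth** follows the Lotka–Volterra competition form against a seasonally
switching capacity `K(t)`:

```
G_i = r_i N_i (1 - N_i / K(t) - sum_{j != i} a_ij N_j)
```

`r_i` is the intrinsic monthly growth rate and `a_ij` the per-individual
depressive effect of species `j` on species `i`. The competition term
`a_ij N_j` is read as a *dimensionless fraction of species i's effective
capacity* (`competition_units="fraction"`, the default). The textbook
absolute-units form `G_i = (r_i N_i / K)(K - N_i - sum a_ij N_j)` is also
implemented (`competition_units="absolute"`). The fractional reading is the
package's resolution of the unstated coefficient units: the published
coefficients are of order 1e-4 while the crop capacity is 62,500/ha, so in
absolute units the interspecific term would never exceed a few individuals
against a capacity headroom of tens of thousands — competition would be
numerically irrelevant and none of the published dominance outcomes could
arise. In the fractional reading the term is order one exactly at the
simulated abundances (1e3–1e4/ha), and the simulated dominance structure
(C. partellus dominant in every system it joins, B. fusca displaced in the
Cp+Bf pair at roughly 80/20) matches the published account. Equilibrium
states of the linear survival system `K_i = N_i + sum a_ij N_j` are exact
fixed points of the growth flow under the absolute convention; under the
fractional convention the corresponding null-cline is the same system with
coefficients rescaled by `K`.

**Parasitism** uses a pluggable strategy. The default, `"saturating"`:

```
L_i = phi_i(t) * N_i * P_i / (P_i + p_meet * N_i)
```

`phi_i(t)` is the reference parasitism fraction in force at time t and
`p_meet = 0.035` the host–parasitoid meeting probability. A guild large
relative to the encounter threshold `p_meet * N_i` realizes the full
reference fraction (per-capita host loss is capped at `phi_i`); a scarce
guild parasitizes `phi_i / p_meet` hosts per female per month. The
mass-action alternative `"bilinear"`, `L_i = phi_i(t) p_meet N_i P_i /
K(t)`, is registered and unit-tested, but note its consequence: guild
recruitment per capita is then bounded by `2.3 * phi_i * p_meet ~
0.024/month`, far below the guild decrease rate of 0.7/month, so under it
parasitoid stocks decay monotonically from any initial condition and the
cyclical host–parasitoid relationship — the central single-species result —
cannot form. That arithmetic is why the saturating form is the default.

**Guild flows** are fixed by published constants: each parasitized host
yields 5 parasitoids at a 0.46 female sex ratio, so `R_i = 2.3 * L_i`
exactly (asserted at every step), and `D_i = 0.7 * P_i`.

## Seasonal forcing

Time starts at the April planting of year 1; a 3-month maize variety gives
cropping blocks [0,3) and [6,9) months of each 12-month year. During a
block `K = 62,500`/ha; outside it the wild refuge supports `K = 625`/ha. At
each cropping → non-cropping boundary the pest stocks are cut once to 10%
(survival on alternative hosts); guilds take no haircut and decline only
through `D_i`. Crop-level parasitism `phi_i` activates 2 months after each
planting (the guild responds from the pest's second field generation);
outside cropping blocks a wild-habitat fraction of 0.05 applies; in the
first two months of each block parasitism is inactive.

The calendar exposes `pest_entry_delay`: with a delay `d`, `K` stays at the
wild level for the first `d` months of each block. Its default is 0 — the
crop capacity is available from planting, and the "pests first recorded one
month after planting" field observation is read as a statement about
detection, not capacity. This reading was adopted because it is the one the
published outcomes identify: with a 1-month capacity delay the single-
species peak is ~1,860/ha and the Cp+Bf split 67/33; with capacity from
planting the peak is ~3,900/ha (published: ~4,900 "after 6 months") and the
Cp+Bf split 80.5/19.5 (published: 81.18/18.82).

## Parameters

| parameter | value | units | meaning |
|---|---|---|---|
| r (Cp, Bf, Sc, Sf) | 0.83, 0.80, 0.80, 0.70 | /month | intrinsic growth |
| phi crop (Cp, Bf, Sc, Sf) | 0.30, 0.25, 0.28, 0.22 | – | reference parasitism fraction |
| phi wild | 0.05 | – | non-cropping parasitism (0.055 kept as named alternate; the source row is garbled) |
| K crop / K wild | 62,500 / 625 | /ha | habitat capacities |
| carryover | 0.10 | – | pest survival across the season boundary |
| parasitoids per host × sex ratio | 5 × 0.46 | – | guild recruitment (2.3 females/host) |
| guild decrease | 0.7 | /month | parasitoid outflow |
| meeting probability | 0.035 | – | encounter saturation threshold |
| dt / horizon | 0.25 / 24 | months | forward-Euler step, simulated period |
| a_ij | see coefficient table | /individual (fractional) | combination-specific blocks |

Coefficient blocks are stored exactly as printed, in the "j/i" layout (the
row species acts on the column species) — `a[i, j]` in memory is the
transpose of the printed grid. Lookup is keyed by the exact species subset
because the same pair carries different coefficients in 2-, 3- and
4-species systems. Every default is traceable through the machine-readable
`PROVENANCE` map; a test asserts full coverage.

**Initial conditions** (not published): each pest starts at the wild
reference-density load `0.5/plant x 625 / 2 = 156.25`/ha, each guild at 10%
of its host. Both are configurable; dominance shares averaged over months
6–24 are insensitive to moderate changes because the wild-season
saturation resets the stocks each half-year. Multi-species runs seed all
species equally.

## Integration and numerics

Forward Euler at dt = 0.25 month (the platform-native fixed step of the
original implementation): `N' = max(0, N + dt (G - L))`, similarly for P;
clips to zero are logged as events, and the season haircut is applied after
the Euler update of the step that crosses the boundary. Stock changes equal
`dt` × net flow bit-exactly away from logged events. With the default
rates, per-step relative changes stay below ~0.3, well inside Euler's
stability region; the saturating parasitism form keeps all per-capita rates
bounded (host loss by `phi`, guild growth by `2.3 phi / p_meet`).

At r = 0.83/month the first-order scheme lags the true exponential phase by
about 7% per month, so against the closed-form logistic the dt = 0.25
trajectory shows a ~45% maximum relative error through mid-growth
(vanishing at saturation), halving as dt halves — the convergence tests
assert the monotone improvement. The 24-month trajectories should therefore
be read as the fixed-step dynamical system the original platform actually
iterates, not as a converged ODE solution; all headline shares and ratios
are computed at the native step.

The first interior pest peak after the 4-month burn-in falls at month 8.75
(late in the second cropping season); the same seasonal peak recurs each
half-year with slightly growing amplitude, so the global maximum lands at
month 20.75 at essentially the same height. "Peak after 6 months" is
operationalized as that first post-burn-in peak.

## Dominance metrics

Shares are reported both instantaneously at month 6 and time-averaged over
months 6–24 (the mean over samples of `N_i / sum_j N_j`, skipping zero-total
samples); the averaged form is the headline number because it is stable
against Euler phase jitter. "Average total pest populations" is the time
mean of the summed pest stocks over the full horizon, averaged across all
systems of a given cardinality (4 sole, 6 pairs, 4 triples, 1 quad); the
cross-cardinality comparisons are ratios of those means in percent. Cycle
detection lists interior local maxima (strict sign change of the first
difference) after a 4-month burn-in and the lag of each guild peak behind
the nearest preceding host peak. The phase portrait pools all pests and all
guilds into one (host, parasitoid) orbit; closure is measured as the
distance between the first and last point of the final 12-month cycle
relative to the loop diameter.

## Coefficient estimation and synthetic data

The estimator is the literal rearrangement of the equilibrium survival
system: per focal species, intercept-free OLS of `survived - N_i` on the
competitor densities, with standard errors, residual scales and design
condition numbers reported; negative estimates are retained but flagged
(no non-negativity constraint, which would distort the standard errors),
and designs with no density variation in some competitor are rejected as
unidentifiable. The synthetic experiment generator draws a full factorial
of arena densities (default levels 0/50/100/200 larvae, 3 replicates) and
adds Gaussian response noise (default sd 5 counts) truncated at zero — the
additive-error linear model multiple regression assumes. The truncation
binds only in cells whose expected survival is within a few sd of zero;
unbiasedness checks therefore use all-positive density levels. Synthetic
data emulate only this statistical structure, not the empirical noise level
or any behavioural detail of real larval competition assays; passing
recovery tests show the estimator is correct under its own model, not that
field coefficients are well determined.

## What the synthetic generators do and do not emulate

Trajectory fixtures (logistic, lagged sine pair, exact circle, flat) carry
analytic ground truth for the metrics tests. The parameter-jitter ensemble
multiplies r, phi and off-diagonal a by independent lognormal factors to
probe ordering robustness. None of these reproduce demographic
stochasticity, spatial structure, temperature dependence, or
parasitoid–parasitoid competition — all outside the model by assumption —
so green tests certify the reconstruction's internal logic, not field
realism.

## Known limitations

* The original platform's exact flow equations are unavailable; the
  parasitism form, coefficient units and entry-delay reading above are this
  package's documented reconstruction, each chosen once and frozen. Under
  them most published shares and ratios reproduce to within a few points
  (e.g. Cp+Bf 80.5/19.5 vs 81.18/18.82), but some do not: the
  reconstruction puts S. frugiperda, not B. fusca, last in the four-species
  system (8.1% vs 11.0%, published 14.85% vs 8.02%), makes B. fusca rather
  than S. frugiperda the Sf+Bf pair winner, and yields a sole-vs-pairs
  load ratio of 76% (published 85.36%) and single-stemborer peaks of
  ~3,900/ha (published ~4,900).
* Guild peaks reach ~25–35% of host peaks, lower than the published
  near-parity; the guild decrease rate of 0.7/month with parasitism active
  only one month per cropping block bounds how much guild stock can
  accumulate under any form that caps per-capita host loss at phi.
* Equal initial seeding across species is assumed; species-specific
  invasion timing (S. frugiperda arrived decades after the stemborers) is
  not modelled.
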