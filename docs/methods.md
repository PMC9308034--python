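# Methods

This note documents the models implemented in `carenet`, the assumptions
behind them, the choices made where the design was genuinely open, and what
the synthetic data do and do not establish.

## Patient-sharing network

Every node is a unique (physician, specialty, municipality) combination; a
physician practising in two municipalities is two nodes, and removing one
leaves the other active. The edge weight between physicians i and j is the
number of **distinct** patients with at least one visit to each within
±`window_days` of one another. Choices:

* *Window*: "three months" is implemented as 91 days, inclusive at both
  boundaries. Calendar-month arithmetic is ill-defined across month lengths
  and would make the window's width depend on the anchor date.
* *Distinct patients, not visit pairs*: a patient who co-visits the same
  pair in several separate windows still contributes 1 to the weight. The
  weight is a patient count; under this rule it is also irrelevant which of
  a patient's visits "anchors" the window, so all anchors are evaluated.
* *Distance*: great-circle (haversine) distance between municipality
  coordinates, boundary inclusive (edges at exactly `d` survive).
* Thresholding sets weights to zero but keeps nodes; isolated physicians
  stay in the system because patients can still reach them through random
  re-location when α > 0.

`build_sharing_network` is checked against an O(visits²) brute-force oracle
on randomized small inputs.

## Capacity estimation

`N` = distinct patients per physician per quarter, averaged over the
quarters in which the physician was active at all, rounded to the nearest
integer. `C` = within each (specialty, half-open 5-hour opening-hour bin
[0,5), [5,10), …), the median `N` of the top-`c`% physicians by `N`; the
top set has size ⌈c/100 · bin size⌉ with a floor of one, so small bins are
well-defined. Fractional medians are rounded to the nearest integer (a
capacity is a patient count). Two conventions required a decision:

* **Flooring**: every physician's capacity is floored at their own load,
  `C := max(C, N)`. Without it, the busiest physicians would start *over*
  capacity with negative free capacity, which the displacement bookkeeping
  cannot represent.
* **Missing opening hours**: physicians absent from the opening-hours
  source receive the median assigned `C` of their specialty; a specialty
  with no opening-hour data at all is treated as a single bin.

## Displacement model

State: each physician has an availability flag, a current patient count and
free capacity `C − count`; each patient has a home municipality (that of
their initial physician), a most recent physician, a rejection counter and
a status in {placed, searching, lost}. Invariants maintained and tested at
every step: located + searching + lost = total; no available physician
exceeds `C`; lost is absorbing and non-decreasing.

One displacement round processes all searching patients in uniformly random
order. The candidate draw mixes two channels: with probability α a uniform
draw over *all* available physicians (full ones included — capacity is
discovered on arrival), otherwise a draw over the available neighbours of
the patient's **most recent** physician, proportional to edge weight. Using
the most recent rather than the original physician supports chained
displacement (a patient displaced twice searches from where they last were).
A candidate farther than `d` from the patient's *home* municipality (never
the current one) triggers a redraw; after ten failed redraws the last
candidate is kept regardless of distance. A patient whose recent physician
has no available neighbours under α = 0 collects one rejection per round
until lost — keeping the `s`-rejection bookkeeping uniform instead of
declaring them lost immediately, which would distort the timing of the
lost-patient limit. The rejection counter resets on successful placement:
`s` bounds one search episode, not lifetime moves.

Scenario (i) removes one uniformly random available physician per step,
country-wide, and lets displacement run to quiescence (at most `s` rounds)
before the next removal; the run ends when one physician remains, or after
complete removal when explicitly requested (at which point 100% of patients
are lost — a terminal-state check in the test suite). Scenario (ii) removes
⌊fraction · n⌋ physicians at once and runs exactly `s` rounds; patients
still searching afterwards are lost.

Randomness: one seeded generator per replicate; replicate `k` of an
ensemble uses `seed + k`. Ensemble defaults are 100 replicates for scenario
(i) and 10 for scenario (ii).

The engine caches the cumulative neighbour weights per source physician
within a removal epoch: the weighted draw depends on availability only,
which changes solely at removals, so the cache is exact and the draws are
bit-identical to the uncached implementation.

## Indicators

Resilience curves are ensemble means ± SD, per state, of remaining free
capacity (relative to the state's initial free capacity; physician states)
and cumulative lost patients (relative to the state's initial patients;
patients attributed to their home state) versus the country-wide fraction
removed. `L_FC` is the smallest removed fraction at which mean free
capacity drops *below* 0.20 of its initial value, `L_LP` the smallest at
which the mean lost fraction *exceeds* 0.01, both linearly interpolated
between recorded removal steps on the ensemble-mean curve (not averaged
per-replicate crossings). A limit never crossed is reported as 1.0 with a
censoring flag. The remaining-free-capacity reading of the 20% limit was
chosen over the alternative "20% filled up" phrasing; the two are not
equivalent and the remaining-capacity version matches how the curves are
tracked.

Risk score: `w_j = a_ij / Σ_k a_ik`, normalised over i's neighbourhood so
that `N_i · w_j` distributes exactly i's patients; `R_i` is the neighbour
mean of `min((N_j + N_i w_j)/C_j, 1)`. Isolated physicians get a missing
score rather than 0 — zero would conflate "no neighbours to burden" with
"no impact", and missing values are excluded from aggregates. Benefit:
min–max normalisation of `C − N` within specialty, the simplest map
attaining both endpoints of [0, 1]; an all-equal specialty scores 0
everywhere. Regional levels use strict inequality against the nationwide
mean. The limit-vs-score regression is plain OLS per specialty across
states, with unweighted state-level mean scores (not patient-weighted),
requiring ≥ 4 complete states and flagging rank-deficient designs.

## Synthetic-data generator

The generator emulates the statistical structure of administrative claims
data at desk scale:

* **Geography**: municipalities scattered uniformly over a ~600 × 280 km
  box and partitioned into spatially contiguous federal states
  (equal-count longitude bands split by latitude). Municipality sizes are
  Zipf-like (rank^−0.9) scaled by a log-normal (σ = 0.8) per-state
  urbanisation factor, so states differ systematically in physician density
  and capacity — the urban/rural heterogeneity that makes regional rankings
  meaningful.
* **Physicians**: 13 specialty labels; per specialty, municipalities drawn
  by size weight, opening hours uniform on 15–45 h/week, and a log-normal
  (σ = 0.75) latent popularity that makes quarterly loads heavy-tailed.
* **Visits**: each patient draws a size-weighted home municipality, a
  Poisson number of visits (mean 13/year, the order of real annual contact
  rates), and physicians with probability ∝ popularity ·
  exp(−distance/`locality_scale_km`) (default 30 km). Dates are i.i.d.
  uniform over one year — no seasonality, the simplest model consistent
  with the ±3-month window logic.
* **Defaults**: 90 municipalities in 9 states, 30 physicians per specialty,
  12 000 patients. At these settings every specialty layer keeps a giant
  component above 50% of its physicians, so downstream simulations are
  non-degenerate.

What the generator does **not** emulate: real population geography,
specialty-specific contact patterns (visits are specialty-agnostic),
patient loyalty dynamics, seasonality, or the absolute scale of national
claims data (~10⁸ visits). Passing tests therefore establish the internal
correctness and qualitative behaviour of the framework, not empirical
values for any real health system.

## Problem sizes and numerics

Stress scenarios in the test suite run on a single-specialty, 200-physician
system (~11 000 patients) — large enough for state-level indicators to be
informative, small enough for ensemble work on one CPU. The
ranking-robustness experiment uses ensembles of 100 replicates per
parameter setting (c ∈ {10, 20, 30}, α ∈ {0, 0.15}); at ensembles of ~20
the 1%-lost crossing is still Monte-Carlo-noise-dominated and state
rankings do not even reproduce themselves across seeds. The exhaustive
oracle for the displacement expectation enumerates all processing orders
and candidate draws; that is feasible only for a handful of searching
patients, so the oracle fixtures use ≤ 4 physicians with single-removal
scenarios (removal choice averaged explicitly).

Known limitations: no cross-specialty substitution (each layer is closed),
no physician re-entry or part-time behaviour, no patient-side
heterogeneity beyond location, and municipality-level geography (all
physicians of a municipality are co-located). Tie-breaking: the giant
component resolves size ties toward the component containing the smallest
node label; capacity medians use the standard linear-interpolation median
before integer rounding.
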