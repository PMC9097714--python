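# Methods

## Model and procedure

`trajscan` screens longitudinal health-event data for ordered pairs of
clinical events E1 → E2 that satisfy two distinct criteria, and composes
longer trajectories from them.

**First-occurrence reduction.** Only the first occurrence of each concept
per patient (per cohort window) enters the analysis. This avoids repeatedly
counting chronic, repeatedly-coded conditions, at the cost of blinding the
method to recurrence dynamics; studies of recurrent events should define
shorter cohort windows so a patient contributes several sequence units. A
patient with several cohort windows is treated as several independent
sequence units, and all counts are unit counts.

**Pair enumeration.** A unit realizes E1 → E2 when
`min_gap ≤ date(E2) − date(E1) ≤ max_gap` (both bounds inclusive);
intermediate events never block a pair. The default `min_gap = 1` enforces
strict temporal order and drops same-day co-recording, which is usually an
artifact of coding practice rather than a temporal signal; `max_gap` is
unbounded by default. Pairs below the count floor are not tested. The floor
may be given as an absolute count or as a cohort fraction; a fraction is
converted with ceiling semantics (`⌈prevalence × n_units⌉`) so "at least
x% of the cohort" is guaranteed.

**Matched groups.** For each pair, the exposed group is every unit with E1
(index date = first E1). The background pool is every unit with no E1 at
all: a unit acquiring E1 later is an exposed unit of this pair, and letting
it also serve as a background member would put the same patient on both
sides of the comparison, so the pool excludes all carriers. Exact matching
uses gender × age bin (default 5 years) × calendar year of the index date —
calendar year absorbs secular shifts in coding and treatment. Within a
stratum, greedy 1:`match_ratio` nearest-neighbour matching on the
propensity score without replacement; exposed units are processed in
ascending patient-id order and distance ties go to the lower patient id,
making the algorithm fully deterministic given the seed. Background members
inherit the index date of their exposed partner and must be under
observation on that date. Exposed units with no eligible candidate are
dropped and reported as unmatched.

**Propensity score.** The probability of exposure fitted by an
L2-regularized logistic regression (C = 1) on pre-index history: indicators
of the K = 100 most prevalent concepts occurring strictly before the index
date, plus the total pre-index event count (scaled by 1/10 to keep it
commensurate with the indicators). Logistic regression is used because its
fitted values are guaranteed probabilities in (0, 1). Candidates evaluate
their features at a provisional index date drawn from their stratum's
exposed index dates; matched candidates are re-indexed at their partner's
date. Because none of this depends on E2, matched groups are computed once
per distinct E1 and shared by all pairs with that E1 — this is an exact
reuse, not an approximation.

**Statistics.**

* Association: Fisher's exact test (two-sided, probability-mass rule) on
  the 2×2 table of E2 acquisition within the gap window after the index
  date, exposed vs background. E2 ascertainment is symmetric in both groups.
* Effect size: `RR = (k_exp/n_exp)/(k_bg/n_bg)` with a 95% Katz log-normal
  CI, `exp(ln RR ± 1.96·√(1/k_exp − 1/n_exp + 1/k_bg − 1/n_bg))`. Zero
  cells use the Haldane–Anscombe correction (0.5 to all four cells) for the
  CI, and for the point estimate when `k_bg = 0`; with the correction
  disabled, `k_bg = 0` reports RR = ∞.
* Direction: exact two-sided binomial test at p = ½ on
  `(n_pair(E1→E2), n_pair(E2→E1))`, counted over all cohort units carrying
  both events (not only matched ones), with same-day co-occurrences already
  excluded by `min_gap`.
* Multiple testing: Benjamini–Hochberg (discovery) or Bonferroni
  (validation), applied separately to the Fisher family and the binomial
  family, each across all tested pairs of the run.
* A pair is **directional** iff corrected Fisher p < α (default 0.05), RR ≥
  the range-of-interest floor (default 1.2), corrected binomial p < α, and
  E1-first is the dominant order. The RR floor is one-sided in this
  version; a protective (RR < 1) window is a documented extension point,
  and validation mode already flags significantly protective pairs as
  `opposite_effect` and reversed dominant order as `opposite_direction`.

**Trajectories.** Directional pairs form a directed graph. Candidate
trajectories are all simple paths of 2..`max_trajectory_len` (default 5)
nodes — the simple-path rule guarantees termination on cyclic graphs and
forbids repeated concepts, which first-occurrence sequences could never
realize anyway. Counting reuses the pairwise gap window on each adjacent
pair of the chain; a unit is counted at most once per trajectory.
Composable but unrealized trajectories (count 0) are suppressed by default.

## Parameter defaults

| parameter | default | rationale |
|---|---|---|
| `min_gap_days` | 1 day | strict temporal order, drop same-day coding |
| `max_gap_days` | unbounded | no temporal horizon unless the study imposes one |
| `min_pair_prevalence` | 1% of units | typical floor for cohort-level screening |
| `rr_min_of_interest` | 1.2 | excludes effects too weak to be of practical interest |
| `alpha` | 0.05 | on corrected p-values |
| `correction` | FDR (discovery), Bonferroni (validation) | exploratory vs confirmatory error control |
| `age_bin_years` | 5 | exact-matching age group width |
| `match_ratio` | 1 | 1:1 matching |
| `propensity_top_k` | 100 | prior-history feature count |
| `privacy_min_count` | 20 | printed counts below this are masked `<20` |
| `max_trajectory_len` | 5 | path-length cap for composition |

## Synthetic data

The generator emulates the table schema the pipeline consumes: uniform
random background events (default 100 concepts, 1–30 events per patient,
uniform dates over a 10-year window, uniform gender, birth years 1940–1999,
everyone observed over the whole window). Injected concept ids are disjoint
from the background pool, so planted structure is exactly recoverable.

* `inject_pair` gives `n_carriers` patients E1 at a random date and,
  independently with probability q, E2 at E1 + gap (gap uniform on 30–365
  days, resampled when it would pass the end of observation).
* `inject_trajectory` plants a full ordered chain into exactly `n_carriers`
  patients with strictly positive gaps.
* `planted_rr_dataset` is the calibrated design used for effect-size
  experiments: carrier E1 dates are confined to the first 30 days of the
  window and carriers acquire E2 only through the conditional channel, so
  the exposed-group prevalence equals q exactly; non-carriers acquire E2 at
  a uniform date with probability p0 = q/RR. With index dates at the window
  start, virtually every non-carrier E2 falls after the index, so the
  matched-background prevalence equals p0 and the measured estimand is
  q/p0 = RR by construction. Without this anchoring, the background
  window-hit probability would depend on the index-date distribution and
  the "design RR" would not be a well-defined target.

What the generator does **not** emulate: age/gender-dependent disease
rates (a confounded mode exists — carrier probability may be tied to
covariates — but is off by default), non-uniform event frequencies, coding
artifacts, censoring by death, or correlated comorbidity structure.
Passing the synthetic validation therefore demonstrates correctness of the
machinery (counting, matching mechanics, test calibration, error control),
not robustness to real-data confounding — on real data the propensity and
exact matching have to carry that weight, and residual confounding remains
possible as in any observational design.

## Validation experiments (problem sizes)

The test suite and `scripts/acceptance.py` run: exact recovery of a
3-event trajectory planted into 100 of 400 patients; zero directional
pairs after FDR on five pure-random datasets of 1000 patients (1–30
events each); ≥ 90% detection over 20 replicates of a planted pair with
100 carriers, q = 0.5, design RR = 3 in 1000 patients with sparse (1–10
event) background — an operating point inside the region where detection
is expected to be reliable (it degrades when carriers ≤ 20 and background
is very sparse); ≥ 90% CI coverage over 50 replicates per design RR in
{1.5, 2, 3, 5}; and exhaustive oracle sweeps of the Fisher (row margins
≤ 30, exact integer enumeration), binomial (n ≤ 25) and BH/Bonferroni
primitives.

## Numerical and design notes

* Same-date ties inside a sequence are ordered by ascending concept id;
  all enumeration orders (pairs, paths, rankings) are deterministic.
* Dates are calendar days; all internal arithmetic is in integer days
  since the Unix epoch on a dense units × concepts matrix of
  first-occurrence dates (NaN = concept absent).
* Fisher's test delegates to `scipy.stats.fisher_exact`, binomial to
  `scipy.stats.binomtest`, corrections to
  `statsmodels.stats.multitest.multipletests`; the test suite pins each of
  them to independent exact-arithmetic oracles.
* Degenerate inputs: a pair whose exposed group cannot be matched at all is
  reported `untestable` and excluded from the correction families; an empty
  background pool or single-class propensity input raises a matching error
  for that pair only.
* The estimator front-end (`TrajectoryDetector`) follows scikit-learn
  conventions (`get_params`/`set_params`/`clone`, fitted attributes with a
  trailing underscore); it is fit-only, like a clusterer.

## Known limitations

* Nearest-neighbour matching is greedy, not optimal; the interface admits a
  strategy plug-in but optimal (network-flow) matching is not implemented.
* The propensity feature set (top-K prior indicators + prior count) is a
  declared, configurable choice; other covariate sets may suit specific
  studies better.
* No hazard-ratio / time-to-event variant; RR with a fixed ascertainment
  window only.
* No trajectory clustering or interactive visualization; graph exports
  (GraphML/DOT) are intended for downstream tools.
* Mortality-completeness and other source-specific reporting biases are out
  of scope and must be handled upstream.
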