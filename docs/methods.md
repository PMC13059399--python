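# Methods

## Problem and counting model

Spontaneous reporting systems collect voluntary post-marketing safety
reports; each report names one or more drugs with role codes (PS primary
suspect, SS secondary suspect, C concomitant, I interacting) and one or
more MedDRA preferred terms (PTs). Disproportionality analysis asks, for a
target drug and an event label, whether the pair is co-reported more often
than the margins predict. All four statistics here operate on the same 2×2
table built from the deduplicated report collection in the study window:

* `a` — reports where the target drug is primary suspect and the label is
  present; `b` — PS reports without the label; `c` — background reports
  (all others, including those naming the drug as SS/C/I) with the label;
  `d` — the remainder. `N = a+b+c+d`, `E = (a+b)(a+c)/N`.

The counting unit is the distinct report: a report contributes at most once
per label and exactly one cell per table, whatever the number of reactions
mapping to that label. Because published screens are ambiguous about the
aggregation unit at SOC level, an alternative `count_unit="event"` counts
each (report, PT) occurrence instead; `report` is the default and what all
headline outputs use.

Event labels come from a PT→SOC surjection plus flat SMQ membership sets
(narrow/broad scope undifferentiated, since screens rarely distinguish
them). At SMQ level a report matching no SMQ is pooled under a reserved
`NA` label; at SOC level a PT absent from the map goes to `unmapped`, which
is excluded from ranked signal tables.

## The four statistics

* **ROR** `= ad/bc` with Wald 95% CI on the log scale. A zero cell triggers
  the Haldane–Anscombe +0.5 correction on all four cells, applied to the
  ROR only and only when needed; PRR, IC and EBGM handle zeros natively.
* **PRR** `= [a/(a+b)]/[c/(c+d)]`, paired with the Pearson χ² of
  independence without continuity correction (a Yates flag exists). The
  uncorrected form matches the χ² magnitudes conventionally reported with
  PRR.
* **BCPNN IC**: the default is the closed-form credibility formula
  `IC = log2((a+½)/(E+½))`,
  `IC025 = IC − 3.3(a+½)^−½ − 2(a+½)^−3/2`. It is deterministic and
  testable against its own large-count limit `log2(a/E)`. The original
  two-layer Beta/Dirichlet-prior normal approximation (`ic_method="bate"`,
  symmetric hyperparameters `α=β=2`, `α1=β1=1`, `γ11=1` with `γ` chosen so
  the prior IC expectation is zero) is provided for comparison; the two
  variants agree in the large-count limit but shrink differently at small
  counts, which is expected.
* **MGPS EBGM**: DuMouchel's gamma-Poisson shrinker. `a ~ Poisson(λE)` with
  prior `λ ~ w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂)` (shape/rate). The prior
  is fitted once per aggregation level on every observed label cell by
  maximizing the negative-binomial marginal likelihood with bounded
  L-BFGS-B from a fixed four-point multistart (the canonical
  (0.2, 0.1, 2.0, 4.0, ⅓) plus dispersed alternatives), on log/logit-
  transformed parameters with box constraints at ±20 (±30 for the weight)
  to keep the line search finite; the fit is deterministic and invariant to
  cell order up to optimizer tolerance. The posterior is the gamma mixture
  `Gamma(αⱼ+a, βⱼ+E)` with weights ∝ mixture likelihood; EBGM is the
  posterior geometric mean `exp(Σ qⱼ(ψ(αⱼ+a) − ln(βⱼ+E)))` — the *geometric*
  mean, per the statistic's definition, not the posterior mean — and EBGM05
  root-finds the mixture CDF at 0.05. The root is bracketed by the
  component 5th percentiles (the mixture CDF is a convex combination of the
  component CDFs) and solved in log space to |CDF−0.05| < 1e-8, which keeps
  relative precision for near-degenerate spike posteriors.

**Signal gate**: a label is flagged iff `a ≥ 3`, ROR lower 95% bound > 1,
`PRR ≥ 2` and `χ² ≥ 4`, `IC025 > 0`, and `EBGM05 > 2` — the standard
published criteria for the four methods, conjunctively, all configurable.
Ranked outputs order labels by IC025 descending with ties broken by case
count then label.

## Numerical caveats

* With `b, c, d` fixed, all four estimates rise with `a` only in the
  background-dominated regime where `E` barely moves; when the margins are
  comparable to `a`, the observed/expected ratio (hence IC and EBGM) need
  not be monotone. Screens of a rare drug against a large background are
  firmly in the monotone regime.
* `EBGM05 ≤ EBGM` is not guaranteed: a degenerate prior fit (e.g. on ~100
  all-null cells the ML prior collapses toward two spikes) can yield a
  bimodal posterior whose minor low-rate mode carries weight just under
  0.05, placing the geometric mean below the 5th percentile by a fraction
  of a percent. The result object logs this as a diagnostic rather than
  failing; gating is unaffected. With ensembles of thousands of cells, as
  in real screens, the fitted prior is smooth and the inversion does not
  occur.
* Fitting the five-parameter prior needs on the order of 100+ cells;
  smaller ensembles produce a warning and possibly spiky priors, which is a
  property of the marginal likelihood, not of the optimizer.

## Synthetic extract

The generator emulates a curated FAERS quarterly extract at desk scale.
Default conditions (chosen once as the standard study conditions for all
tests): 50,000 reports, 25 drugs with the analysis drug primary-suspect on
2% of reports, a 100-PT vocabulary with uniform 1% background rates, a mean
of 2 event draws per report (geometric), >99% unknown sex/age (99.5%/99.7%)
with one dominant reporting country (93.5%) and one dominant indication
(78%), outcome codes mostly absent, 5% of cases duplicated as a version-1
update, quarters uniform over 2018Q1–2024Q3, and a mean of 0.7 extra SS/C
drugs per report.

Per report: a PS drug is drawn from the drug distribution; the event count
`K ≥ 1` is geometric with mean 2; `K` PTs are drawn i.i.d. from the event
distribution conditional on the PS drug — the background with every
signalled event's probability multiplied by its `rr`, renormalized — and
deduplicated into the reaction set. Injecting signals on the renormalized
conditional keeps the oracle closed-form: with `q` the conditional event
probability and `G` the geometric PGF,
`P(event on report | PS drug) = 1 − G(1−q)`, and the expected 2×2 table of
any pair follows by summing over drugs. This exact oracle — not the naive
`rr × background rate`, which ignores renormalization and multi-draw
overlap — is what recovery tests compare against.

What the generator does **not** emulate: drug-name misspellings beyond the
synonym map, time-varying reporting rates, stimulated reporting,
correlations between events or between events and demographics, and
indication–drug coupling. Passing tests therefore demonstrate correctness
of the counting and statistics on clean structured input, and
conservativeness of the gate under independence — not robustness to real
FAERS dirtiness.

## Test and validation sizes

Chosen as the package's standard validation conditions: χ²/ROR oracle
equivalence on 1,000 random tables against generic independence-test and
log-odds routines; EBGM/EBGM05 against 10⁶ posterior draws (1%); prior
recovery from 50,000 simulated cells (20% relative error, allowing
component label switching); large-count limits at `a = 10⁵` (1%); null
calibration over 20 seeded 20,000-report extracts (flagged fraction ≤ 5%;
observed 0%); the Monte-Carlo check of the generator oracle over 200
datasets of 50,000 reports (3 SE). The published burosumab table values
are out of reach by construction — they need the 7.48M-report FAERS
background — so validation rests on the self-contained arithmetic
(percentage columns from printed counts) plus these property suites.

## Design choices

* Deduplication keeps the highest case version, ties broken by latest
  quarter then input order — the FAERS convention that later transmissions
  supersede earlier ones; how any specific curation tool deduplicates is
  not claimed.
* "Unknown" demographics are an explicit category, not missing data,
  because descriptive tables tabulate Unknown as a row.
* Outcome categories are not mutually exclusive (a report can be death +
  hospitalization); "unknown" outcome means no outcome code present, so
  outcome percentages need not sum to 100.
* Percentages are rendered round-half-up to 2 decimals, matching how such
  tables are printed.
* The background for the 2×2 tables is every non-PS report, including
  reports naming the drug in a non-suspect role, mirroring the PS-only
  inclusion rule.
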