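# pvsignal

Disproportionality-based signal detection for spontaneous adverse-event
reports, in the style of FAERS pharmacovigilance screens: given a target
drug (the motivating study screened burosumab, the anti-FGF23 antibody used
in X-linked hypophosphatemia), find adverse events reported with the drug
more often than the reporting background predicts.

The package is aimed at pharmacovigilance analysts and methods researchers.
It covers the whole screening workflow:

* **ingest** FAERS-style quarterly tables (dollar-delimited DEMO / DRUG /
  REAC / OUTC / INDI) or a one-row-per-report CSV; normalize drug names
  through a synonym map (`CRYSVITA` → `burosumab`), deduplicate case
  versions (keep latest), and restrict to a quarter window and a
  primary-suspect (PS) drug;
* **aggregate** reaction terms at MedDRA PT, SOC and SMQ levels;
* **screen** each (drug, event-label) pair with four disproportionality
  statistics on its 2×2 table, and gate signals on all four at once;
* **simulate** FAERS-like extracts with known embedded signals so every
  stage is testable without any database download.

## The statistics

For a 2×2 table — `a` reports with the PS drug and the event, `b` with the
drug only, `c` with the event only, `d` with neither, `N = a+b+c+d`,
`E = (a+b)(a+c)/N` —

| method | estimate | reported bound |
|---|---|---|
| ROR | `ad / bc` | Wald 95% CI, `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` |
| PRR | `[a/(a+b)] / [c/(c+d)]` | Pearson χ² of independence |
| BCPNN | `IC = log2((a+½)/(E+½))` | `IC025 = IC − 3.3(a+½)^−½ − 2(a+½)^−3/2` |
| MGPS | `EBGM = exp E[ln λ | a]` | `EBGM05` = 5th posterior percentile |

The MGPS models `a ~ Poisson(λE)` with a two-component gamma mixture prior
on the relative reporting rate λ, fitted by maximizing the
negative-binomial marginal likelihood over all cells (the DuMouchel
shrinker); the posterior is again a gamma mixture, evaluated with digamma
and root-found quantiles.

A pair is a **signal** when it passes all four default thresholds: `a ≥ 3`,
ROR lower CI > 1, `PRR ≥ 2` with `χ² ≥ 4`, `IC025 > 0`, `EBGM05 > 2` (all
configurable).

## Worked example

Simulate a 50,000-report extract with three embedded rr=20 signals on the
analysis drug, then screen it:

```sh
python analysis/01_simulate.py          # writes scratch/sim/
python analysis/03_signals.py           # writes results/analysis/
```

which prints:

```
screened N=50000 reports, 997 PS for drug000; signals per level: PT: 3/100, SOC: 0/10, SMQ: 0/3
ground-truth events recovered in PT top-10: 3/3 (pt023, pt011, pt007)
  pt023  241  15.43  3.05  9.55  1
  pt011  238  15.21  3.04  9.55  1
  pt007  225  13.86  2.95  9.55  1
  pt049   22   1.11 -0.57  0.65  0
  pt025   19   1.01 -0.76  0.65  0
```

The three embedded drug–event pairs (and nothing else) pass the combined
gate: each has ~230 co-reports, ROR ≈ 15, IC025 ≈ 3 bits and EBGM05 ≈ 9.6,
while the strongest null event sits at IC025 < 0. The columns shown are
label, case reports, ROR, IC025, EBGM05 and the gate verdict;
`results/analysis/` holds the full ranked tables (ranked by IC025
descending) at all three MedDRA levels, plus the Table-1-style descriptive
summaries from `analysis/02_descriptives.py` and the null calibration from
`analysis/04_null_calibration.py` (mean flagged fraction 0.00% over 20
signal-free extracts).

The same screen is available as a CLI for real extracts:

```sh
pvsignal signals --input extract/ --format faers --drug burosumab \
    --synonyms synonyms.tsv --meddra-pt-soc pt_soc.tsv --meddra-smq smq.tsv \
    --from-quarter 2018Q1 --to-quarter 2024Q3 --out results/
```

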