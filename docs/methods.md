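# Methods

## Model and procedure

`pvsignal` performs disproportionality analysis on spontaneous-report
databases. The unit of counting is always the *report*: a report mentioning
three sibling PTs under one HLT contributes once to that HLT's count, and
duplicated reaction rows within a report are ignored. For a drug set D and
an event term t at level L, the 2×2 margins are

- `n_obs` — reports with a drug in D (matching the role filter) and at
  least one reaction whose PT falls under t,
- `n_drug` — reports with a drug in D,
- `n_effect` — reports with at least one reaction under t, any drug,
- `n_total` — all reports.

By default only `role = suspected` drug mentions count as exposure;
concomitant/interacting roles can be included for sensitivity analyses.
The comparator is the full database including the exposed reports
(`background: full`), which is the standard semantics of the expected
count `n_exp = n_drug · n_effect / n_total`. The alternative
`background: other_drugs` instead applies the event rate among unexposed
reports, `n_exp = n_drug · (n_effect − n_obs) / (n_total − n_drug)`, at the
expected-count step; the raw 2×2 counts are unchanged.

### Information Component

`IC = log2((n_obs + 0.5)/(n_exp + 0.5))` is the shrinkage log2
observed-to-expected ratio. The credibility interval treats `n_obs` as
Poisson with mean `r · n_exp` and takes the posterior of the rate ratio as

    r | data ~ Gamma(shape = n_obs + 0.5, rate = n_exp + 0.5)

with `IC025 = log2 q_0.025` and `IC975 = log2 q_0.975`. This gamma-quantile
formulation is consistent with the point estimate above (the posterior mean
of `r` is exactly `(n_obs+0.5)/(n_exp+0.5)`) and is validated in the test
suite against a Monte-Carlo posterior-sampling oracle; a legacy
normal-approximation interval (`IC ± z·sd`, with `sd² = ψ₁(n_obs+0.5)/ln²2`
the exact log-scale posterior variance) is available as
`ic_method: normal_approx` for comparability with older implementations.
The signal rule is strict: `IC025 > 0`, so a bound of exactly 0 is not a
signal.

The interval treats `n_exp` as a known constant — the usual practice, and a
good approximation because `n_exp` aggregates the whole database and its
relative sampling error is negligible next to that of `n_obs`.

### Reporting odds ratio

`ROR = (a·d)/(b·c)` on a report-level 2×2 table with the Woolf (log-normal)
95% CI, `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`. If any cell is zero, 0.5
is added to all four cells (Haldane–Anscombe) and the result is flagged
`continuity_corrected`; the reciprocal identity `ROR(A,B) = 1/ROR(B,A)`
holds exactly only on uncorrected tables. Head-to-head drug comparisons
restrict the table to reports suspected of exactly one of the two drugs;
co-suspected reports are excluded and counted in the scan metadata.

### Staged scan

1. SOC screen at class level (all class drugs pooled, each report once).
2. Drill-down at HLGT and HLT (configurable) for the class and each drug,
   restricted to SOCs whose **class-level** IC025 is positive. Drug-level
   SOC results do not gate the drill-down. PT-level results are computed
   for the configured focus terms rather than exhaustively, unless `PT` is
   added to `levels`.
3. Pairwise RORs over all ordered drug pairs × focus terms.
4. Dose stratification for drugs with a dose rule: *high dose* means daily
   dose strictly over the threshold (so a report at exactly the threshold
   is low dose), reports without a dose are excluded from stratification
   (count recorded), IC is computed within each stratum against the
   configured background, and the high-vs-low ROR uses the low-dose
   stratum as reference. A term whose stratum is empty is skipped with a
   warning rather than failing the stage.

The scan is fully deterministic given dataset and configuration; the config
seed is echoed into the metadata for provenance but no stage draws random
numbers.

## Hierarchy handling

The dictionary is a validated five-level DAG: each LLT has exactly one PT
parent, links above PT may be one-to-many (multi-axiality), SOC terms have
no parents, and every non-SOC term must have at least one parent — which,
with the levels-increase-by-one rule, guarantees acyclicity and that every
term reaches a SOC. Each PT may carry a primary-SOC marker; with
`soc_axis: primary` (default) SOC-level counting assigns each PT to its
primary SOC only, which keeps per-drug SOC denominators a partition of the
reported PTs and avoids double-counting a report across a multi-axial PT's
SOCs. `soc_axis: all` counts a multi-axial PT in every SOC it reaches.
ICSR reactions are stored at PT level; an `llt_code` column is accepted and
mapped losslessly to the unique PT parent on load.

## Synthetic-data generator

The generator emulates the statistical structure that matters for
disproportionality analysis, not clinical realism:

- **Background**: `n_background_reports` (default 200,000) reports, each
  carrying one of 50 interchangeable background drugs as suspected, so the
  `other_drugs` comparator is meaningful.
- **Event counts**: each report draws `K = 1 + Poisson(1.38)` PTs; this
  lambda puts the median of K at 2 with IQR [1, 3], matching large
  spontaneous-report databases.
- **Event identities**: PT draws follow a power-law weight vector over the
  dictionary's PTs (rank-r weight ∝ r^−1), giving the long-tailed term
  frequency profile of real data.
- **Index drugs**: default profiles ship three drugs with distinct,
  realistic demographic/indication/dose mixes (one older, high-fatality
  myeloproliferative-neoplasm population; two ~78%-female rheumatoid-
  arthritis populations with marketed daily doses of 5/10 mg and 2/4 mg).
  These are realistic defaults, not asserted outputs, though `describe()`
  recovers them within sampling error.
- **Planted signals**: for a drug with a planted (term, rate_ratio), the
  weights of all PTs under the term are multiplied by the rate ratio and
  renormalised, optionally only within a dose stratum. Renormalisation
  keeps the per-report event-count distribution invariant, but it means the
  realised observed/expected ratio sits somewhat below the nominal rate
  ratio: the boost is divided by the new normaliser, the planted drug's own
  reports inflate `n_effect`, and report-level deduplication compresses
  multi-draw events. Recovery tests therefore check realised ratios (the
  generator records them in `GroundTruth`) rather than nominal ones; at a
  5,000-report drug in a ~215,000-report database a nominal 4× plant
  realises around 3.2–3.5×.

What the generator does **not** emulate: reporting latency and time trends,
country effects and duplicate reports across centres, drug-name synonymy,
missing-data mechanisms beyond optional missing dose, and correlated
event co-occurrence beyond what shared weights induce. Passing tests
therefore demonstrate that the statistics and the scan logic are correct
and calibrated under independence-with-planted-effects — not that real
databases are free of the confounding, stimulated reporting, or coding
drift that affect observed signals.

## Numerical choices

- `n_expected` is kept real-valued; no rounding anywhere before output.
- Gamma quantiles come from `scipy.stats.gamma.ppf`; vectorised evaluation
  is used for whole-level screens.
- The ROR z-multiplier is the exact normal 97.5% point (1.95996…), not 1.96
  rounded.
- Ties/degenerate inputs: `IC(0, 0) = 0` by the +0.5 terms;
  `ancestors_at_level(x, level(x)) = {x}`; an empty drug margin yields a
  valid all-zero-exposure table; `ror` refuses arms with zero reports.
- Term ordering is deterministic everywhere (sorted codes; scan outputs
  sorted by IC025 descending within scope), so identical inputs produce
  byte-identical result files.

## Problem sizes in tests and the acceptance script

Calibration and recovery checks run on databases of 200,000 background
reports plus 3 × 5,000 index-drug reports over a 27-SOC (729-PT)
dictionary — large enough that a rate-ratio-4 HLT plant realises expected
counts ≥ 20 and the SOC gate operates in its intended regime, while 10–20
seed replicates complete in well under a minute each stage. The ranking and
dose-stratification checks use smaller backgrounds (10,000–20,000 reports)
because RORs compare index-drug arms only and do not involve the
background margin. The Monte-Carlo oracle for the credibility interval uses
10^6 posterior draws per grid point; at the smallest counts the oracle's
own quantile standard error reaches ~0.006 on the log2 scale, so agreement
is asserted to two decimals within 3× that sampling error.

## Known limitations

- No multiple-comparison adjustment across the scan (none is standard for
  IC-based screening; the staged gate is the multiplicity control).
- Only PRR-free statistics are implemented (IC and ROR); PRR and empirical-
  Bayes shrinkage scores are out of scope.
- The signal rule is a screening threshold: a positive IC025 is a
  hypothesis about reporting, not a causal claim about the drug.
- Subgroup analyses by age/sex/indication and latency analyses are not
  implemented.
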