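# Methods

## The scoring model

The model is a near-field, semi-quantitative rating of inhalation exposure
for one *situation* (a job task under stated working conditions). It
assumes the contaminant reaches the worker's breathing zone from a nearby
point source only: far-field/background contributions, dermal uptake, and
ingestion are outside its scope, and a regular 8 h/day, 5 day/week work
pattern is implicit in the duration/frequency scores.

Each of twelve modifying factors takes exactly one classification from a
small ordered set, each classification carrying a dimensionless score.
Eleven factors multiply (position factor; potential emission and handling;
historical exposure; process type with cleaning/inspection/maintenance;
general ventilation and containment; localized control; PPE; health-hazard
category; task duration; task frequency; distance from the source) and the
room-volume factor divides, reflecting dilution in larger workrooms. The
reported score is the natural log of that ratio. Scores per classification
range 1.0–10.0; 1.0 always denotes the factor's no-exposure class. The
score multipliers encode observed exposure ratios (for example, tasks
without LEV run roughly 3× higher than with LEV; no PPE roughly 5× higher
than >90% protection; manual operation roughly 1.7× higher than full
automation), with potential emission classified separately for liquids
(mist/haze generation) and solids (dustiness) over an identical score set.

Two conventions close the gaps the log transform opens:

* **All-no-exposure profiles** report score 1.00 and category 1, although
  ln(1) = 0. This keeps the published band layout (category 1 is exactly
  1.00) while the log product of an all-ones profile is zero.
* **Lower clamp.** Any other profile reports max(ln product, 1.01), so
  every non-trivial situation lands in category ≥ 2. Profiles with a log
  product in (0, 1.01) are rare corner cases (e.g. a single factor barely
  above its no-exposure class); the clamp is flagged on the result, and
  the unclamped `log_score` is always carried alongside. Strict
  monotonicity in the factor scores holds for `log_score`; the clamp
  necessarily flattens the *reported* score below 1.01.

**Banding** rounds the score half-up to 2 decimals (the resolution at
which the bands are published) and assigns by inclusive ranges
1.00 / 1.01–4.76 / 4.77–9.38 / 9.39–14.01. The upper limit equals the
maximum attainable score ln(3·5·5·2·3·3·5·6·3·5·2 / 1) = 14.01, and the
band 2/3 cut points sit at 34% and 67% of it (within 0.01). Scores above
the top limit (plus rounding tolerance) are rejected as inconsistent with
the factor table. A score-maximisation oracle enumerates every attainable
log product by walking the factors and accumulating the deduplicated set
of partial log sums (4330 distinct values for the default table) —
exhaustive over all classification combinations without materialising the
~1.8×10⁸-row cartesian product.

**The table is data.** Factor definitions, classification labels, scores,
aliases and the no-exposure flags live in a versioned YAML config.
Label matching is case-insensitive and whitespace-collapsed, with unicode
dashes, `≤`/`≥` and `³` normalised; aliases absorb the abbreviated
classification phrasings that appear in assessment worksheets (e.g.
"Manual handling with low-level cleaning" for the canonical manual-
handling class). No fuzzy matching: an unmatched label is an error that
lists the valid labels.

## Exposure statistics

Concentrations are 8h-TWA ppm and assumed lognormal within a situation
(the similar-exposure-group convention). All logs are natural.

* GM = exp(mean ln y); GSD = exp(sample SD of ln y) with the **n−1
  denominator**. The convention is a genuine choice — published summary
  tables rarely state theirs — and n−1 is used here because it makes the
  grouped precision identity (below) exact. GSD is reported absent for
  singleton groups.
* 90th percentile: `X_0.90 = GM · GSD^1.282`, with the multiplier kept at
  the conventional 3-figure 1.282 rather than z₀.₉₀ = 1.28155.
* Pooled GM over groups: exp(Σ n_c ln GM_c / Σ n_c).
* OEL exceedance counts values strictly above the limit.

## Agreement statistics

With d_i = ln(estimate_i) − ln(measurement_i):
bias = mean d_i; relative bias = (e^bias − 1)·100%; precision =
√(Σ(d_i − bias)²/(n₀−1)); accuracy = mean |d_i| (MAE); residual limits of
agreement = mean ± 1.96·SD (the Bland–Altman convention; 1.96 chosen
because the 95% limits are conventionally normal-theory). The precision
formula is implemented with the square root so that "bias ± precision"
reads on one log scale.

When only (n, GM, GSD) summaries exist, the situation estimate a_c is
constant within its group, and two identities recover the individual-level
statistics exactly:

* Σ_{i∈c} d_i = n_c (a_c − ln GM_c), so grouped bias is the n-weighted
  mean of a_c − ln GM_c;
* Σ_{i∈c} (d_i − b)² = n_c (a_c − m_c − b)² + (n_c−1)(ln GSD_c)², the
  within term being exact under the n−1 GSD convention.

MAE has no such identity; a folded-normal approximation
E|X|, X ~ N(a_c − m_c, ln²GSD_c) is provided and flagged
`accuracy_is_approximate`. Correlations use the sample Pearson r with the
two-sided t-test p-value (n−2 df); zero-variance input is an error rather
than r = NaN.

## Synthetic individual data

Individual measurements behind published summaries are typically never
released. The simulator draws ln y ~ Normal(ln GM, ln²GSD) per group from
a seeded `numpy` Generator (byte-identical per seed). Its defaults are the
study conditions of the packaged dataset: group sizes 1–20 and GM/GSD as
in the summary fixture when those rows are passed as the spec. The
`exact_moments` mode standardises each group's draws so the *sample*
GM/GSD equal the targets exactly, making the grouped identities
bit-reproducible against simulated individuals. What the simulator does
not emulate: autocorrelation within workers or days,
between/within-worker variance components, censoring at detection limits,
and any deviation from lognormality — so passing tests demonstrate the
statistics' internal consistency, not robustness to those features of
real monitoring data.

## Packaged validation dataset

The fixtures transcribe a styrene exposure study of the FRP
(fiberglass-reinforced plastics) lamination process: 36 situations
(22 lamination, 14 inspection) at 22 Korean companies, 160 personal
samples, with per-situation n/AM/GM/GSD/min–max, an external REACH-model's
daily-average/50th/90th concentration estimates, and the scoring model's
score and category per situation. Checksums are pinned and totals are
recomputed in tests. Three transcription caveats, established while
freezing the tests:

* the published measured-90th column derives from unrounded GM/GSD: the
  closed form applied to the printed 2-dp values agrees to ~0.5% (and to
  half a last printed digit for the sub-0.1 ppm inspection rows), not to
  the last digit;
* the published overall agreement statistics for the external model
  (e.g. 50th-percentile bias −1.00 with precision 2.07) are only partly
  recoverable from the situation-level summaries: the grouped
  reconstruction here gives bias −0.98 but precision 1.46, and no
  estimate-vs-measurement pairing of the printed columns reproduces the
  published precisions, which are internally inconsistent with their own
  subgroup values and evidently rest on unpublished individual-level
  estimates;
* the published subgroup correlations (0.67 lamination, 0.85 inspection)
  likewise do not reproduce from the printed columns (0.645 and 0.776
  here), although the all-situations correlation does (0.935 vs 0.93).

## Numerical choices and limitations

* Half-up decimal rounding for all 2-dp displays and banding (float
  banker's rounding would misplace boundary scores).
* Scoring equals direct formula evaluation to 1e-12; grouped identities
  match individual statistics to 1e-9 on seeded simulations (tested at
  100 datasets).
* Situations lacking a measured 90th percentile (n = 1) carry `None`/NaN
  and are excluded from any statistic needing spread.
* The model yields a *category*, not a concentration; calibrating score
  against measured concentrations (e.g. by mixed-effects regression) is
  out of scope, as are the internals of any external estimation model —
  their outputs are treated purely as input data.
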