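# Methods

This note documents the models and procedures the package implements, the
choices made where the published description leaves the design open, and
what the synthetic data can and cannot show.

## Scoring model

An assessed area supplies one observation per item: binary presence/absence,
an ordinal quality rating on a declared finite scale, or a proportion of
properties in [0, 1]. Scoring proceeds in four steps.

1. **Recoding.** Every observation is mapped to [0, 1] with 0 the most
   desirable state. Binary and proportion items flip (1 − x) when the
   feature's presence is desirable; ordinal levels are mapped to equally
   spaced points before the same orientation rule. Equal spacing is the
   minimal assumption for ordinal scales whose level spacing is unstated.
   Proportion items are reverse-coded (1 − p) when presence is desirable;
   they enter *factor analysis* in their original form but *scoring* in
   recoded form, which follows the instrument's construction sequence.
2. **Item weighting.** The recoded value is multiplied by the item's integer
   Thurstone multiplier (1–4; see below).
3. **Domain aggregation.** Weighted item scores are summed per domain
   (raw range 0 to the sum of member multipliers), then min–max transformed:
   `T_d = (raw − min) / range × χ × w_d`, with χ = 100 / Σ w_d. The
   transformed maxima are therefore 20/20/40/20 and the composite spans
   0–100, higher = less desirable. `raw_min` is fixed at 0 in the shipped
   instrument but kept symbolic so other instruments can reuse the engine.
4. **Missing items** are a hard error by default; an explicit
   `allow_missing="prorate"` policy rescales the observed-item sum to the
   full domain maximum and flags the domain in the output. Prorating is a
   practical extension, not part of the original scoring rule.

Scores are computed and compared at full precision; output files round to
two decimals for presentation only.

### The default weight table

The published per-item multipliers are not publicly deposited. The shipped
default table is **reconstructed**: plausible integers in 1–4 constrained so
each domain's multiplier sum equals the published raw maxima (9, 10, 13,
14). All multipliers are overridable in the YAML config, and the weighting
pipeline can regenerate a table from any importance survey.

## Thurstone item weighting

Respondents judge each candidate feature by valence (good/bad) and magnitude
(five ordered categories). The pair maps onto a 9-point favourability scale
with "not at all" at the midpoint 5. The raw item weight is the median of
the item's 9-point distribution; the signed weight subtracts 5; the
multiplier is |signed weight| clamped to [1, 4].

Open points resolved here:

* **Even-count medians** that straddle two scale points round toward the
  midpoint (an equidistant pair resolves to 5). Weights must be integers in
  −4…+4; rounding toward the midpoint is the conservative choice that never
  inflates a multiplier.
* **"No clear consensus"** is operationalised as: fewer than 70% of
  non-midpoint responses share one valence (threshold configurable). The
  original rule is qualitative; this is a reproducible rendering of it.
* A **signed weight of 0** excludes the item: no integer multiplier in 1–4
  can represent indifference.
* Respondents who skip an item, or give a magnitude without a valence, are
  dropped for that item only (logged), not listwise across items.
* Item ranking (for pilot selection) uses the mean magnitude score;
  ties break lexicographically by item id so ordering is deterministic.

## Development pipeline

**Screening.** Each pilot item is paired 1:1 with a validation-survey
question; each respondent contributes one pair (their area's item value,
their answer). The Kendall τ-b screen retains items at p < .05, plus any in
the expert-override list; a collapsing map then merges related retained
items (combined by their mean). The exact item↔question pairing of the
original study is not public, so the pairing is an explicit argument.

**Factor analysis.** Extraction is principal axis factoring on Pearson
correlations (polychoric correlation is deliberately not used: the items mix
binary, ordinal and continuous kinds, and the simplest reading of the
original analysis is product-moment). Communalities start at squared
multiple correlations and iterate to a tolerance of 1e-4 (the field-standard
stopping rule; stricter tolerances add iterations without changing loadings
at reported precision), with mild damping to guard against oscillation when
over-extracting. Rotation is oblique Geomin (ε = 0.01) by the
gradient-projection algorithm from the identity start plus ten seeded random
orthonormal starts, keeping the lowest criterion value; factors are ordered
by sum of squared loadings and sign-aligned on their dominant item.

**Fit indices.** The discrepancy of a PAF solution has no likelihood, so a
parallel maximum-likelihood factor model (profile minimisation over
uniquenesses, the same objective as R's `factanal`, against which it is
tested) is fitted at each candidate dimensionality purely for χ²
(Bartlett-corrected), CFI, TLI and RMSEA. Reported loadings always come from
PAF + Geomin. TLI may exceed 1 in small samples and is reported as computed.

**Refinement.** Stage 1 fits the full item set at every candidate factor
count; the count is selected among candidates whose every factor holds at
least two salient (|loading| ≥ 0.4) items — the interpretability guard that
rejects a five-factor solution whose extra factor comprises a single item —
preferring adequate fit (RMSEA ≤ 0.08 and CFI ≥ 0.95), then agreement with
the eigenvalue ≥ 1 count, then parsimony. Stage 2 deletes one item per
re-estimation — the item with the smallest maximum absolute loading,
whenever that value is below 0.4, ties broken by item id — until a fixed
point. Candidates whose extraction fails to converge are recorded and
skipped. EFA uses complete cases only.

## Validation statistics

* **Item–domain consistency**: Spearman correlation of each weighted item
  score with its domain total, pass at ≥ 0.2. The item is *included* in the
  total by default (the scale-domain-total convention); the stricter
  item-rest variant is a flag. Constant items are reported as failures with
  a reason rather than raised.
* **Aesthetic attachment**: the sum of the scenery, space and peacefulness
  importance items, min–max transformed to 0–100 (higher = more attached).
  The anchoring of the original transformed sum is unstated; 0–100 min–max
  is this package's stated convention.
* **Convergent validity**: Spearman correlations of domain scores with the
  four perception items and attachment at the individual level (each
  respondent paired with their area's scores) and with the deprivation index
  at area level. Significance is two-sided at 0.05 with no multiplicity
  correction, mirroring the original presentation; a Benjamini–Hochberg
  option exists in statsmodels for users who want it.
* **Utility**: one-way ANOVA per domain across deprivation quintiles or
  settlement types, with Tukey HSD pairwise tests aggregated into
  homogeneous subsets (maximal runs of mean-sorted groups with no
  significant internal pair — the SPSS-style display).
* **Inter-rater reliability**: Krippendorff's α via the coincidence-matrix
  formulation, difference metric chosen by item kind (nominal for binary,
  ordinal for ordinal, interval for proportions), pass at ≥ 0.8. α is
  mathematically negative under systematic disagreement and is reported as
  computed. All-identical ratings give α = 1 with a degenerate-data note.
  Bootstrap confidence intervals are omitted (point values suffice for the
  pass/fail criterion).

## Synthetic data generator

The generator emulates the study design: 405 postcode areas (40/20/40%
city / town-fringe / village mix), a 545-respondent weighting survey, a
606-return resident survey of which 500 survive the age-65 and
area-linkage eligibility rules, and a ten-area two-rater reliability subset.

* **Areas.** Four latent domain factors (pairwise correlation 0.2 — a
  conventional oblique default; the true inter-factor correlations are not
  printed) with settlement-type mean shifts, item values = signed loading ×
  factor + unique noise, discretised per item kind (median split for binary,
  roughly uniform quantile cuts for ordinal, clamped affine map for
  proportions). Latent loadings are disattenuated by the closed-form
  categorisation factor so loadings recovered from the *observed* items
  match the configured (published) pattern; uniqueness defaults to
  1 − loading² and is overridable per item.
* **Deprivation** is a linear blend of the realised standardised domain
  scores calibrated to signed target correlations (+, +, −, + by default,
  magnitudes 0.22/0.25/−0.17/0.67), plus independent noise; infeasible
  target vectors (implied R² ≥ 1) raise a config error. Quintiles are
  rank-based, 5 = most deprived.
* **Weighting survey**: 9-point ratings are the planted weight's scale
  position plus rounded Gaussian dispersion (SD 1.0, at which the median
  recovers the planted weight essentially always at n = 545); designated
  no-consensus items are drawn bimodally.
* **Residents**: ages are truncated-normal (mean 74.07, SD 7.79, minimum
  65); perception items discretise affine functions of the respondent's
  area's standardised domain scores with unit individual noise; ineligible
  returns (missing/unknown area, under-65, missing age) are appended in the
  study's proportions. The published exclusion counts are internally
  inconsistent (606 − 500 eligible = 106, but the itemised exclusions sum to
  116); the generator follows the 500-of-606 split.
* **Second rater** copies sheets with per-item disagreement at a configured
  rate (default 5%): binary flips, ±1 ordinal jitter, clamped Gaussian
  jitter for proportions.

All draws flow from one seeded `numpy` Generator passed explicitly; the same
seed reproduces a bundle byte-for-byte.

**What passing tests show — and don't.** The generator plants exactly the
structure the pipeline assumes: simple-structure loadings, monotone
couplings, honest raters, no spatial autocorrelation, no systematic
non-response. Recovery on this data demonstrates the *software* is correct
(estimators recover planted truth at the study's sample sizes), not that the
instrument would behave identically on field data, where cross-loadings,
polytomous rater drift and geography are real.

## Problem sizes in tests

The test suite exercises the full study design (405 areas, 545 + 606
respondents) for single-bundle checks and 20 seeds for Monte-Carlo recovery
claims; the screening type-I check uses 300 independent items at 120 areas.
These sizes keep the whole suite under a minute on one core while leaving
the Monte-Carlo assertions comfortably powered.

## Known limitations

* The default multipliers and the item↔validation-question pairing are
  reconstructions; users replicating the published tool should substitute
  the licensed originals.
* Confirmatory factor analysis is out of scope by design (the instrument's
  authors defer it to future samples).
* Pearson-based EFA on mixed binary/ordinal items attenuates loadings; a
  polychoric option would strengthen small-loading items but is not
  implemented.
* The Tukey homogeneous-subset display is the greedy SPSS-style
  presentation, not a partition with simultaneous coverage guarantees.
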