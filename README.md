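# operat

A Python implementation of the **Older People's External Residential
Assessment Tool (OPERAT)**: a 16-item observational audit that scores how
suitable an external residential environment is for older people, together
with the full psychometric pipeline used to construct and validate such an
instrument.

## Who this is for

Researchers in environmental gerontology and public health who want to
(a) score neighbourhood walk-through audit sheets with the published OPERAT
weighting scheme, or (b) rebuild or adapt the instrument for new settings —
deriving item weights from an importance survey, screening items against
resident perceptions, finding the factor structure, and checking internal
consistency, convergent validity, utility and inter-rater reliability.

## The instrument and its arithmetic

OPERAT groups 16 observed items (presence/absence, ordinal quality ratings
and proportion-of-properties counts) into four domains:

| Domain | Items | Raw max | EAG weight | Transformed max |
|---|---|---|---|---|
| Natural Elements | 3 | 9 | 1 | 20 |
| Incivilities and Nuisance | 3 | 10 | 1 | 20 |
| Navigation and Mobility | 5 | 13 | 2 | 40 |
| Territorial Functioning | 5 | 14 | 1 | 20 |

Each observation is recoded onto a 0 = most desirable / 1 = least desirable
scale and multiplied by an integer item weight *m* ∈ {1,…,4} derived from an
older-people importance survey by Thurstone scaling (the median of a 9-point
favourability scale, minus its midpoint). Item scores are summed to a raw
domain score and min–max transformed onto a common footing weighted by the
Expert Advisory Group (EAG) domain weights *w_d*:

```
χ = 100 / Σ_d w_d                      (= 100 / (1+1+2+1) = 20)
T_d = (raw_d − min_d) / range_d × χ × w_d
OPERAT total = Σ_d T_d  ∈ [0, 100]     (higher = less desirable)
```

The development pipeline mirrors how the instrument was built: Kendall
τ-b screening of pilot items against resident validation surveys (p < .05,
with expert overrides and item collapsing), principal-axis factoring with
oblique Geomin rotation, iterative deletion of items loading below 0.4 (one
per re-estimation), factor-count selection by the eigenvalue ≥ 1 rule plus
ML fit indices (χ², CFI, TLI, RMSEA) with an interpretability guard, and
validation statistics: item–domain Spearman correlations (≥ 0.2),
convergent-validity correlations, one-way ANOVA with Tukey HSD homogeneous
subsets across deprivation quintiles and settlement types, and
Krippendorff's α (≥ 0.8) for two-rater reliability.

Because the field data are not publicly deposited, the package ships a
synthetic-data module that emulates all four data streams (assessments with
deprivation/settlement covariates, the weighting survey, the resident
validation survey, a second-rater copy) from the published four-factor
loading pattern, with planted ground truth for recovery testing.

## Worked example

```bash
operat simulate --outdir data --seed 42 --n-areas 60
operat score --input data/assessments.csv --output scores.csv --summary summary.csv
operat weights --survey data/weighting.csv --output weights.json
operat develop --assessments data/assessments.csv --factors 1..5 --report model.json
```

which prints:

```
wrote synthetic bundle (60 areas, seed 42) -> data
scored 60 areas -> scores.csv
weighted 16 items (0 excluded) -> weights.json
selected 4-factor model, 16 items (RMSEA 0.051) -> model.json
```

`scores.csv` holds one row per area with the four raw domain scores, the
four transformed domain scores and the 0–100 total; `summary.csv` mirrors
the instrument's summary presentation (max possible raw/transformed,
observed range, mean, median, SD). `weights.json` reports, per item, the
9-point distribution's median, the signed weight (−4…+4), the scoring
multiplier, and the valence-consensus flag (items with no clear consensus or
a zero weight are excluded). `model.json` contains the fit grid, the Geomin
pattern matrix (sub-0.4 loadings blanked in the display copy) and the
deletion history.

The same functionality is available as a library:

```python
from operat import load_default_instrument, score_area
from operat.synthetic import SimulationConfig, simulate_bundle

spec = load_default_instrument()        # 16 items, chi = 20
bundle = simulate_bundle(SimulationConfig(seed=42))
report = score_area(spec, bundle.assessments[0])
print(round(report.total, 2))           # 50.33
```

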