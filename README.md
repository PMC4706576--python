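# cc-centile

Centile-width morphometry of the corpus callosum (CC) for group studies
of focal white-matter volume loss — in particular the thinning of the
genu and mid–posterior callosal body seen in children after acute
profound hypoxic–ischaemic brain injury, where the commissural fibres
of the paracentral lobules cross the midline.

The package implements the full analysis chain that such a study needs,
for anyone with mid-sagittal binary CC masks (or width tables):

1. **Geometry** — trace the CC outline on a mid-sagittal binary mask,
   locate the rostral and splenial tips from the shape skeleton, and
   divide the shape into 100 radial segments by 99 percentile slices
   placed at equal arc-length fractions of an iteratively refitted
   centreline (the Denenberg centile technique).  Each slice's length is
   one *centile width* `w_1 … w_99` (mm); the chain also reports area,
   perimeter and centreline length.
2. **Regionalization** — correlation-matrix PCA of the subjects × 99
   width matrix, retention of every component explaining > 1% of total
   variance, varimax rotation, assignment of each centile to the factor
   with the largest |loading| (contiguous anatomical regions emerge),
   and regression-method factor scores (mean zero per factor).
3. **Group statistics** — Shapiro–Wilk screen, paired *t* of the global
   measures, per-centile comparisons with 95% CIs and Bonferroni
   control at *m* = 99, and one-way ANOVA of the factor scores
   (*F* = MS_between / MS_within, α = 0.05).
4. **Classification** — soft-margin linear SVM (K(x, y) = ⟨x, y⟩,
   C = 1) on the 99 widths with stratified 10-fold cross-validation,
   per-fold feature standardization, and the full metric suite:
   confusion matrix, accuracy/error, sensitivity/specificity, per-class
   precision/recall/F-measure, ROC curves and trapezoid AUC.
5. **Synthetic cohorts** — a generator of age-matched case/control
   cohorts (13 vs 13 by default) whose width profiles carry a global
   size factor, smooth regional covariance, per-centile noise, and a
   focal thinning effect in the genu (centiles 8–15) and mid-posterior
   body (centiles 61–70) peaking at 1.47 mm at centile 63.  It can also
   render any width profile as a rasterized arched mask, closing the
   loop for end-to-end testing of the geometry.

## Worked example

```sh
cc-centile run-all --seed 3 --out out/
```

simulates a default cohort, regionalizes it, runs the statistics and
classifies it.  On this seed it prints:

```
wrote out/cohort.csv (26 subjects x 99 widths)
retained 6 factors (end-taper: [2]); runs: {2: [(1, 5), (95, 99)],
  4: [(6, 18), (57, 61), (68, 84)], 3: [(19, 33)], 1: [(34, 56)],
  6: [(62, 67)], 5: [(85, 94)]}
significant anatomical regions at alpha=0.05: [3, 6]
CV accuracy 0.885, AUC {'case': 0.964, 'control': 0.964}
```

Reading: on this 26-subject replicate PCA retained six components above
the 1% line (the count fluctuates around seven at this n; at 200
subjects it is stably seven); the rotated factor claiming the profile's
extreme ends (the tapering-shape factor, here factor 2) was flagged and
excluded from the group comparison; factor 6 — the contiguous run over
centiles 62–67, inside the induced mid-posterior-body thinning — is
among the significant regions (which regions clear α varies from cohort
to cohort at n = 13 + 13, the mid-posterior body factor being the most
frequent, see `docs/methods.md`); and the linear SVM separated cases
from controls with 88.5% cross-validated accuracy and AUC 0.96.  The
per-centile
table (`out/centile_comparison.csv`) shows the largest mean difference
near centile 63 with no centile surviving Bonferroni correction —
the regional factors and the multivariate classifier detect what the
mass-univariate test cannot.

The same stages run individually (`simulate`, `extract`, `regions`,
`stats`, `classify`), and the library API mirrors them
(`extract_width_profile`, `regionalize`, `centile_comparison`,
`anova_factor_scores`, `classify_cohort`, `generate_cohort`,
`render_mask`).

Masks are accepted as PNG (non-zero = foreground, spacing given
explicitly) or single-slice NIfTI (spacing from the header); tables are
plain CSV with columns `subject_id, group, age, w01..w99`.

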