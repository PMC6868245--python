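# Methods

`phenobreed` implements a phenomics-assisted, prescriptive plant-breeding
analysis for multi-environment soybean trials: from plot-level records with
stage-wise sensor traits, through mixed-model quality control and genetic
summaries, to random-forest yield prediction, feature selection, and
genotype-by-management (G×M) fit classification. Because raw field data of
this kind are rarely shareable, the package is driven by a synthetic trial
generator that is itself a first-class, tested component.

## The synthetic trial

Two studies are emulated with 32 genotypes in randomized complete blocks of
three replications: a row-spacing study (38 vs 76 cm, five environments) and
a seeding-density study (low/medium/high, four environments), for
32·2·5·3 + 32·3·4·3 = 2112 plot records. Seed yield follows

    y_ijkl = μ + l_i + g_j + gl_ij + t_k + gt_jk + r_l(i) + ε_ijkl

with all random terms i.i.d. Gaussian. Default components (kg²/ha²) are
σ²_g = 40 000, σ²_l = 90 000, σ²_gl = 10 000, σ²_t = 2 500, σ²_gt = 900,
σ²_r = 2 500, σ²_ε = 90 000 around a grand mean of 3 500 kg/ha. These were
chosen once so that seed-yield entry-mean heritability lands in the
0.78–0.96 range typical of well-run soybean trials and the spread of the fit
deviation D_g (below) is near 100–200 kg/ha; they are not tuned thereafter.
Yields are floored at zero; with the defaults the floor is ~5 SD away and
never binds.

**Latent drivers.** Traits are not drawn independently of yield. Each plot
carries three latent physiological drivers per growth stage — chlorophyll
status, water status, canopy size — each split into a genotype component
(share 0.6) and plot noise (share 0.8, unit total variance). Drivers feed
yield through stage- and treatment-conditional weights (chlorophyll at seed
fill is the strongest; canopy size pays off more under wide rows and low
density) and feed the 22 traits × 3 stages through per-trait loadings. SPAD
is the cleanest chlorophyll proxy (loading-to-noise 4:1), which makes
SPAD_S3 the planted strongest predictor of yield; MTA, VI_WBI and VI_CRI
carry zero loadings and are planted pure-noise predictors. This is the
minimal structure under which variable importance is real, ranked, and
treatment-conditional — the properties the downstream machinery must
recover.

**Planted fit classes.** A fraction (default 5/32) of genotypes receives a
systematic G×M shift, mediated through the canopy driver under the first
level of the study's contrast pair (38 cm; medium density) so that the shift
is visible in the traits as well as in yield. The shift magnitude is
`gxm_shift_sd` × SD(D_g) where SD(D_g) is the *post-shift* dispersion of the
fit deviation, solved self-consistently (δ² = k²·v₀ / (1 − k²f(1−f)) with v₀
the analytic null variance and f the shifted fraction). Sizing against the
post-shift SD keeps "a k-SD outlier" meaningful relative to the ±1 SD class
boundary, which the shifted genotypes themselves inflate; sizing against the
null SD would cap 2-SD recovery near 70% no matter how clean the data.

**Injections.** Missingness masks exactly `round(rate · n_trait_cells)`
predictor cells uniformly at random (never yield); outliers shift cells by
±`shift_sd` within-cell residual SDs. Both record their positions in a
ground-truth sidecar, and both draw from dedicated random substreams so that
changing one rate never perturbs any other draw.

**What the generator does not emulate:** spatial field trend, sensor
physics, non-Gaussian trait error, genotype-by-year structure, or
correlated (non-MCAR) missingness. Passing tests therefore demonstrate that
the estimators and selection machinery recover planted truth under the
model's own assumptions — not that they are robust to field pathologies
outside them.

## Mixed-model layer

All estimators use balanced-design closed forms, which coincide with REML on
balanced data and are exactly testable against independent algebra:

- **Screening model.** The full fixed-effects RCB model is solved by least
  squares under sum-to-zero coding (the design matrix is solved directly, so
  near-balance from per-trait missing cells is handled exactly).
  Replication-within-location is estimated unshrunk when forming residuals —
  this keeps residuals summing to zero within every environment × replication
  cell — while its variance component is still reported by method of moments.
- **Outlier rule.** Internally studentized residuals e/(s√(1−h)) with h the
  observation leverage from the QR factorization; |t| > 3 flags the cell.
  One pass per trait: flag, remove, and the caller refits. Whether removal
  should be per-cell or listwise is a judgment call; the package removes
  single cells to preserve the rest of the plot record.
- **Variance components.** Per management system, the genotype × location
  layout with replications in locations is decomposed by expected mean
  squares; negative method-of-moments solutions truncate to zero and are
  flagged. Unbalanced layouts are rejected with an explicit error rather
  than silently approximated.
- **Heritability.** Entry-mean H² = σ²_g / (σ²_g + σ²_gl/r + σ²_ε/(rl)) in
  the default convention, which divides the G×E term by the number of
  replications r; the `standard` convention divides by the number of
  environments l instead. Both are exposed because the two conventions
  circulate in the applied literature and differ whenever r ≠ l.
- **BLUPs.** Per management-treatment × location trial, y = μ + r + g + ε
  with genotype random; the balanced closed form shrinks genotype mean
  deviations by λ = σ̂²_g/(σ̂²_g + σ̂²_ε/r). Groups whose σ̂²_g truncates to
  zero shrink fully to the trial mean.

## Imputation

Missing predictor cells are imputed with an iterative random-forest scheme:
mean-initialize, sweep columns in ascending missingness, fit a
100-tree regression forest (p/3 split candidates, minimum leaf 5) of all
other columns on the rows where the target is observed, predict its missing
rows, and stop at the first increase of the normalized change
Δ = Σ(new−old)²/Σnew², rolling back one sweep. All 66 predictors are
continuous, so no categorical branch is implemented. Observed cells are
returned bit-identical.

## Yield models, importance, and RFE

Forests are bagging ensembles of depth-unlimited regression trees with
per-node feature subsampling (default mtry = p/3, minimum leaf 5, 300 trees
— tree count chosen for single-CPU turnaround; results are insensitive
beyond ~200 trees). In-bag indices are tracked per tree, so out-of-bag
(OOB) error and tree-wise permutation importance need no extra data: for
each tree and predictor, the predictor is permuted among that tree's OOB
rows and the OOB MSE increase recorded; raw importance is the mean increase
over trees, scaled importance maps onto [0, 100] with the top predictor at
100 (negative raws floor at 0; rank ties break by column order).

Training repeats a fresh 80/20 split ten times; when tuning is enabled the
split-candidate count is chosen per repeat by 10-fold cross-validated RMSE
over {p/3, √p, 2p/3}. R² is 1 − SS_res/SS_tot on the evaluation set, never a
squared correlation. All split, fold, bootstrap and permutation streams
derive from one master seed.

**Genotype-effect design matrix.** Models are trained on BLUP *deviations*:
response and predictors are centered within each management × location trial
before scaling, i.e. the predicted random genotype effects rather than
trial means plus effects. This is deliberate. Environment main effects
cannot legitimately be predicted from genotype phenotypes, and leaving them
in the response lets any column that differs between trials — including a
pure-noise trait shrunk to a constant per trial — act as a location
fingerprint and collect spurious importance. Centering removes the channel;
planted importance ordering is unchanged and planted noise traits fall to
~0 as they should. A trait with zero dispersion after centering is kept as
an all-zero column with a warning rather than dropped, so subset sizes stay
comparable.

**RFE.** Backward elimination on the importance ranking: per repeat, rank on
the training split, retrain on the top-k for a size grid
{1..10, 12, 15, 20, 25, 30, 40, 50, p}, and score by OOB RMSE. The optimal
size minimizes mean OOB RMSE; the tolerance size is the smallest within 5%
of that minimum; the consensus subset collects predictors present in the
optimal subset of at least half the repeats. The final tolerance subset
takes the top predictors by mean rank and is re-evaluated against the full
model on held-out data.

## Prescriptive tier

The fit deviation D_g is the genotype's seed-yield BLUP difference between
the two contrast levels (38−76 cm; medium−low density), averaged over
locations. Classes partition genotypes at μ_g ± 1 sample SD: above the band
adapted to the first level, below to the second, inside (boundaries
included) universal. Classification is invariant to adding a constant to
all BLUPs and equivariant under contrast reversal (D_g negates, adapted
labels swap).

Selection decisions at a 20% intensity are scored with a confusion matrix
(selected = top-k by predicted yield, positive = top-k by observed; ties at
the boundary break by stable input order, logged), from which sensitivity,
specificity, precision, balanced accuracy and selection accuracy follow;
undefined ratios return as missing with a warning.

The fit classifier is a 200-tree random forest on the RFE-selected trait
subset, with two guards against leakage: splits are stratified at the
*genotype* level (all rows of a genotype stay on one side — with 32
genotypes an 80/20 split leaves ~6 unseen test genotypes, so metrics are
averaged over repeats and reported with Monte-Carlo SDs), and minority-class
upsampling is applied inside the training split only (upsampling before the
split would duplicate rows across the boundary). Training-source comparison
re-runs the classifier on rows from each single treatment level and on the
pooled data, holding the class labels fixed.

## Numerical and degenerate-input conventions

- Zero residual SD (perfect fit) flags no outliers; thresholds at +∞ flag
  none by construction.
- All-zero variance components make H² undefined and raise.
- Zero dispersion of D_g puts every genotype in the universal class.
- Division by zero in a vegetation-index ratio returns a missing marker with
  a warning; the iPAR fraction clips to [0, 1] and warns when below-canopy
  light exceeds the above-canopy reference.
- The printed form of the light-interception equation in some field
  protocols inverts the ratio; this package computes 1 − P_below/P_above,
  the form consistent with "fraction intercepted".

## Problem sizes used in the test suite

Monte-Carlo checks use 500 simulated trials for variance-component and
heritability recovery, 50 seeds for RFE support recovery and fit-class
power/calibration, 100 masked replicates for the imputation benefit, and
1000 random fixtures for the confusion-metric oracle. Forest sizes in these
loops (25–200 trees) and the 120–150-row fixtures were chosen as the
smallest sizes at which the statistics stabilize; the estimators themselves
are size-agnostic. The end-to-end determinism check runs the full pipeline
twice at reduced forest sizes and compares output files byte for byte.

## Known limitations

- Balanced-design closed forms only; unbalanced layouts are rejected, not
  approximated. Imputation (or cell removal plus refit) is the supported
  route back to balance.
- Single imputation: no uncertainty propagation from imputed cells.
- The vegetation-index registry ships canonical literature formulas for the
  named indices; instrument-specific variants must be registered by the
  user.
- No spatial adjustment, no repeated-measures covariance, no significance
  tests of fixed effects — the package reports estimates, not p-values.
- With 32 genotypes, fit-class cohorts are small (~5); per-class classifier
  metrics are accordingly noisy and should be read with their Monte-Carlo
  SDs.
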