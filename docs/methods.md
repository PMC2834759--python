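# Methods

This note documents the statistical procedures implemented in `hypoxmet`,
the choices made where the design was genuinely open, and what the synthetic
cohort generator does and does not emulate.

## Data model

Concentrations are wide samples × analytes tables (µM) with an explicit
missingness mask. A literal 0 is a valid, observed concentration; only
empty/sentinel cells are missing. This keeps "quantified as zero" distinct
from "not detected", which is what the detection filter needs. Units never
enter any statistic: everything downstream operates on logs or on
concentration ratios.

Every sample belongs to one animal at one of three timepoints (SA = start of
hypoxia, EA = end of hypoxia, ER = end of reoxygenation); animals belong to
one of four groups (21% O₂, 100% O₂ × 15 min, 100% O₂ × 60 min, sham
control). Controls have hypoxia duration 0 by invariant.

## Preprocessing

* **Detection filter.** An analyte is retained when observed in ≥ 15% of all
  samples (inclusive threshold, literal reading of "at least"). The filter is
  idempotent and reports what it drops.
* **Features.** The feature matrix holds log-scale values of (i) retained
  analytes, (ii) 28 curated sums/ratios (BCAA, aromatic and total amino
  acids, Fischer ratio, Ala/BCAA, Gly/BCAA, acylcarnitine ratios, Krebs
  sum, …), and (iii) automatically enumerated pairwise analyte/analyte
  ratios within the classes relevant to the duration model (acylcarnitines,
  amino acids, biogenic amines, energy metabolism). Pairwise ratios are
  unordered (A/B only): log(B/A) = −log(A/B) carries identical information.
  Enumeration is lexicographic and capped (default 5000) so feature order is
  deterministic. A ratio is missing when either endpoint is missing or the
  denominator is zero; a sum is missing when any member is.
* **BCAA membership** defaults to {Val, Leu, Ile} and is configurable,
  because targeted panels differ in whether Leu/Ile are resolved or combined.
* **Log bases.** Natural log internally (the base cancels in every test
  statistic); log₂ for the heat-map, because the display clips at ±3 ≈
  8-fold, an anchor only consistent with base 2; base 10 remains available.
* **Imputation.** Local least squares: for each feature with missing values,
  rank the other features by |Pearson r| on pairwise-complete samples
  (computed once, on the pre-imputation matrix — the method is single-pass,
  not iterative), regress the target on the top k = 6 plus an intercept over
  samples where all are observed, and fill missing cells with predictions.
  Fallback to the observed mean when fewer than k + 2 supporting samples
  exist or a predictor is unavailable in the row being filled. Observed
  values are never altered. Imputation feeds the multivariate stage only;
  univariate statistics run on unimputed data, and the curated ratios are
  recomputed from imputed analyte concentrations rather than imputed
  directly.
* **Changes.** Per-animal log differences between interval endpoints
  (EA/SA for hypoxia, ER/EA for reoxygenation); an entry exists only when
  both endpoints are observed.

## Univariate statistics

The tested response is the per-animal log change over an interval. The group
contrast is a cell-means model with group-specific residual variances; for
two groups its REML solution coincides with Welch's unequal-variance t with
Satterthwaite df, which is what is computed (vectorized); for more than two
groups all pairwise Welch contrasts plus a Welch omnibus ANOVA F are
returned. Features with fewer than two observations in any group are flagged
untestable and excluded from multiplicity correction. BH q-values are
computed within each contrast family separately (hypoxia effect,
reoxygenation effect, between-protocol differences), matching the reporting
of separate significant-feature counts per analysis.

Fold changes are medians over animals of the original-scale concentration
ratio between timepoints, reported in percent (ratio × 100), with a sign
flag encoding whether the treated median change exceeds the control one —
the sign convention is presentational, so it is kept separate from the
magnitude.

Duration regressions are OLS of a feature's EA log level (default;
configurable to the EA/SA change) on minutes of hypoxia, reporting slope,
R², adjusted R² (= 1 − (1 − R²)(n−1)/(n−2)) and the two-sided slope p.
Cohort-balance checks use one-way ANOVA plus Tukey HSD on numeric
covariates, as a guard against design bias.

## Duration model (PLS1)

NIPALS PLS1 on mean-centered, unit-variance-scaled X and y (ddof = 1).
Numerical conventions: weight vectors unit-norm; components truncated when
‖X'y‖ or t't falls below 1e−12 (rank exhaustion); zero-variance features
dropped with a warning; requested components capped at min(n−1, p). With A =
rank(X) the fitted values coincide with OLS — this is asserted against a
normal-equations oracle in the tests, as is agreement with an independent
PLS implementation.

* **Component count**: leave-one-out CV, choosing the A that minimizes LOO
  RMSE, ties to the smaller A. Note that with a strict minimum rule extra
  components often genuinely reduce LOO error (they de-noise the first
  weight vector), so selected A > 1 on single-signal data is expected
  behavior, not overfitting.
* **Q²/RMSE**: seeded 10-fold CV, fold sizes differing by ≤ 1, with
  centering/scaling refit inside each training fold — the no-leakage
  property is tested (permuted y rarely reaches Q² > 0.3).
  Q² = 1 − PRESS/TSS; RMSE is in minutes on the original y scale.
* **Permutation p**: the add-one-smoothed fraction of y-permutations whose
  CV RMSE is ≤ the observed one, (1 + #better)/(n_perm + 1). The verbal
  definition "proportion of models with higher RMSE" would assign p ≈ 1 to a
  good model; the implemented direction is the standard one. Default
  n_perm = 5000; the component count stays fixed across permutations
  (a flag re-runs LOO selection inside each permutation for the stricter
  reading).
* **VIP**: per-feature importance weighted by each component's explained
  y-variance, VIP_j = sqrt(p Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a) with
  SS_a = q_a² t_a't_a; mean(VIP²) = 1 is asserted to
  1e−8 on every fit. Model reduction keeps features with VIP strictly > 1
  (so an all-tied VIP = 1 panel selects nothing, by design) and refits with
  re-selected A. VIP stability is reported as the median and 10%/90%
  quantiles of per-training-fold VIPs; an alternative parameterization
  (30 random 90% resamples, 20%/80% quantiles) is exposed because both
  conventions are in circulation.

## Heat-map layout

Columns are per-animal, per-interval change profiles; each row is centered
on the mean change of the sham controls for the matching interval, so zero
means "changed like a control". Columns are ordered by complete-linkage
agglomeration on Euclidean distance (metric configurable; leaf order is the
deterministic recursive traversal of the merge tree); rows by k-means with
k = 5, seeded, 10 restarts, best within-cluster sum of squares kept, ordered
cluster-by-cluster and within clusters by distance to centroid. The display
copy is clipped to ±3 log₂ units; the unclipped matrix is retained. The
features shown are those significant at q < 0.01 in the hypoxia or
reoxygenation family (padded with the top hypoxia features if too few pass).
Rendering to an image is out of scope; the layout (matrices, orders,
dendrogram, clusters) is the product.

## Synthetic cohorts

The generator's defaults are the study conditions: group sizes 8/8/11
treated + 6 controls; per-animal hypoxia duration ~ N(69, 24) minutes
truncated at zero (resampled until positive — positivity is physical);
three samples per animal. All planted effects are multiplicative on
concentrations (additive on logs), since every downstream statistic runs on
logs or median ratios:

* baselines are log-normal with class-typical medians (amino acids
  ~150 µM, oxysterols ~0.1 µM, …), per-analyte spread 1.0 (log scale),
  between-animal spread 0.25, per-timepoint noise 0.2;
* hypoxic surges multiply EA concentrations by planted fold changes —
  lactate 8.5, α-ketoglutarate 2.66, succinate 80, fumarate 5.87 (the
  printed 850/266/8000/587% as median EA/SA ratios in percent), plus
  moderate increases/decreases on a realistic scatter of amino acids,
  acylcarnitines and biogenic amines;
* duration-linked analytes gain exp(slope · duration) at EA. Slopes of
  0.021/min (Ala) and 0.016/min (Gly) calibrate the population adjusted R²
  of Ala/BCAA and Gly/BCAA against duration to ≈ 0.58 and ≈ 0.45 under the
  default noise; single-cohort estimates at n = 27 scatter around these
  values with an SD of roughly 0.1;
* reoxygenation reverses a fraction ρ of the log-scale excursion at ER
  (ρ = 1 full return to baseline, 0 none), per analyte and group: lactate
  recovers similarly everywhere (ρ = 0.85), the Krebs intermediates fastest
  under 21% O₂ (0.90) and slowest under prolonged 100% O₂ (0.35);
* missingness is MCAR at 2% plus five uninformative analytes observed in
  only ~10% of samples, below the detection threshold;
* durations are sampled independently of treatment group, and controls
  drift only by noise.

Everything is reproducible from a single integer seed, and the planted
parameters (durations, informative features with slopes, implied median
ratios) are returned as ground truth.

What the generator does **not** emulate: correlated analyte blocks within
classes (baselines are independent given the class medians), departure from
log-normality, limit-of-detection (left-censored) missingness, batch/plate
effects, within-animal autocorrelation beyond the shared baseline, or
clinical covariates beyond hypoxia duration. Passing recovery tests
therefore demonstrates correctness of the estimators under the planted
model, not robustness to those real-data complications.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use scaled designs chosen to keep
runs quick while leaving the checked properties intact: permutation tests at
n_perm = 200 (99 inside repeated-recovery loops) rather than the 5000
default; 100-seed recovery/calibration loops; null cohorts with 500
features; 27 × 200 feature matrices for the planted-recovery study. The
acceptance script derives all its randomness from `--seed` and recomputes
every reported value at run time.

## Known limitations

* The heteroscedastic contrast is the Welch/Satterthwaite approximation,
  accurate but not exact at very small group sizes (n = 6 controls).
* VIP-based selection with strict threshold 1 keeps roughly the upper tail
  of the importance distribution; on highly collinear panels (thousands of
  pairwise ratios) the selected set is large and correlated — the reduced
  model's R² is optimistic, which is why Q², RMSE and the permutation p are
  the primary quality measures.
* LLS imputation assumes approximately linear inter-feature structure on the
  log scale; under MNAR (detection-limit) missingness it will be biased, as
  will any method unaware of censoring.
* With n = 33 animals the heat-map's k-means row clusters are descriptive,
  not inferential.
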