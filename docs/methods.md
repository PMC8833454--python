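# Methods

This note documents the statistical model behind famap, the choices that
were genuinely open when it was built, and what the synthetic phantom does
and does not establish about real data.

## The mapping model

The core inference is a multivariate voxel-symptom mapping: an ε-support-
vector regression of a continuous behavioural score on voxel-wise features
(skeletonized FA in [0, 1], or 0/1 lesion indicators), followed by
permutation inference on the per-voxel feature weights of the linear model.
The multivariate model considers all voxels jointly, so voxels contribute
conditionally on the rest of the topography — the property that lets this
family of methods recover distributed networks that mass-univariate voxel
tests tend to fragment.

**Hyperparameter selection.** *C* controls the regularization/fit
trade-off. Both selection criteria are computed by repeated K-fold
cross-validation (default five times 5-fold, seeded):

* *model fit*: mean over folds of the squared Pearson correlation between
  held-out predictions and observed scores (folds with constant observed
  scores are skipped with a warning; constant predictions score r = 0);
* *weight reproducibility*: mean pairwise Pearson correlation of the
  weight vectors over **all** unordered pairs of the folds × repeats
  training-subset models (pairs are taken across repeats, not only within).

The chosen *C* maximizes the sum of the two criteria after min-max
normalization across the grid; exact ties resolve to the smaller *C*
(stronger regularization). This rule is one concrete reading of "maximize
both"; the trace of both curves is returned so users can apply their own
rule.

**Permutation p-values.** The observed weights are computed once. Each
permutation shuffles the score vector without replacement (seeded) and
refits at the same *C*. Since the feature matrix never changes, the linear
Gram matrix is precomputed once and each refit solves only the dual problem
in n subjects; primal weights are recovered as `dual_coef @ X[support]`.
Sampled p-values use add-one smoothing, `p = (1 + #extreme)/(n_perm + 1)`,
guaranteeing p > 0 and a valid test size; an exhaustive mode enumerates all
n! orderings for tiny n and returns the exact rank fraction. The comparison
tail is an explicit switch (`negative`, `positive`, `two_sided`): which
weight sign is "pathological" depends on the feature coding (for FA
features a damage model predicts lower FA with worse scores, but the
empirical direction can differ), so the package never hard-codes it.
Default: `negative`.

**Degenerate voxels.** Zero-variance columns (e.g. FA = 0 across all
subjects inside lesion cores) stay in the model so voxel bookkeeping is
untouched, but their p is reported as 1 and they are flagged in the result.

**Thresholding.** Benjamini–Hochberg step-up at q = 0.05 (delegated to
statsmodels; the test suite holds it to the literal step-up definition),
then removal of significant connected components under 20 voxels.
Connectivity default is 26 (the common volumetric default; 6 and 18
available). The filter is idempotent and only ever removes voxels.

**Covariate control.** Two strategies, matching common practice:
`residualize_behaviour` replaces the scores by their OLS residuals on
(intercept, covariate); `covary_in_model` additionally residualizes every
feature column. Constant covariates and post-residualization constant
scores raise degenerate-input errors rather than propagating zeros.

**Fixed numerical choices.** SVR ε = 0.1 (a common default; exposed in
config). No feature scaling by default — FA is already bounded in [0, 1] —
with an optional per-voxel z-scoring flag. FA values outside [0, 1] by more
than 1e-6 are clipped with a logged warning (projection/interpolation
overshoot is common), not rejected. World-to-voxel lookup rounds half away
from zero after applying the inverse affine, i.e. nearest voxel centre.

## Disconnectome

A streamline crosses the damage map iff at least one of its points maps to
a mask voxel; sub-voxel segment/surface intersection is deliberately not
implemented (point sampling at the generator's 0.5 mm step cannot skip a
1 mm voxel plane). Endpoints take the parcel label at their voxel, snapping
to the nearest labelled voxel within 3 mm (configurable) when they fall on
background; streamlines with an unassignable endpoint are counted in an
explicit unassigned bucket. Intra-region streamlines are kept and counted
once toward their region. Absolute crossing counts are the primary
statistic; proportions (crossing/total per pair and per region) are always
reported alongside, because proportions alone overstate complete
disconnection of faintly connected pairs.

## Atlas overlap

Probabilistic tract maps are binarized at an inclusive P ≥ 0.4, overlap
with the significance mask is voxel count × voxel volume (|det| of the
affine's linear part), and rows under 20 mm³ are omitted. No atlas is
bundled; maps are declared in a TSV manifest.

## Cohort statistics

2×2 chi-square is Pearson's without Yates continuity correction by default
— the convention under which printed demographic-table statistics reproduce
exactly from their raw counts (the corrected variant is a flag).
Mann-Whitney U is reported as min(U_x, U_y) with mid-ranks; p exact for
n_x·n_y ≤ 400 without ties, else normal approximation with tie correction.
The t test is pooled-variance by default (df = n_x + n_y − 2), Welch
optional.

## The phantom: what it emulates, and what it does not

The phantom grid is 16³ at 1 mm isotropic. The "skeleton" is the union of
the three orthogonal mid-planes inset by 2 voxels (~400 voxels): thin,
connected, 3D — the geometric properties of a TBSS skeleton that matter for
cluster statistics. Parcels are slabs along the first axis (a stand-in for
a cortical parcellation); the "critical" region is a contiguous ~10%
sub-region of the skeleton grown by seeded BFS.

Per subject, a spherical lesion (default radius 4 mm, ~270 mm³, about 6% of
the grid — proportionally a large middle-cerebral-artery stroke, matching
cohorts where lesion volumes of 100–175 cm³ are typical) is centred on a
random skeleton voxel and depresses FA from 0.6 by 0.3 inside the ball;
N(0, 0.02) measurement noise is added and values are clipped to [0, 1].
The radius matters for statistical power: each skeleton voxel is lesioned
in roughly `n_subjects × (lesion skeleton coverage / skeleton size)`
subjects, and per-voxel permutation tests need that number to be well above
a handful.

Scores follow `score = 12 + 60 × mean(FA over critical voxels) + N(0, σ)`,
which places intact subjects near 48 and heavily lesioned ones near 30 on
an ABA-2-like 0–50 scale with its clinical cutoff at 44. The default score
noise σ = 3 mimics a realistically noisy cohort; the strong-effect
validation runs use σ = 0.5. The nuisance covariate is the standardized
score mixed with independent noise to a target correlation of 0.56, mapped
to a WAB-like scale (mean 60, SD 20) — it reproduces the correlation, not
any mechanistic relation. Phantom tractograms are straight lines between
random voxels of two parcels, resampled at 0.5 mm with optional Gaussian
jitter on interior points, with exact per-pair counts recorded as ground
truth.

All generators are pure functions of (parameters, seed).

**Limitations.** Lesions are spheres, not vascular territories; there are
no remote/Wallerian FA effects, no spatial autocorrelation of FA noise, no
registration or skeleton-projection error, and the planted effect is linear
in the critical-region mean rather than a per-voxel weight profile.
Passing the phantom validations therefore shows the *inference machinery*
is correct and calibrated under a known generative model — not that the
pipeline's assumptions hold in any particular patient cohort.

## Validation problem sizes

The test-suite and acceptance-script simulations use 16³ phantoms
(~400 skeleton voxels), 50–60 subjects, 500–1000 permutations, C grids of
9–13 powers of two, 10 recovery repetitions and 50 null runs — sizes chosen
so the full validation runs in minutes on one CPU while leaving the
permutation and FDR machinery fully exercised. Measured under these
conditions: mean recovery sensitivity ≈ 0.8–0.9 and precision ≈ 0.6–0.7
against the planted critical region, and no null run with any
FDR-significant voxel. Precision is bounded away from 1 by design: voxels
adjacent to the critical region share lesions with it, so their FA is
genuinely correlated with the score — a spatial-smear property real lesion
data share.

## Known limitations of the implementation

* Permutation inference is defined only for the linear kernel (feature
  weights exist in the primal); the rbf kernel is available for prediction
  only.
* Whether permutation refits should re-optimize *C* per permutation is an
  open methodological question; famap reuses the chosen *C* for all
  permutations, which is the computationally standard choice.
* The streamline crossing test is pointwise; tractograms sampled much more
  coarsely than the voxel size could miss thin masks.
* BH-FDR assumes independence or positive dependence across voxel
  p-values; under the strong spatial dependence of permutation weight maps
  it is conservative (observed null any-discovery rate ≈ 0).
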