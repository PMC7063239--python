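# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `limbalign`. Every number
quoted here is computed by the test suite or the acceptance script.

## Shape models and alignment

Landmark configurations are aligned by generalized Procrustes analysis
(GPA): each shape is centered, then iteratively superimposed on the running
consensus (rotation + translation; similarity scaling is available but
**off by default**, because overall size is biologically meaningful in
skeletal data — the first principal component of such data is essentially
size, and scaling it away would discard the dominant anatomical factor and
the main carrier of sexual dimorphism). Iterations stop when the consensus
RMS change falls below 1e−8 mm (maximum 100 iterations); the total residual
is checked to be non-increasing on every run. Reflections are never allowed
inside alignment; mirroring is an explicit, separate operation across the
sagittal plane (the X–Z plane of the template frame: +X anterior, +Y
subject-left, +Z superior).

Pairwise superimposition uses the closed-form SVD (Kabsch/Umeyama)
solution. Degenerate inputs (rank < 2 after centering) raise; the optimal
rotation is otherwise unique. The test suite cross-checks the residual
against an SVD-free brute-force search over a nested rotation grid.

PCA models are fitted by SVD of the centered data matrix (covariance with
the n−1 divisor). Eigenvector signs are fixed so each component's
largest-magnitude loading is positive, making models reproducible across
platforms. Retained dimensionality is controlled by cumulative explained
variance: 0.98 for decoupled and articulated models, 0.995 for recoupled
models. The recoupled model is retained more generously because it is the
reference in the pose-variance statistic (below); its truncation error must
stay well below the quantity being estimated. The full eigenvalue spectrum
is kept alongside the retained modes so compactness curves always end at 1.

## Joint angles

Joint pose is expressed as intrinsic rotations in the order flexion (about
Y), abduction (about X), endorotation (about Z) — tag `"YXZ-intrinsic"`.
This order matches clinical naming for lower-limb joints and makes the
generator and the measurement exactly inverse to each other (round trips
agree to < 1e−6°; the matrix route is cross-checked against a quaternion
composition oracle). Near gimbal lock (|abduction| → 90°) the
flexion/endorotation split is degenerate; the result is flagged and the
endorotation forced to zero.

Angular deviation between a test and a control construct is measured by
superimposing the proximal parts, then decomposing the rotation that best
carries the control's distal part onto the test's. Two consequences are
worth stating explicitly:

* the decomposition axes are the **control's** axes. The rotation magnitude
  and the point RMSE are invariant to any global rigid motion of the pair,
  but the per-axis split is not; validation therefore superimposes controls
  on the articulated model mean first, so reported axes are anatomical;
* joint centers are defined as centroids of named articular landmark groups
  (femoral head for the hip, femoral condyles for the knee, tibial mortise
  for the ankle), so they scale and move with the subject.

## The denoising pipeline

Decoupled scores (pose-free anatomy) predict articulated scores (anatomy +
pose) through PLS regression. PLS is computed by scikit-learn's NIPALS
implementation with mean centering and **no** variance scaling: PC scores
carry their eigenvalue-weighted scale, and whitening them would equalize
modes that differ by orders of magnitude in anatomical variance. At full
rank the fit coincides with ordinary least squares (asserted to 1e−6 on
every run).

The component count k* minimizes the mean left/right dissimilarity of the
predicted constructs — the whole two-bone construct of the mirrored left
side superimposed on the right, residual RMSE in mm. Ties are broken by
parsimony: the smallest k within 1 % of the minimum wins. On the default
synthetic population the curve has its minimum at k* = 1 for all three
joints and turns upward for larger k, where overfitting lets scan pose leak
back into the prediction (at the knee the dissimilarity grows ~30-fold
between k = 1 and k = 6).

Recoupling rigidly superimposes each subject's own bone geometry (no
scaling) onto its counterpart in the regressed construct, preserving
anatomical detail bit-for-bit up to a rigid transform. The instant map —
PLS from articulated to recoupled scores, default 200 components capped at
the available rank — performs the whole correction in one step on new
data. Its error-evolution curve does **not** collapse to zero asymmetry:
it converges to the true (anatomy-only) asymmetry of the recoupled
constructs plus a small second-order residual (~0.5 mm at the hip) from
the interaction between whole-construct alignment and pose; it stays an
order of magnitude below pose levels at every component count, while the
prediction accuracy against the offline recoupled constructs is
non-increasing in k.

Offline denoising is exactly pose-invariant for fixed anatomy (the
decoupled scores do not change with pose). Instant denoising is nearly
invariant; under ±15°-per-axis inputs the outputs of a model trained at
that pose amplitude agree to within 0.35× the input pose displacement. The
residual is inherent: a linear shape model truncated at 98 % variance spans
the tangent of the rotation manifold, not its quadratic part, so
large-rotation displacements have an out-of-model component of order θ²
times the lever arm. Whole-limb correction chains the per-joint denoisers
and connects consecutive constructs by rigid superimposition of the shared
bone; the assembly order (ankle→knee→hip vs hip→knee→ankle) changes the
result by < 0.1 mm mean point distance.

## Pose-variance estimation

The share of articulated-data variance contributed by pose is estimated as
the percentage of variance the recoupled model cannot represent: each datum
is rigidly aligned to the model mean, projected on the retained modes, and
the residual sum of squares divided by the data's total variance about its
mean. Alignment before projection is essential — without it the statistic
conflates frame offsets with shape. Data already in the model's aligned
frame are projected directly, mirroring how training scores are computed.

The ground-truth counterpart used in tests is the same statistic evaluated
against an SSM fitted to the generator's true neutral constructs (same
retained variance). This — rather than the naive per-scan
‖posed − rigid-fit(neutral)‖² fraction — is the correct estimand: part of
a pose rotation's displacement field is collinear with the anatomy-driven
neutral-alignment directions and is not separable from anatomy by *any*
model. Learned and ground-truth statistics agree within 2 percentage points
at 300 subjects.

## The synthetic cohort

The generator emulates a CT-derived lower-limb landmark cohort. Defaults
(all configurable):

| parameter | default | rationale |
|---|---|---|
| subjects | 300 (500 for dimorphism runs) | main study scale; both sides used |
| landmarks | pelvis 120, femur 160, tibia 140, foot 100 | dense quasi-landmark budget per bone |
| femur length | 450 mm | adult template; keeps mm errors on a realistic scale |
| size latent | scale sd 6 %, ≥ 60 % of anatomical variance | size dominates real skeletal PCA |
| minor latents | 4 (limb elongation, shaft radius, knee width, pelvis size), 10 % of variance | residual shape heterogeneity |
| sex effect | 30 % of per-bone variance; 70 % of it through overall size, the rest through width contrasts (wider knee/ankle, narrower pelvic inlet in males) | size is the most sex-discriminative direction in skeletal data; width contrasts carry the size-independent signal |
| sex ratio | 2:1 male:female | unbalanced cohort; label variance 8/9 enters the calibration |
| neutral alignment | per-joint angles = coefficients × apparent size, clipped ±10°; hip (3, 2, 4)°, knee (4, 1, 1.5)°, ankle (3, 1.5, 1.5)° per size-sd | constitutional alignment is anatomy-driven and of a few degrees sd; a single driving factor matches the one-component regime of the regressed model |
| scanner pose | truncated normal, hip (2, 2.5, 5)°, knee (1.5, 0.8, 1.2)°, ankle (2.5, 2.5, 2)° sd, clipped ±15° | repeat-scan pose differences are largest in hip endorotation and smallest at the knee |
| mock pose | uniform ±15° per axis per joint | the validation experiment's regime |
| asymmetry | 0.3 mm iid on left-bone landmarks | directional asymmetry well below pose effects, so L/R dissimilarity is pose-dominated |
| rescans | 40 subject-side couples | anatomy shared, pose redrawn |

Deformation fields are *pure shape*: centered and orthogonalized against
the rigid motions (and, for the sex width features, against the bone's size
direction), so the planted variance budget survives Procrustes alignment
exactly and planted fractions are recoverable. Field amplitudes are
calibrated in closed form from the variance fractions. All randomness flows
from one master seed through named substreams (latents, sex, asymmetry,
pose, global motion); populations regenerate bit-identically.

What the generator does **not** emulate: real bone surface geometry and
correspondence error, segmentation noise, pathology, age structure,
population admixture, soft tissue, and any sex–alignment interaction beyond
the size pathway. Passing tests therefore demonstrate the machinery —
pose removal, model compactness gains, planted-effect recovery — under
idealized correspondences, not clinical accuracy on real scans.

## Dimorphism analysis

With a binary label the canonical pair is unique: the canonical direction
is the least-squares discriminant in score space and r the multiple
correlation; its p-value comes from label permutations (QR-accelerated,
seeded). Explained variance by sex is a one-component PLS regression with
the label as the sole predictor — equivalently per-column least squares —
expressed as a percentage of (eigenvalue-scaled) score variance over the
first 20 PCs. At 500 subjects this estimator carries a Monte-Carlo sd of
about 3 percentage points, dominated by the draw-specific sample
correlation between the label and the size latent (shared by all bones of
the same subjects), so recovery checks average over independent cohorts.

Effect shapes reconstruct the model at ±2× the mean male/female canonical
scores along the canonical direction; "size correction" rescales both
shapes to a common centroid size before differencing, which exactly
removes a planted pure-scale group difference. Per-landmark significance
uses a two-sample permutation test on the landmark-wise mean displacement
with Benjamini–Hochberg FDR across landmarks. With strongly correlated
landmarks the BH decision is effectively all-or-nothing per bone; under a
global null this means a full-bone false alarm in about α of the seeds and
nothing otherwise, which is what nominal control guarantees under such
dependence — the null check counts triggering seeds against a binomial
bound rather than averaging rejected fractions.

## Validation experiments and problem sizes

The mock experiment samples K = 1000 shapes from the recoupled model's
mean and first PC, corrupts each with uniform ±15° per-axis rotations
through the idealized joint, and compares before/after-correction
deviations (paired sign-flip permutation test, 10 000 permutations,
seeded; the attainable p-value floor is 1/10 001). The rescan experiment
compares the two scans of each couple to each other; after offline
correction the within-couple differences drop by more than 95 % (in fact
to numerical noise, since the two scans share bone geometry exactly).

Default problem sizes — 300 subjects (640 scans) for the pipeline, 500 for
dimorphism, K = 1000 mocks — were chosen so the full suite and the
acceptance script each run in minutes on a single CPU while keeping the
Monte-Carlo error of every asserted quantity below its tolerance.

## Serialization

Shape models and pipelines are stored as single-file compressed `.npz`
containers: arrays under prefixed keys (`bone/<part>/...`,
`art|rec/<joint>/...`, PLS maps under `regr|inst/<joint>/...`) plus an
embedded JSON metadata block (layout version, retained counts, joint
definitions, configuration). Landmark CSV (`point_id,part,side,x,y,z`, mm,
"." decimal separator) round-trips bit-exactly; PLY/OBJ vertex clouds are
supported with a JSON sidecar carrying ids, part labels and side.

## Known limitations

* Linear models linearize rotations: both the articulated model's pose
  modes and the instant map degrade quadratically with pose amplitude.
  The offline route is immune, but needs the per-bone decomposition.
* The regressed model at k* = 1 predicts alignment from the dominant
  anatomical factor only; anatomy-alignment relationships orthogonal to it
  would need more components and would trade against pose reintroduction.
* Pose variance collinear with anatomy-driven alignment directions is not
  identifiable by any model; the pose-variance statistic estimates the
  separable part.
* The per-landmark significance map is marginal; with correlated landmarks
  it localizes effects only when landmark noise is not dominated by shared
  latent factors.
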