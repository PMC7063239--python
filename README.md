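# limbalign

Statistical shape models (SSMs) of articulated anatomy suffer from
positional interference: when a multi-bone construct — a hip, a knee, an
ankle, a whole lower limb — is Procrustes-aligned as a single unit, the
joint pose at scan time survives the alignment and masquerades as shape
variance. The first principal components of such an "articulated" model mix
anatomy with leg position, which inflates the model, degrades its
compactness, and confounds downstream association studies (sex, genetics,
alignment pathology).

`limbalign` implements a regression-based method that separates scan-time
pose from the *neutral alignment* — the inter-bone configuration a subject's
skeleton adopts with no movement or load — without ever imposing idealized
joint models on the data. It is written for researchers in geometric
morphometrics, musculoskeletal biomechanics and anatomical image analysis
who work with dense homologous landmark sets.

## The method

Every structure is a point-distribution model over aligned landmark
configurations,

    S = S̄ + P b,

with `S̄` the mean shape, `P` the matrix of principal-component
eigenvectors and `b` the per-subject score vector. Four model families are
chained:

1. **Decoupled SSMs** — each bone aligned and modeled in isolation
   (generalized Procrustes, no scaling). Per-bone alignment destroys pose
   by construction, so decoupled scores are pose-free descriptors of
   anatomy.
2. **Articulated SSMs** — two-bone joint constructs aligned as a whole;
   relative bone pose survives as apparent shape variance.
3. **Regressed model** — a partial least squares (PLS) regression from
   decoupled scores to articulated scores. Pose is noise independent of
   anatomy, so the prediction averages it out and returns each subject's
   *neutral* construct. The number of PLS components is selected by error
   evolution: the left/right dissimilarity of the predicted constructs is
   dominated by residual pose (anatomy is nearly symmetric, scan pose is
   not); too many components reintroduce pose through overfitting, so the
   dissimilarity curve has a minimum (typically at one component, since the
   dominant anatomical factor — size — drives neutral alignment).
4. **Recoupled model** — each subject's original bone geometry is rigidly
   superimposed back onto the regressed construct, restoring all anatomical
   detail while keeping the neutral alignment; a second PLS map from
   articulated to recoupled scores then performs *instant* one-step
   denoising of new data.

Validation follows two experiments: repeat-scan ("rescan") couples, which
share anatomy but not pose, and mock datasets sampled from the recoupled
model's mean and first PC and corrupted by rotations uniform on
[−15°, +15°] per axis through idealized joint centers. A sexual-dimorphism
module quantifies the sex–shape relationship on the corrected models by
canonical correlation analysis (CCA), PLS-regression explained variance,
amplified male/female effect shapes and permutation/FDR significance maps.

Because the source cohort is not public, the package ships a first-class
synthetic generator (`limbalign.synthetic`) producing articulated lower-limb
landmark populations with ground truth: latent-driven bone shape (size
dominant), anatomy-driven neutral alignment, scanner pose noise, mirrored
left sides, rescan couples and a planted sex effect.

## Worked example

```python
from limbalign import (GeneratorConfig, sample_population, train_pipeline,
                       make_mock_set, validate_mock, compactness_curve)

pop = sample_population(GeneratorConfig(n_subjects=120, seed=42))
pipe = train_pipeline(pop.scan_records(), pop.joints, pop.bone_parts)
print("selected PLS components:", pipe.k_star)

art = compactness_curve(pipe.articulated_models["hip"])
rec = compactness_curve(pipe.recoupled_models["hip"])
print(f"hip: articulated PC1 {art[0]*100:.1f}% vs recoupled PC1 {rec[0]*100:.1f}%")

mock = make_mock_set(pipe.recoupled_models["hip"], pipe.joints["hip"],
                     K=200, limit_deg=15.0, seed=0)
report = validate_mock(pipe, mock, seed=0)
print(report.table[["joint", "metric", "before_mean", "before_sd",
                    "after_mean", "p_value"]].round(3).to_string(index=False))
```

prints

```
selected PLS components: {'hip': 1, 'knee': 1, 'ankle': 1}
hip: articulated PC1 87.2% vs recoupled PC1 91.3%
joint       metric  before_mean  before_sd  after_mean  p_value
  hip      flexion        7.362      4.217       0.015      0.0
  hip    abduction        7.463      4.298       0.011      0.0
  hip endorotation        7.236      4.225       0.035      0.0
  hip      rmse_mm       43.889     16.711       0.081      0.0
```

Reading: error evolution selects one PLS component per joint; removing pose
makes the hip model more compact (first mode 87.2 % → 91.3 % of variance);
and mock constructs whose hip pose was corrupted by uniform ±15° rotations
(mean absolute deviation ≈ 7.4° per axis, ≈ 44 mm point RMSE) are restored
to within a few hundredths of a degree of their unposed controls. The
reported permutation p-values are at the resolution floor of the 10 000
sign-flip permutations (p < 10⁻⁴, displayed as 0.0 after rounding).

The same workflow is available from a shell:

```sh
limbalign simulate --config cfg.yaml --out data/
limbalign build    --data data/ --out pipeline.npz
limbalign validate --pipeline pipeline.npz --mode mock --out mock.csv
limbalign denoise  --pipeline pipeline.npz --in data/sub0000_right_scan0.csv \
                   --joint knee --out neutral.csv --instant
limbalign dimorphism --pipeline pipeline.npz --data data/ --joint hip \
                   --out dim.json --map displacement.csv
```

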