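import numpy as np
import pytest

from limbalign.denoiser import train_pipeline
from limbalign.geometry import generalized_procrustes, mirror
from limbalign.shape_model import fit_ssm, project
from limbalign.synthetic import GeneratorConfig, make_template, sample_population


@pytest.fixture(scope="session")
def template_bundle():
    return make_template()


@pytest.fixture(scope="session")
def default_population():
    """Main study conditions: 300 subjects, both sides, 40 rescan couples."""
    return sample_population(GeneratorConfig(n_subjects=300, seed=12345))


@pytest.fixture(scope="session")
def trained_pipeline(default_population):
    pop = default_population
    return train_pipeline(pop.scan_records(), pop.joints, pop.bone_parts)


@pytest.fixture(scope="session")
def small_population():
    return sample_population(GeneratorConfig(n_subjects=60, seed=7,
                                             n_rescan_pairs=8))


@pytest.fixture(scope="session")
def small_pipeline(small_population):
    pop = small_population
    return train_pipeline(pop.scan_records(), pop.joints, pop.bone_parts)


@pytest.fixture(scope="session")
def uniform_pose_pipeline():
    """Pipeline trained under the mock-experiment pose regime (+/-15 deg)."""
    pop = sample_population(GeneratorConfig(n_subjects=60, seed=17,
                                            pose_profile="uniform",
                                            n_rescan_pairs=8))
    return pop, train_pipeline(pop.scan_records(), pop.joints, pop.bone_parts)


@pytest.fixture(scope="session")
def zero_pose_population():
    cfg = GeneratorConfig(
        n_subjects=40, seed=5, asymmetry_sd=0.0, n_rescan_pairs=4,
        scanner_pose_sd={"hip": (0.0, 0.0, 0.0), "knee": (0.0, 0.0, 0.0),
                         "ankle": (0.0, 0.0, 0.0)})
    return sample_population(cfg)


@pytest.fixture(scope="session")
def zero_pose_pipeline(zero_pose_population):
    pop = zero_pose_population
    return train_pipeline(pop.scan_records(), pop.joints, pop.bone_parts)


@pytest.fixture(scope="session")
def dimorph_population():
    """Planted-sex-effect conditions: 500 subjects, 30% sex variance."""
    return sample_population(GeneratorConfig(n_subjects=500, seed=4242))


@pytest.fixture(scope="session")
def dimorph_percent_replicates():
    """Femur sex-explained-variance estimates over independent n=500 cohorts."""
    from limbalign.latent_regression import plsr_explained_variance
    out = []
    for seed in (101, 102, 103):
        pop = sample_population(GeneratorConfig(n_subjects=500, seed=seed))
        shapes, sex = [], []
        for s in pop.subjects:
            for side in ("right", "left"):
                b = s.bones[side]["femur"]
                shapes.append(mirror(b) if side == "left" else b)
                sex.append(s.sex)
        aligned, _, _ = generalized_procrustes(shapes)
        model = fit_ssm(aligned, variance_kept=0.995)
        scores = np.stack([project(model, a).b for a in aligned])
        out.append(plsr_explained_variance(scores[:, :20],
                                           np.asarray(sex, float)))
    return out


@pytest.fixture(scope="session")
def dimorph_bone_models(dimorph_population):
    """Decoupled per-bone models with scores and labels, both sides pooled."""
    pop = dimorph_population
    out = {}
    for part in ("pelvis", "femur", "tibia"):
        shapes, sex = [], []
        for s in pop.subjects:
            for side in ("right", "left"):
                b = s.bones[side][part]
                shapes.append(mirror(b) if side == "left" else b)
                sex.append(s.sex)
        aligned, _, _ = generalized_procrustes(shapes)
        model = fit_ssm(aligned, variance_kept=0.995)
        scores = np.stack([project(model, a).b for a in aligned])
        out[part] = (model, scores, np.asarray(sex), aligned)
    return out
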