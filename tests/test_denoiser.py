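import numpy as np
import pytest

from limbalign.denoiser import (chain_joints, denoise, error_evolution,
                                predict_neutral, recouple, train_pipeline)
from limbalign.evaluation import measure_joint_deviation, validate_rescan
from limbalign.geometry import mirror, procrustes_align
from limbalign.latent_regression import fit_pls
from limbalign.shape_model import (align_and_project, align_to_model,
                                   compactness_curve, fit_ssm, project,
                                   reconstruct)
from limbalign.geometry import generalized_procrustes
from limbalign.synthetic import apply_pose, size_driver


def joint_construct_of(pop, record, joint_name):
    c = record.construct
    c = mirror(c) if c.side == "left" else c
    return pop.joint_construct(c, joint_name)


class TestDecoupledModels:
    def test_scores_are_pose_invariant(self, small_population, small_pipeline):
        pop, pipe = small_population, small_pipeline
        model = pipe.bone_models["femur"]
        s = pop.subjects[0]  # rescan subject: two poses, same anatomy
        scans = [r for r in s.scans if r.side == "right"]
        b = [align_and_project(model, r.construct.extract_parts("femur")).b
             for r in scans]
        assert np.allclose(b[0], b[1], atol=1e-8)
        neutral_b = align_and_project(
            model, s.neutral_rf["right"].extract_parts("femur")).b
        assert np.allclose(b[0], neutral_b, atol=1e-8)

    def test_first_mode_is_the_size_axis(self, default_population,
                                         trained_pipeline):
        pop, pipe = default_population, trained_pipeline
        model = pipe.bone_models["femur"]
        drivers, scores = [], []
        for s in pop.subjects:
            scores.append(align_and_project(
                model, s.bones["right"]["femur"]).b[0])
            drivers.append(size_driver(pop.template, s.latents, s.sex))
        r = abs(np.corrcoef(scores, drivers)[0, 1])
        assert r > 0.95  # mode 1 dominated by overall size


class TestArticulatedModels:
    def test_pose_noise_increases_total_variance(self, small_population):
        pop = small_population
        posed, neutral = [], []
        for s in pop.subjects:
            rec = s.scans[0]
            posed.append(joint_construct_of(pop, rec, "hip"))
            neutral.append(pop.joint_construct(s.neutral_rf["right"], "hip"))
        ap, _, _ = generalized_procrustes(posed)
        an, _, _ = generalized_procrustes(neutral)
        var_p = np.stack([a.vector for a in ap]).var(axis=0).sum()
        var_n = np.stack([a.vector for a in an]).var(axis=0).sum()
        assert var_p > var_n

    def test_first_mode_share_drops_with_pose(self, trained_pipeline):
        for name in trained_pipeline.joints:
            art = compactness_curve(trained_pipeline.articulated_models[name])
            rec = compactness_curve(trained_pipeline.recoupled_models[name])
            assert rec[0] > art[0]


class TestComponentSelection:
    def test_one_component_wins_and_curve_turns_upward(self, trained_pipeline):
        for name in trained_pipeline.joints:
            assert trained_pipeline.k_star[name] == 1
            curve = trained_pipeline.error_curves[name]["lr_dissimilarity_mm"]
            assert curve.iloc[-1] > curve.min()  # overfitting reintroduces pose
            assert not np.all(np.diff(curve) <= 0)

    def test_zero_pose_symmetric_curve_near_zero(self, zero_pose_pipeline):
        for name in zero_pose_pipeline.joints:
            curve = zero_pose_pipeline.error_curves[name]["lr_dissimilarity_mm"]
            assert curve.max() < 0.05  # mm


class TestRegressedModel:
    def test_mean_predicts_mean(self, trained_pipeline):
        for name in trained_pipeline.joints:
            pls = trained_pipeline.regressed_models[name]
            assert np.allclose(pls.predict(pls.x_mean), pls.y_mean, atol=1e-10)

    def test_pose_invariance_of_regressed_construct(self, small_population,
                                                    small_pipeline):
        pop, pipe = small_population, small_pipeline
        s = pop.subjects[1]  # rescan subject
        scans = [r for r in s.scans if r.side == "right"]
        out = [predict_neutral(pipe, "knee",
                               joint_construct_of(pop, r, "knee"))
               for r in scans]
        assert np.allclose(out[0].coords, out[1].coords, atol=1e-8)

    def test_neutral_angles_recovered_qualitatively(self, small_population,
                                                    small_pipeline):
        pop, pipe = small_population, small_pipeline
        joint = pipe.joints["hip"]
        true, est = [], []
        for s in pop.subjects[:30]:
            den = denoise(pipe, "hip",
                          joint_construct_of(pop, s.scans[0], "hip"),
                          method="offline")
            control = pop.joint_construct(s.zero_rf["right"], "hip")
            ang, _ = measure_joint_deviation(den, control, joint)
            true.append(s.neutral_angles["hip"])
            est.append(ang.as_array)
        true, est = np.array(true), np.array(est)
        for axis in range(3):
            assert np.corrcoef(true[:, axis], est[:, axis])[0, 1] > 0.95


class TestRecoupling:
    def test_identity_when_originals_equal_regressed(self, small_pipeline,
                                                     small_population):
        pop = small_population
        reg = predict_neutral(small_pipeline, "hip",
                              joint_construct_of(pop, pop.subjects[3].scans[0],
                                                 "hip"))
        bones = {p: reg.extract_parts(p) for p in reg.parts}
        rec = recouple(reg, bones)
        assert np.allclose(rec.coords, reg.coords, atol=1e-9)

    def test_bone_geometry_preserved_rigidly(self, small_pipeline,
                                             small_population):
        pop = small_population
        s = pop.subjects[4]
        construct = joint_construct_of(pop, s.scans[0], "knee")
        den = denoise(small_pipeline, "knee", construct, method="offline")
        for part in ("femur", "tibia"):
            _, _, rmse = procrustes_align(construct.extract_parts(part),
                                          den.extract_parts(part))
            assert rmse < 1e-8

    def test_recoupled_alignment_matches_regressed(self, small_pipeline,
                                                   small_population):
        pop = small_population
        joint = small_pipeline.joints["hip"]
        s = pop.subjects[5]
        construct = joint_construct_of(pop, s.scans[0], "hip")
        reg = predict_neutral(small_pipeline, "hip", construct)
        den = denoise(small_pipeline, "hip", construct, method="offline")
        ang, _ = measure_joint_deviation(den, reg, joint)
        assert np.abs(ang.as_array).max() < 0.1

    def test_missing_part_rejected(self, small_pipeline, small_population):
        pop = small_population
        reg = predict_neutral(small_pipeline, "hip",
                              joint_construct_of(pop, pop.subjects[0].scans[0],
                                                 "hip"))
        with pytest.raises(KeyError):
            recouple(reg, {"pelvis": reg.extract_parts("pelvis")})


class TestInstantPrediction:
    def test_close_to_offline_recoupled_construct(self, small_population,
                                                  small_pipeline):
        pop, pipe = small_population, small_pipeline
        errs, radii = [], []
        for s in pop.subjects[:20]:
            c = joint_construct_of(pop, s.scans[0], "hip")
            off = denoise(pipe, "hip", c, method="offline")
            inst = denoise(pipe, "hip", c, method="instant")
            _, aligned, _ = procrustes_align(inst, off)
            errs.append(np.linalg.norm(aligned.coords - off.coords,
                                       axis=1).mean())
            radii.append(np.linalg.norm(off.coords - off.centroid,
                                        axis=1).mean())
        assert np.mean(errs) < 0.05 * np.mean(radii)

    def test_accuracy_improves_with_components(self, small_pipeline):
        tr = small_pipeline.training["hip"]
        y_art, y_rec = tr["Y_art"], tr["Y_rec"]
        n = len(y_art)
        cut = int(0.8 * n)
        model_hi = small_pipeline.recoupled_models["hip"]
        errs = {}
        for k in (1, tr["k_instant"]):
            m = fit_pls(y_art[:cut], y_rec[:cut], k)
            pred = m.predict(y_art[cut:])
            errs[k] = np.sqrt(((pred - y_rec[cut:]) ** 2).sum(axis=1)).mean()
        assert errs[tr["k_instant"]] <= errs[1]

    def test_zero_pose_denoise_is_near_identity(self, zero_pose_population,
                                                zero_pose_pipeline):
        pop, pipe = zero_pose_population, zero_pose_pipeline
        art = pipe.articulated_models["ankle"]
        for s in pop.subjects[:8]:
            c = joint_construct_of(pop, s.scans[0], "ankle")
            den = denoise(pipe, "ankle", c, method="instant")
            _, _, rmse = procrustes_align(den, align_to_model(
                pipe.recoupled_models["ankle"], c))
            # residual bounded by the articulated-model truncation error
            al = align_to_model(art, c)
            b = project(art, al).b
            trunc = np.sqrt(((al.vector - reconstruct(art, b).vector) ** 2)
                            .reshape(-1, 3).sum(axis=1).mean())
            assert rmse < 3 * trunc + 0.1

    def test_end_to_end_pose_invariance(self, uniform_pose_pipeline):
        pop, pipe = uniform_pose_pipeline
        s = pop.subjects[6]
        neutral = pop.joint_construct(s.neutral_rf["right"], "hip")
        joint = pipe.joints["hip"]
        rng = np.random.default_rng(0)
        poses = [rng.uniform(-15, 15, 3) for _ in range(4)]
        offline = [denoise(pipe, "hip", apply_pose(neutral, joint, p),
                           method="offline") for p in poses]
        instant = [denoise(pipe, "hip", apply_pose(neutral, joint, p),
                           method="instant") for p in poses]
        # offline route: decoupled scores are exactly pose-invariant
        for out in offline[1:]:
            assert np.allclose(out.coords, offline[0].coords, atol=1e-6)
        # instant route: nearly invariant (linear model of a rotation
        # manifold; tolerance 0.35 x input pose displacement)
        before = [procrustes_align(apply_pose(neutral, joint, p), neutral)[2]
                  for p in poses]
        diffs = [procrustes_align(a, instant[0])[2] for a in instant[1:]]
        assert np.mean(diffs) < 0.35 * np.mean(before)


class TestChainJoints:
    def test_posed_limb_angles_recovered(self, default_population,
                                         trained_pipeline):
        pop, pipe = default_population, trained_pipeline
        errs = {name: [] for name in pipe.joints}
        for s in pop.subjects[:30]:
            rec = s.scans[0]
            limb, residuals = chain_joints(pipe, rec.construct)
            control = s.zero_rf["right"]
            for name, joint in pipe.joints.items():
                jl = pop.joint_construct(limb, name)
                jc = pop.joint_construct(control, name)
                ang, _ = measure_joint_deviation(jl, jc, joint)
                errs[name].append(np.abs(ang.as_array
                                         - s.neutral_angles[name]))
            assert max(residuals.values()) < 1e-6  # shared bones consistent
        for name, e in errs.items():
            assert np.mean(e, axis=0).max() < 1.0  # MAE per axis, degrees

    def test_order_near_commutative(self, small_population, small_pipeline):
        pop, pipe = small_population, small_pipeline
        rec = pop.subjects[13].scans[0]
        a, _ = chain_joints(pipe, rec.construct, order=("ankle", "knee", "hip"))
        b, _ = chain_joints(pipe, rec.construct, order=("hip", "knee", "ankle"))
        _, aligned, _ = procrustes_align(b, a)
        assert np.linalg.norm(aligned.coords - a.coords, axis=1).mean() < 0.1

    def test_untrained_joint_rejected(self, small_pipeline, small_population):
        rec = small_population.subjects[0].scans[0]
        with pytest.raises(KeyError):
            chain_joints(small_pipeline, rec.construct,
                         order=("ankle", "knee", "shoulder"))


class TestRescanProperty:
    def test_offline_correction_removes_pair_differences(self,
                                                         default_population,
                                                         trained_pipeline):
        pairs = default_population.rescan_pairs()
        report = validate_rescan(trained_pipeline, pairs, n_perm=2000, seed=1)
        assert report.consistent()
        tab = report.table
        ang = tab[tab.metric != "rmse_mm"]
        # >= 95% reduction of within-pair angular differences
        assert np.all(ang.after_mean <= 0.05 * ang.before_mean)
        assert np.all(tab.p_value < 0.001)


def test_error_evolution_instant_path(small_pipeline):
    from limbalign.denoiser import _lr_pairs, _mean_lr_dissimilarity
    curve = error_evolution(small_pipeline, "hip", path="instant")
    vals = curve["lr_dissimilarity_mm"].to_numpy()
    tr = small_pipeline.training["hip"]
    pairs = _lr_pairs(tr["rows"])
    used = sorted({i for p in pairs for i in p})
    pos = {i: k for k, i in enumerate(used)}
    pose_level = _mean_lr_dissimilarity(
        small_pipeline.articulated_models["hip"], tr["Y_art"][used],
        pairs, pos)
    # full-rank instant map keeps asymmetry far below articulated pose levels
    assert vals[-1] < 0.25 * pose_level and vals[-1] < 1.0  # sub-mm
    with pytest.raises(ValueError):
        error_evolution(small_pipeline, "hip", path="bogus")
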