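"""Error metrics and the two validation experiments.

Provides the left/right dissimilarity driving component selection, the
joint-angle deviation measurement (flexion / abduction / endorotation plus
point RMSE) used throughout, and the mock- and rescan-validation reports:
per joint and metric, mean +/- sd before and after pose correction with a
paired permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .denoiser import DenoisePipeline, JointSpec, denoise, error_evolution
from .geometry import (CorrespondenceError, LandmarkShape, PoseAngles,
                       euler_from_rotation, mirror, procrustes_align)

ANGLE_METRICS = ("flexion", "abduction", "endorotation")


def lr_dissimilarity(right: LandmarkShape, left: LandmarkShape,
                     relabel_map: dict | None = None) -> float:
    """RMSE between a right construct and the mirrored left one (mm).

    The whole multi-bone construct is superimposed rigidly (no scale), so
    differences in relative bone pose between the sides remain in the
    residual — the quantity assumed to be dominated by scan pose rather
    than true asymmetry.
    """
    l = mirror(left, relabel_map) if left.side == "left" else left
    if not l.same_points(right):
        raise CorrespondenceError("left/right point sets differ after relabeling")
    _, _, rmse = procrustes_align(l, right)
    return rmse


def measure_joint_deviation(test: LandmarkShape, control: LandmarkShape,
                            joint: JointSpec) -> tuple[PoseAngles, float]:
    """Joint-angle deviation of ``test`` from the unposed ``control``.

    The proximal parts are superimposed first (rigid), then the rotation
    best carrying the control's distal part onto the test's is decomposed
    into flexion/abduction/endorotation; the RMSE covers all construct
    landmarks after the proximal superimposition.
    """
    if not test.same_points(control):
        raise CorrespondenceError("test/control point sets differ")
    tf, _, _ = procrustes_align(test.extract_parts(joint.proximal),
                                control.extract_parts(joint.proximal))
    test_al = test.with_coords(tf.apply(test.coords), frame=control.frame)
    tf2, _, _ = procrustes_align(control.extract_parts(joint.distal),
                                 test_al.extract_parts(joint.distal))
    angles = euler_from_rotation(tf2.rotation)
    rmse = float(np.sqrt(((test_al.coords - control.coords) ** 2)
                         .sum(axis=1).mean()))
    return angles, rmse


def paired_permutation_pvalue(before: np.ndarray, after: np.ndarray,
                              n_perm: int = 10000, seed: int = 0) -> float:
    """One-sided sign-flip permutation test that ``before`` exceeds ``after``."""
    d = np.asarray(before, float) - np.asarray(after, float)
    if d.size == 0:
        raise ValueError("empty inputs")
    rng = np.random.default_rng(seed)
    obs = d.mean()
    signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
    perm = (signs * d).mean(axis=1)
    return float((1 + (perm >= obs - 1e-12).sum()) / (n_perm + 1))


@dataclass(eq=False)
class ValidationReport:
    """Per joint x metric summary: mean +/- sd before/after correction."""

    table: pd.DataFrame
    per_case: dict = field(default_factory=dict)  # (joint, metric) -> (before, after)
    experiment: str = ""

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def consistent(self) -> bool:
        """Summary means must equal direct recomputation from stored cases."""
        for _, row in self.table.iterrows():
            b, a = self.per_case[(row["joint"], row["metric"])]
            if not (np.isclose(row["before_mean"], np.mean(b))
                    and np.isclose(row["after_mean"], np.mean(a))):
                return False
        return True


def _deviation_arrays(tests, controls, joint: JointSpec):
    ang = np.empty((len(tests), 3))
    rmse = np.empty(len(tests))
    for i, (t, c) in enumerate(zip(tests, controls)):
        a, r = measure_joint_deviation(t, c, joint)
        ang[i] = a.as_array
        rmse[i] = r
    return np.abs(ang), rmse


def _report_rows(joint_name: str, before, after, n_perm, seed, tag):
    ang_b, rmse_b = before
    ang_a, rmse_a = after
    rows, cases = [], {}
    for j, metric in enumerate(ANGLE_METRICS + ("rmse_mm",)):
        b = rmse_b if metric == "rmse_mm" else ang_b[:, j]
        a = rmse_a if metric == "rmse_mm" else ang_a[:, j]
        p = paired_permutation_pvalue(b, a, n_perm=n_perm, seed=seed + j)
        rows.append({"experiment": tag, "joint": joint_name, "metric": metric,
                     "before_mean": b.mean(), "before_sd": b.std(ddof=1),
                     "after_mean": a.mean(), "after_sd": a.std(ddof=1),
                     "p_value": p, "n": len(b)})
        cases[(joint_name, metric)] = (b, a)
    return rows, cases


def validate_mock(pipeline: DenoisePipeline, mock, method: str = "offline",
                  n_perm: int = 10000, seed: int = 0) -> ValidationReport:
    """Angular/RMSE deviations of mock shapes from their unposed controls,
    before and after denoising (the virtual-cases experiment)."""
    if not mock.posed:
        raise ValueError("empty mock set")
    rows, cases = [], {}
    for joint in mock.joints:
        before = _deviation_arrays(mock.posed, mock.controls, joint)
        denoised = [denoise(pipeline, joint.name, s, method=method)
                    for s in mock.posed]
        after = _deviation_arrays(denoised, mock.controls, joint)
        r, c = _report_rows(joint.name, before, after, n_perm, seed, "mock")
        rows += r
        cases.update(c)
    return ValidationReport(pd.DataFrame(rows), cases, "mock")


def validate_rescan(pipeline: DenoisePipeline, pairs,
                    method: str = "offline", n_perm: int = 10000,
                    seed: int = 0) -> ValidationReport:
    """Within-couple deviations of repeat scans, before and after denoising.

    Rescan couples share anatomy and neutral alignment but not pose, so the
    second scan of each couple serves as the control for the first; after
    correction both scans should coincide.  The control is first superimposed
    on the articulated model mean so the angle decomposition axes are
    anatomical rather than inherited from an arbitrary scanner frame.
    """
    if not pairs:
        raise ValueError("no rescan pairs")
    rows, cases = [], {}

    def rf(record):
        c = record.construct
        return mirror(c) if c.side == "left" else c

    from .shape_model import align_to_model
    for name, joint in pipeline.joints.items():
        parts = list(joint.parts)
        art = pipeline.articulated_models[name]
        a_list = [rf(a).extract_parts(parts) for a, _ in pairs]
        b_list = [align_to_model(art, rf(b).extract_parts(parts))
                  for _, b in pairs]
        before = _deviation_arrays(a_list, b_list, joint)
        da = [denoise(pipeline, name, s, method=method) for s in a_list]
        db = [denoise(pipeline, name, s, method=method) for s in b_list]
        after = _deviation_arrays(da, db, joint)
        r, c = _report_rows(name, before, after, n_perm, seed, "rescan")
        rows += r
        cases.update(c)
    return ValidationReport(pd.DataFrame(rows), cases, "rescan")


def error_evolution_curve(pipeline: DenoisePipeline, joint_name: str,
                          ks=None, path: str = "regressed") -> pd.DataFrame:
    """Mean L/R dissimilarity against PLS component count."""
    return error_evolution(pipeline, joint_name, ks=ks, path=path)
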