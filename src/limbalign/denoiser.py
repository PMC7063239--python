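"""The pose-denoising pipeline for articulated shape models.

The central idea: per-bone ("decoupled") models are pose-free by
construction, because every bone is aligned on its own, while models of
multi-bone joint constructs aligned as a whole ("articulated") retain the
relative bone pose at scan time as apparent shape variance.  Since pose is
noise independent of anatomy, a PLS regression from decoupled scores to
articulated scores averages pose out, yielding the neutrally aligned
("regressed") construct; superimposing each subject's original bones back
onto it ("recoupling") restores the anatomical detail lost to regression
smoothing.  A second PLS map from articulated scores straight to recoupled
scores provides one-step ("instant") denoising of new data.

The number of regression components is selected by error evolution: the
left/right dissimilarity of predicted constructs is dominated by residual
pose (anatomy is nearly symmetric, scan pose is not), so the component
count minimizing it removes the most pose, and larger counts reintroduce
pose through overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import LandmarkShape, generalized_procrustes, mirror, procrustes_align
from .latent_regression import PLSModel, fit_pls
from .shape_model import (ShapeModel, align_to_model, fit_ssm, project,
                          reconstruct)


@dataclass(eq=False)
class JointSpec:
    """A two-bone joint: part labels, idealized center and distal chain.

    ``center_point_ids`` name the articular landmarks whose centroid defines
    the joint center on any construct carrying them, so the center scales
    and moves with the subject.  ``distal_chain`` lists every part distal to
    the joint in a full limb (used when rotating through the joint).
    """

    name: str
    proximal: str
    distal: str
    center_point_ids: np.ndarray
    joint_type: str = "spherical"
    template_center: np.ndarray | None = None
    distal_chain: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.center_point_ids = np.asarray(self.center_point_ids)
        if not self.distal_chain:
            self.distal_chain = (self.distal,)

    @property
    def parts(self) -> tuple[str, str]:
        return (self.proximal, self.distal)

    def center(self, shape: LandmarkShape) -> np.ndarray:
        mask = np.isin(shape.point_ids, self.center_point_ids)
        if not mask.any():
            raise KeyError(f"joint {self.name}: no center landmarks in shape")
        return shape.coords[mask].mean(axis=0)


@dataclass
class ScanRecord:
    """One scan of one side of one subject: the full construct, as acquired."""

    subject_id: int
    side: str
    scan_index: int
    construct: LandmarkShape


@dataclass
class PipelineConfig:
    variance_kept: float = 0.98
    variance_kept_recoupled: float = 0.995
    k_range: tuple[int, ...] | None = None
    k_instant: int = 200
    allow_scale: bool = False
    gpa_tol: float = 1e-8
    gpa_max_iter: int = 100
    tie_tolerance: float = 0.01  # smallest k within 1% of the minimum wins


@dataclass(eq=False)
class DenoisePipeline:
    """Trained per-bone, per-joint models plus the regression maps."""

    joints: dict[str, JointSpec]
    bone_parts: tuple[str, ...]
    bone_models: dict[str, ShapeModel]
    articulated_models: dict[str, ShapeModel]
    regressed_models: dict[str, PLSModel]
    recoupled_models: dict[str, ShapeModel]
    instant_models: dict[str, PLSModel]
    k_star: dict[str, int]
    error_curves: dict[str, pd.DataFrame]
    training: dict[str, dict] = field(default_factory=dict)
    config: PipelineConfig = field(default_factory=PipelineConfig)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _to_right_frame(record: ScanRecord) -> LandmarkShape:
    c = record.construct
    return mirror(c) if c.side == "left" else c


def build_decoupled_models(constructs: list[LandmarkShape], bone_parts,
                           config: PipelineConfig):
    """GPA + PCA per isolated bone; pose is destroyed by construction."""
    models: dict[str, ShapeModel] = {}
    aligned_bones: dict[str, list[LandmarkShape]] = {}
    scores: dict[str, np.ndarray] = {}
    for part in bone_parts:
        shapes = [c.extract_parts(part) for c in constructs]
        aligned, _, _ = generalized_procrustes(shapes, allow_scale=config.allow_scale,
                                               tol=config.gpa_tol,
                                               max_iter=config.gpa_max_iter)
        m = fit_ssm(aligned, variance_kept=config.variance_kept,
                    model_id=f"decoupled:{part}")
        models[part] = m
        aligned_bones[part] = aligned
        scores[part] = np.stack([project(m, s).b for s in aligned])
    return models, aligned_bones, scores


def build_articulated_model(constructs: list[LandmarkShape], joint: JointSpec,
                            config: PipelineConfig):
    """GPA + PCA of whole two-bone constructs; relative pose survives."""
    shapes = [c.extract_parts(list(joint.parts)) for c in constructs]
    aligned, _, _ = generalized_procrustes(shapes, allow_scale=config.allow_scale,
                                           tol=config.gpa_tol,
                                           max_iter=config.gpa_max_iter)
    m = fit_ssm(aligned, variance_kept=config.variance_kept,
                model_id=f"articulated:{joint.name}")
    scores = np.stack([project(m, s).b for s in aligned])
    return m, aligned, scores


def _lr_pairs(rows: pd.DataFrame) -> list[tuple[int, int]]:
    """Per subject, the row indices of the first right and first left scan."""
    pairs = []
    for _, grp in rows.groupby("subject_id", sort=True):
        rights = grp[grp.side == "right"].index
        lefts = grp[grp.side == "left"].index
        if len(rights) and len(lefts):
            pairs.append((int(rights[0]), int(lefts[0])))
    return pairs


def _mean_lr_dissimilarity(model: ShapeModel, yhat: np.ndarray,
                           pairs: list[tuple[int, int]],
                           row_pos: dict[int, int]) -> float:
    vals = []
    for i_r, i_l in pairs:
        right = reconstruct(model, yhat[row_pos[i_r]])
        left = reconstruct(model, yhat[row_pos[i_l]])
        _, _, rmse = procrustes_align(left, right)
        vals.append(rmse)
    return float(np.mean(vals))


def select_components(X: np.ndarray, Y: np.ndarray, response_model: ShapeModel,
                      rows: pd.DataFrame, k_range, config: PipelineConfig,
                      ) -> tuple[int, pd.DataFrame]:
    """Error-evolution selection of the PLS component count.

    For each candidate k the regression is refitted and the mean
    dissimilarity between the predicted right and (mirrored) left constructs
    of every subject is recorded; the smallest k within ``tie_tolerance`` of
    the minimum wins.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    pairs = _lr_pairs(rows)
    if not pairs:
        raise ValueError("component selection needs subjects with both sides")
    used = sorted({i for pair in pairs for i in pair})
    row_pos = {i: p for p, i in enumerate(used)}
    curve = []
    for k in k_range:
        m = fit_pls(X, Y, k)
        yhat = m.predict(X[used])
        curve.append(_mean_lr_dissimilarity(response_model, yhat, pairs, row_pos))
    curve = np.asarray(curve)
    thresh = curve.min() * (1.0 + config.tie_tolerance)
    k_star = int(k_range[int(np.argmax(curve <= thresh))])
    return k_star, pd.DataFrame({"k": k_range, "lr_dissimilarity_mm": curve})


def recouple(regressed: LandmarkShape,
             original_bones: dict[str, LandmarkShape]) -> LandmarkShape:
    """Rigidly superimpose each original bone onto the regressed construct.

    The output keeps the regressed relative placement of the bones but each
    bone's geometry is the subject's own, bit-identical up to the rigid
    transform (no scaling), preserving all anatomical detail.
    """
    coords = regressed.coords.copy()
    for part in regressed.parts:
        if part not in original_bones:
            raise KeyError(f"recouple: missing original bone {part!r}")
        target = regressed.extract_parts(part)
        bone = original_bones[part]
        _, placed, _ = procrustes_align(bone, target, allow_scale=False)
        coords[regressed.part_mask(part)] = placed.coords
    return regressed.with_coords(coords)


def train_pipeline(records: list[ScanRecord], joints: dict[str, JointSpec],
                   bone_parts, config: PipelineConfig | None = None,
                   ) -> DenoisePipeline:
    """Fit the full denoising pipeline on a set of scans."""
    config = config or PipelineConfig()
    if not records:
        raise ValueError("no training records")
    constructs = [_to_right_frame(r) for r in records]
    rows = pd.DataFrame({"subject_id": [r.subject_id for r in records],
                         "side": [r.side for r in records],
                         "scan_index": [r.scan_index for r in records]})

    bone_models, aligned_bones, bone_scores = build_decoupled_models(
        constructs, bone_parts, config)

    articulated_models, regressed_models, recoupled_models = {}, {}, {}
    instant_models, k_stars, curves, training = {}, {}, {}, {}
    for name, joint in joints.items():
        art_model, art_aligned, y_art = build_articulated_model(constructs, joint, config)
        x = np.hstack([bone_scores[joint.proximal], bone_scores[joint.distal]])
        rank = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
        k_range = config.k_range or range(1, min(8, rank) + 1)
        k_star, curve = select_components(x, y_art, art_model, rows, k_range, config)
        pls = fit_pls(x, y_art, k_star)
        yhat = pls.predict(x)
        rec_constructs = []
        for i in range(len(records)):
            regressed = reconstruct(art_model, yhat[i])
            bones = {p: aligned_bones[p][i] for p in joint.parts}
            rec_constructs.append(recouple(regressed, bones))
        rec_aligned, _, _ = generalized_procrustes(
            rec_constructs, allow_scale=config.allow_scale,
            tol=config.gpa_tol, max_iter=config.gpa_max_iter)
        rec_model = fit_ssm(rec_aligned, variance_kept=config.variance_kept_recoupled,
                            model_id=f"recoupled:{name}")
        y_rec = np.stack([project(rec_model, s).b for s in rec_aligned])
        k_inst = min(config.k_instant, y_art.shape[1],
                     int(np.linalg.matrix_rank(y_art - y_art.mean(axis=0))))
        instant = fit_pls(y_art, y_rec, k_inst)

        articulated_models[name] = art_model
        regressed_models[name] = pls
        recoupled_models[name] = rec_model
        instant_models[name] = instant
        k_stars[name] = k_star
        curves[name] = curve
        training[name] = {"X": x, "Y_art": y_art, "Y_rec": y_rec,
                          "rows": rows, "k_instant": k_inst}

    return DenoisePipeline(joints=dict(joints), bone_parts=tuple(bone_parts),
                           bone_models=bone_models,
                           articulated_models=articulated_models,
                           regressed_models=regressed_models,
                           recoupled_models=recoupled_models,
                           instant_models=instant_models,
                           k_star=k_stars, error_curves=curves,
                           training=training, config=config)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _decoupled_scores_for(pipeline: DenoisePipeline, joint: JointSpec,
                          construct: LandmarkShape):
    bones = {}
    blocks = []
    for part in joint.parts:
        model = pipeline.bone_models[part]
        aligned = align_to_model(model, construct.extract_parts(part))
        bones[part] = aligned
        blocks.append(project(model, aligned).b)
    return np.concatenate(blocks), bones


def _as_right_joint_construct(pipeline: DenoisePipeline, joint: JointSpec,
                              construct: LandmarkShape) -> LandmarkShape:
    c = mirror(construct) if construct.side == "left" else construct
    return c.extract_parts(list(joint.parts))


def predict_neutral(pipeline: DenoisePipeline, joint_name: str,
                    construct: LandmarkShape) -> LandmarkShape:
    """Regressed (smoothed, neutrally aligned) construct for a subject."""
    joint = pipeline.joints[joint_name]
    c = _as_right_joint_construct(pipeline, joint, construct)
    x, _ = _decoupled_scores_for(pipeline, joint, c)
    yhat = pipeline.regressed_models[joint_name].predict(x)
    return reconstruct(pipeline.articulated_models[joint_name], yhat)


def denoise(pipeline: DenoisePipeline, joint_name: str,
            construct: LandmarkShape, method: str = "offline") -> LandmarkShape:
    """Pose-corrected construct, by the offline or the instant route.

    offline: decoupled scores -> regressed construct -> recoupling with the
    subject's own bones (pose-invariant for fixed anatomy).
    instant: articulated scores -> recoupled scores in one PLS step.
    """
    joint = pipeline.joints[joint_name]
    c = _as_right_joint_construct(pipeline, joint, construct)
    if method == "instant":
        art = pipeline.articulated_models[joint_name]
        b = project(art, align_to_model(art, c)).b
        y = pipeline.instant_models[joint_name].predict(b)
        return reconstruct(pipeline.recoupled_models[joint_name], y)
    if method != "offline":
        raise ValueError(f"unknown method {method!r}")
    joint_spec = pipeline.joints[joint_name]
    x, bones = _decoupled_scores_for(pipeline, joint_spec, c)
    yhat = pipeline.regressed_models[joint_name].predict(x)
    regressed = reconstruct(pipeline.articulated_models[joint_name], yhat)
    return recouple(regressed, bones)


def chain_joints(pipeline: DenoisePipeline, limb: LandmarkShape,
                 order=("ankle", "knee", "hip"), method: str = "offline",
                 ) -> tuple[LandmarkShape, dict[str, float]]:
    """Assemble a full neutral limb from consecutively denoised joints.

    Each joint's two-bone construct is denoised separately; consecutive
    constructs are connected by rigid superimposition of the shared bone.
    Residual misfit of each shared bone is reported per joint (mm RMSE).
    """
    for name in order:
        if name not in pipeline.joints:
            raise KeyError(f"joint {name!r} not trained")
    limb_rf = mirror(limb) if limb.side == "left" else limb
    denoised = {name: denoise(pipeline, name, limb_rf, method=method)
                for name in order}

    assembled: dict[str, LandmarkShape] = {}
    residuals: dict[str, float] = {}
    first = denoised[order[0]]
    for part in first.parts:
        assembled[part] = first.extract_parts(part)
    residuals[order[0]] = 0.0
    for name in order[1:]:
        c = denoised[name]
        joint = pipeline.joints[name]
        shared = joint.proximal if joint.proximal in assembled else joint.distal
        if shared not in assembled:
            raise KeyError(f"chain order {order} has no shared bone at {name}")
        new_part = joint.distal if shared == joint.proximal else joint.proximal
        tf, _, rmse = procrustes_align(c.extract_parts(shared), assembled[shared])
        residuals[name] = rmse
        moved = c.with_coords(tf.apply(c.coords), frame=assembled[shared].frame)
        assembled[new_part] = moved.extract_parts(new_part)

    parts_in_order = [p for p in pipeline.bone_parts if p in assembled]
    coords = np.vstack([assembled[p].coords for p in parts_in_order])
    ids = np.concatenate([assembled[p].point_ids for p in parts_in_order])
    labels = np.concatenate([assembled[p].part_labels for p in parts_in_order])
    shape = LandmarkShape(coords, ids, labels, side="right",
                          frame=first.frame)
    return shape, residuals


def error_evolution(pipeline: DenoisePipeline, joint_name: str,
                    ks=None, path: str = "regressed") -> pd.DataFrame:
    """Mean L/R dissimilarity versus component count for either mapping.

    ``path="regressed"`` re-evaluates the decoupled->articulated mapping
    (the curve used for selection); ``path="instant"`` evaluates the
    articulated->recoupled mapping, which does not reintroduce pose.
    """
    tr = pipeline.training.get(joint_name)
    if tr is None:
        raise ValueError("pipeline carries no training data")
    if path == "regressed":
        if ks is None:
            return pipeline.error_curves[joint_name].copy()
        _, curve = select_components(tr["X"], tr["Y_art"],
                                     pipeline.articulated_models[joint_name],
                                     tr["rows"], ks, pipeline.config)
        return curve
    if path != "instant":
        raise ValueError(f"unknown path {path!r}")
    rows = tr["rows"]
    pairs = _lr_pairs(rows)
    used = sorted({i for pair in pairs for i in pair})
    row_pos = {i: p for p, i in enumerate(used)}
    rec_model = pipeline.recoupled_models[joint_name]
    if ks is None:
        ks = range(1, tr["k_instant"] + 1)
    vals = []
    for k in ks:
        m = fit_pls(tr["Y_art"], tr["Y_rec"], int(k))
        yhat = m.predict(tr["Y_art"][used])
        vals.append(_mean_lr_dissimilarity(rec_model, yhat, pairs, row_pos))
    return pd.DataFrame({"k": list(ks), "lr_dissimilarity_mm": vals})
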