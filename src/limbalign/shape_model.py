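"""Point-distribution (PCA) shape models over aligned landmark sets.

A statistical shape model represents every aligned configuration as
``S = S_mean + P @ b`` with ``P`` the matrix of unit eigenvectors of the
sample covariance of the flattened landmark coordinates and ``b`` the
per-subject weight (score) vector.  This module fits such models, projects
shapes into and out of score space, and provides the two model-level
statistics used downstream: the compactness curve (cumulative explained
variance per mode) and the percentage of variance in a dataset that a model
cannot explain, which is the pose-variance estimator applied to articulated
data versus a pose-free model.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import LandmarkShape, procrustes_align


@dataclass
class ScoreVector:
    """Weights ``b`` of a shape in a model's eigenvector basis."""

    b: np.ndarray
    model_id: str = ""

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, float).reshape(-1)


@dataclass(eq=False)
class ShapeModel:
    """Linear point-distribution model (mean, eigenvectors, eigenvalues).

    ``components`` holds the ``t`` retained unit eigenvectors as columns;
    ``eigenvalues`` the matching variances (mm^2).  ``all_eigenvalues`` keeps
    the full spectrum so compactness can be reported over every mode even
    when only ``t`` are retained for reconstruction.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    all_eigenvalues: np.ndarray
    t: int
    n_train: int
    point_ids: np.ndarray
    part_labels: np.ndarray
    meta: dict = field(default_factory=dict)
    model_id: str = ""

    @property
    def mean_shape(self) -> LandmarkShape:
        return LandmarkShape(self.mean.reshape(-1, 3), self.point_ids,
                             self.part_labels, side=self.meta.get("side", "right"),
                             frame="gpa-aligned")

    def template(self) -> LandmarkShape:
        return self.mean_shape


def fit_ssm(aligned: list[LandmarkShape], variance_kept: float = 0.98,
            t: int | None = None, meta: dict | None = None,
            model_id: str = "") -> ShapeModel:
    """Fit a PCA shape model to GPA-aligned shapes.

    Modes are computed by SVD of the centered data matrix (covariance with
    the n-1 divisor).  Retention is by cumulative explained variance
    (``variance_kept``) unless an explicit mode count ``t`` is given.  Each
    component's sign is fixed so its largest-magnitude loading is positive.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 training shapes")
    for s in aligned:
        if s.frame != "gpa-aligned":
            raise ValueError(f"shape frame {s.frame!r} is not 'gpa-aligned'")
        if not aligned[0].same_points(s):
            raise ValueError("training shapes have differing point sets")
    data = np.stack([s.vector for s in aligned])
    mean = data.mean(axis=0)
    x = data - mean
    n = data.shape[0]
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    eig = sv ** 2 / (n - 1)
    rank_mask = eig > max(eig[0], 1.0) * 1e-12
    eig = eig[rank_mask]
    vt = vt[rank_mask]
    if t is not None:
        t_keep = int(min(t, len(eig)))
    else:
        if not 0 < variance_kept <= 1:
            raise ValueError("variance_kept must be in (0, 1]")
        cum = np.cumsum(eig) / eig.sum()
        t_keep = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    comps = vt[:t_keep].copy()
    for row in comps:  # deterministic sign convention
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return ShapeModel(mean=mean, components=comps.T, eigenvalues=eig[:t_keep],
                      all_eigenvalues=eig, t=t_keep, n_train=n,
                      point_ids=aligned[0].point_ids,
                      part_labels=aligned[0].part_labels,
                      meta={"side": aligned[0].side, **(meta or {})},
                      model_id=model_id)


def project(model: ShapeModel, shape: LandmarkShape) -> ScoreVector:
    """Orthogonal projection ``b = P.T @ (S - S_mean)`` (shape pre-aligned)."""
    vec = shape.vector
    if vec.shape[0] != model.mean.shape[0]:
        raise ValueError("shape dimension does not match model")
    return ScoreVector(model.components.T @ (vec - model.mean), model.model_id)


def reconstruct(model: ShapeModel, b: ScoreVector | np.ndarray) -> LandmarkShape:
    """Exact linear reconstruction ``S_mean + P @ b``."""
    arr = b.b if isinstance(b, ScoreVector) else np.asarray(b, float).reshape(-1)
    if arr.shape[0] != model.t:
        raise ValueError(f"score length {arr.shape[0]} != t={model.t}")
    vec = model.mean + model.components @ arr
    return LandmarkShape.from_vector(model.mean_shape, vec)


def align_to_model(model: ShapeModel, shape: LandmarkShape,
                   allow_scale: bool = False) -> LandmarkShape:
    """Rigidly superimpose a raw shape onto the model mean."""
    _, aligned, _ = procrustes_align(shape, model.mean_shape, allow_scale=allow_scale)
    return aligned


def align_and_project(model: ShapeModel, shape: LandmarkShape,
                      allow_scale: bool = False) -> ScoreVector:
    return project(model, align_to_model(model, shape, allow_scale=allow_scale))


def score_matrix(model: ShapeModel, shapes: list[LandmarkShape],
                 align: bool = False) -> np.ndarray:
    """Stack scores of many shapes into an (m, t) matrix."""
    if align:
        shapes = [align_to_model(model, s) for s in shapes]
    return np.stack([project(model, s).b for s in shapes])


def compactness_curve(model: ShapeModel) -> np.ndarray:
    """Cumulative explained-variance fractions over all modes (ends at 1)."""
    lam = model.all_eigenvalues
    return np.cumsum(lam) / lam.sum()


def explained_variance_fractions(model: ShapeModel) -> np.ndarray:
    lam = model.all_eigenvalues
    return lam / lam.sum()


def unexplained_variance(data: list[LandmarkShape], model: ShapeModel) -> float:
    """Percent of a dataset's variance the model cannot represent.

    Each datum is rigidly aligned (no scale) to the model mean, projected
    onto the retained modes, and the squared residual accumulated; the
    denominator is the total variance of the aligned data about their own
    mean.  Data already carrying the ``gpa-aligned`` frame tag are projected
    as-is, mirroring how training scores are computed.  Applied to
    articulated (posed) data with a pose-free model this estimates the
    share of apparent shape variance contributed by pose.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    vecs = []
    for s in data:
        al = s if s.frame == "gpa-aligned" else align_to_model(model, s)
        vecs.append(al.vector)
    v = np.stack(vecs)
    centered_model = v - model.mean
    resid = centered_model - centered_model @ model.components @ model.components.T
    num = (resid ** 2).sum()
    den = ((v - v.mean(axis=0)) ** 2).sum()
    if den == 0:
        return 0.0
    return float(100.0 * num / den)


# ---------------------------------------------------------------------------
# Serialization (single-file .npz container with a JSON metadata block)
# ---------------------------------------------------------------------------

_LAYOUT_VERSION = 1


def model_to_arrays(model: ShapeModel, prefix: str = "") -> dict[str, np.ndarray]:
    meta = {"layout": _LAYOUT_VERSION, "t": model.t, "n_train": model.n_train,
            "model_id": model.model_id, "meta": model.meta}
    return {
        f"{prefix}mean": model.mean,
        f"{prefix}components": model.components,
        f"{prefix}eigenvalues": model.eigenvalues,
        f"{prefix}all_eigenvalues": model.all_eigenvalues,
        f"{prefix}point_ids": model.point_ids.astype(str),
        f"{prefix}part_labels": model.part_labels.astype(str),
        f"{prefix}meta_json": np.array(json.dumps(meta)),
    }


def model_from_arrays(arrays, prefix: str = "") -> ShapeModel:
    meta = json.loads(str(arrays[f"{prefix}meta_json"]))
    return ShapeModel(mean=np.asarray(arrays[f"{prefix}mean"]),
                      components=np.asarray(arrays[f"{prefix}components"]),
                      eigenvalues=np.asarray(arrays[f"{prefix}eigenvalues"]),
                      all_eigenvalues=np.asarray(arrays[f"{prefix}all_eigenvalues"]),
                      t=int(meta["t"]), n_train=int(meta["n_train"]),
                      point_ids=np.asarray(arrays[f"{prefix}point_ids"]),
                      part_labels=np.asarray(arrays[f"{prefix}part_labels"]),
                      meta=meta["meta"], model_id=meta["model_id"])


def save_model(model: ShapeModel, path) -> None:
    np.savez_compressed(path, **model_to_arrays(model))


def load_model(path) -> ShapeModel:
    with np.load(path, allow_pickle=False) as arrays:
        return model_from_arrays(arrays)
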