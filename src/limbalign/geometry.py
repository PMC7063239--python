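"""Rigid and similarity superimposition of homologous landmark configurations.

Alignment primitives used by every other module: pairwise Procrustes
superimposition (ordinary least squares, optionally similarity), generalized
Procrustes alignment (GPA) of a whole sample, sagittal mirroring for
left/right pooling, and conversions between rotation matrices and clinical
joint angles.

Coordinate convention (template frame): +X anterior, +Y subject-left
(medio-lateral), +Z superior (longitudinal).  Joint angles are intrinsic
rotations applied in the order flexion (about Y), abduction (about X),
endorotation (about Z); the tag ``"YXZ-intrinsic"`` records this convention
on every :class:`PoseAngles` instance.  The sagittal plane is the X–Z plane,
so mirroring reflects the Y coordinate by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

EULER_CONVENTION = "YXZ-intrinsic"
_SCIPY_SEQ = "YXZ"  # uppercase = intrinsic in scipy


class CorrespondenceError(ValueError):
    """Point sets do not share identifiers/ordering."""


@dataclass(eq=False)
class LandmarkShape:
    """Ordered dense landmark coordinates for one structure.

    Parameters
    ----------
    coords : (n, 3) float array, millimetres.
    point_ids : (n,) array of stable landmark identifiers.
    part_labels : (n,) array assigning each point to a bone ("femur", ...).
    side : "right" or "left".
    frame : coordinate-frame tag ("raw", "gpa-aligned" or "template").
    """

    coords: np.ndarray
    point_ids: np.ndarray
    part_labels: np.ndarray
    side: str = "right"
    frame: str = "raw"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.point_ids = np.asarray(self.point_ids)
        self.part_labels = np.asarray(self.part_labels)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        n = self.coords.shape[0]
        if n < 4:
            raise ValueError(f"need at least 4 landmarks, got {n}")
        if len(self.point_ids) != n or len(self.part_labels) != n:
            raise ValueError("point_ids/part_labels length mismatch")
        if len(np.unique(self.point_ids)) != n:
            raise ValueError("duplicate point_ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def vector(self) -> np.ndarray:
        """Row-major flattened coordinates, shape (3n,)."""
        return self.coords.reshape(-1)

    @property
    def parts(self) -> list[str]:
        seen: list[str] = []
        for p in self.part_labels:
            if p not in seen:
                seen.append(str(p))
        return seen

    def part_mask(self, part: str) -> np.ndarray:
        return self.part_labels == part

    def extract_parts(self, parts) -> "LandmarkShape":
        if isinstance(parts, str):
            parts = [parts]
        mask = np.isin(self.part_labels, list(parts))
        if not mask.any():
            raise KeyError(f"parts {parts!r} not present (have {self.parts})")
        return LandmarkShape(self.coords[mask], self.point_ids[mask],
                             self.part_labels[mask], self.side, self.frame)

    def with_coords(self, coords: np.ndarray, frame: str | None = None) -> "LandmarkShape":
        return LandmarkShape(np.asarray(coords, float), self.point_ids,
                             self.part_labels, self.side,
                             self.frame if frame is None else frame)

    @classmethod
    def from_vector(cls, template: "LandmarkShape", vec: np.ndarray,
                    frame: str = "gpa-aligned") -> "LandmarkShape":
        coords = np.asarray(vec, float).reshape(-1, 3)
        return template.with_coords(coords, frame=frame)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def centroid_size(self) -> float:
        """Square root of the summed squared distances to the centroid (mm)."""
        return float(np.sqrt(((self.coords - self.centroid) ** 2).sum()))

    def same_points(self, other: "LandmarkShape") -> bool:
        return (self.n_points == other.n_points
                and np.array_equal(self.point_ids, other.point_ids))


@dataclass
class RigidTransform:
    """Similarity transform ``x -> scale * R @ x + t`` (scale = 1 when rigid)."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0
    reflection_used: bool = False

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.scale * coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class PoseAngles:
    """Clinical joint angles in degrees under a declared Euler convention."""

    flexion: float
    abduction: float
    endorotation: float
    convention: str = EULER_CONVENTION
    gimbal_lock: bool = False

    def __post_init__(self) -> None:
        for name in ("flexion", "abduction", "endorotation"):
            v = float(getattr(self, name))
            if not -180.0 < v <= 180.0 + 1e-9:
                raise ValueError(f"{name}={v} outside (-180, 180]")
            setattr(self, name, v)

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.flexion, self.abduction, self.endorotation])

    @classmethod
    def from_array(cls, arr, **kw) -> "PoseAngles":
        f, a, e = np.asarray(arr, float)
        return cls(f, a, e, **kw)


# ---------------------------------------------------------------------------
# Pairwise Procrustes
# ---------------------------------------------------------------------------

def _check_nondegenerate(centered: np.ndarray, what: str) -> None:
    # rank >= 2 is required for a well-defined rotation in 3D
    s = np.linalg.svd(centered, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    if (s > 1e-9 * scale).sum() < 2:
        raise np.linalg.LinAlgError(
            f"{what} landmarks are coincident or collinear (rank < 2)")


def procrustes_align(source: LandmarkShape, target: LandmarkShape,
                     allow_scale: bool = False,
                     allow_reflection: bool = False,
                     ) -> tuple[RigidTransform, LandmarkShape, float]:
    """Least-squares superimposition of ``source`` onto ``target``.

    Returns the optimal transform within the allowed class (rigid by
    default; similarity when ``allow_scale``), the transformed source and
    the root-mean-square residual per landmark (mm).
    """
    if not source.same_points(target):
        raise CorrespondenceError("source/target point sets differ")
    mu_s = source.coords.mean(axis=0)
    mu_t = target.coords.mean(axis=0)
    a = source.coords - mu_s
    b = target.coords - mu_t
    _check_nondegenerate(a, "source")
    _check_nondegenerate(b, "target")

    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    reflection_used = False
    sign = np.ones(3)
    if d < 0:
        if allow_reflection:
            reflection_used = True
        else:
            sign[-1] = -1.0
    rot = vt.T @ np.diag(sign) @ u.T
    scale = 1.0
    if allow_scale:
        scale = float((s * sign).sum() / (a ** 2).sum())
    translation = mu_t - scale * rot @ mu_s
    tf = RigidTransform(rot, translation, scale, reflection_used)
    aligned = source.with_coords(tf.apply(source.coords), frame=target.frame)
    rmse = float(np.sqrt(((aligned.coords - target.coords) ** 2).sum(axis=1).mean()))
    return tf, aligned, rmse


# ---------------------------------------------------------------------------
# Generalized Procrustes alignment
# ---------------------------------------------------------------------------

def generalized_procrustes(shapes: list[LandmarkShape],
                           allow_scale: bool = False,
                           tol: float = 1e-8,
                           max_iter: int = 100,
                           ) -> tuple[list[LandmarkShape], LandmarkShape, int]:
    """Iterative superimposition of a sample of shapes onto their consensus.

    All shapes are aligned (translation + rotation, optionally scale) to the
    running consensus, which is re-estimated as the arithmetic mean until its
    RMS change drops below ``tol`` (mm).  The total residual is non-increasing
    across iterations; a violation beyond numerical noise raises a warning.
    """
    if len(shapes) < 2:
        raise ValueError("need at least 2 shapes for GPA")
    ref = shapes[0]
    for s in shapes[1:]:
        if not ref.same_points(s):
            raise CorrespondenceError("shapes have differing point sets")

    centered = [s.coords - s.coords.mean(axis=0) for s in shapes]
    consensus = np.mean(centered, axis=0)
    consensus_shape = ref.with_coords(consensus, frame="gpa-aligned")
    aligned = [s.with_coords(c, frame="gpa-aligned") for s, c in zip(shapes, centered)]
    prev_residual = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_aligned = []
        residual = 0.0
        for s in aligned:
            _, al, rmse = procrustes_align(s, consensus_shape, allow_scale=allow_scale)
            new_aligned.append(al)
            residual += rmse ** 2 * s.n_points
        aligned = new_aligned
        new_consensus = np.mean([s.coords for s in aligned], axis=0)
        if allow_scale:
            # pin consensus size to avoid the shrinking degeneracy
            size = np.sqrt(((new_consensus - new_consensus.mean(0)) ** 2).sum())
            ref_size = np.sqrt(((consensus - consensus.mean(0)) ** 2).sum())
            if size > 0:
                new_consensus *= ref_size / size if n_iter > 1 else 1.0
        if residual > prev_residual * (1 + 1e-9) + 1e-9:
            warnings.warn("GPA residual increased between iterations "
                          f"({prev_residual:.6g} -> {residual:.6g})")
        prev_residual = residual
        change = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        consensus_shape = ref.with_coords(consensus, frame="gpa-aligned")
        if change < tol:
            break
    else:
        warnings.warn(f"GPA did not converge in {max_iter} iterations")
    return aligned, consensus_shape, n_iter


# ---------------------------------------------------------------------------
# Mirroring
# ---------------------------------------------------------------------------

def mirror(shape: LandmarkShape, relabel_map: dict | None = None,
           axis: int = 1) -> LandmarkShape:
    """Reflect a shape across the sagittal plane and flip its side flag.

    With the template frame used throughout (+Y medio-lateral) the sagittal
    plane has normal +Y, hence ``axis=1``.  ``relabel_map`` is a bijection on
    point ids pairing left/right homologues; ``None`` means every landmark is
    its own homologue (the single-limb template case), so only the reflection
    is applied.
    """
    coords = shape.coords.copy()
    coords[:, axis] = -coords[:, axis]
    ids = shape.point_ids
    order = np.arange(shape.n_points)
    if relabel_map is not None:
        if set(relabel_map.keys()) != set(relabel_map.values()) or \
                len(set(relabel_map.values())) != len(relabel_map):
            raise ValueError("relabel_map must be a bijection on point_ids")
        new_ids = np.array([relabel_map[i] for i in ids.tolist()])
        # re-order rows so the output follows the canonical id ordering
        pos = {pid: k for k, pid in enumerate(new_ids.tolist())}
        try:
            order = np.array([pos[pid] for pid in ids.tolist()])
        except KeyError as exc:
            raise ValueError(f"relabel_map does not cover point id {exc}") from exc
    other = "left" if shape.side == "right" else "right"
    return LandmarkShape(coords[order], ids, shape.part_labels[order],
                         side=other, frame=shape.frame)


# ---------------------------------------------------------------------------
# Euler angles
# ---------------------------------------------------------------------------

def rotation_from_euler(angles: PoseAngles | np.ndarray) -> np.ndarray:
    """Rotation matrix for (flexion, abduction, endorotation) degrees."""
    if isinstance(angles, PoseAngles):
        arr = angles.as_array
    else:
        arr = np.asarray(angles, float)
    return Rotation.from_euler(_SCIPY_SEQ, arr, degrees=True).as_matrix()


def euler_from_rotation(rotation: np.ndarray) -> PoseAngles:
    """Decompose a proper rotation into flexion/abduction/endorotation.

    Near gimbal lock (|abduction| -> 90 deg) the flexion/endorotation split is
    degenerate; scipy's tie-break (endorotation forced to 0) is kept and the
    result is flagged.
    """
    rotation = np.asarray(rotation, float)
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-6) or \
            np.linalg.det(rotation) < 0:
        raise ValueError("input is not a proper rotation matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at exact gimbal lock
        f, a, e = Rotation.from_matrix(rotation).as_euler(_SCIPY_SEQ, degrees=True)
    lock = bool(abs(abs(a) - 90.0) < 1e-6)
    if lock:
        warnings.warn("gimbal lock: |abduction| = 90 deg, "
                      "flexion/endorotation resolved by convention")
    return PoseAngles(f, a, e, gimbal_lock=lock)
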