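"""Synthetic articulated lower-limb landmark populations with ground truth.

Generates dense-landmark skeletal data emulating what a CT-derived cohort
provides to the denoising pipeline, with every nuisance the pipeline must
handle planted and recorded:

* per-bone anatomy driven by a low-dimensional latent vector in which an
  overall-size latent dominates (the first principal component of real
  skeletal data is nearly always size);
* a neutral inter-bone alignment that is a deterministic, bounded affine
  function of the size latent (constitutional alignment is anatomy-driven);
* scan-time pose noise applied as rigid rotations of the distal chain
  through idealized joint centers — a truncated-normal "scanner" profile
  for routine scans and the uniform +/-15 deg-per-axis profile used in the
  mock validation experiment;
* mirrored left limbs with small independent landmark noise (directional
  asymmetry well below pose effects) and independent pose;
* repeat-scan ("rescan") couples sharing anatomy but not pose;
* a planted binary sex effect carrying a configurable fraction of the
  anatomical variance (wider knee/ankle and narrower pelvis in males, plus
  an overall size component).

Everything regenerates bit-identically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .denoiser import JointSpec, ScanRecord
from .geometry import LandmarkShape, PoseAngles, mirror, rotation_from_euler
from .shape_model import ShapeModel, reconstruct

BONE_PARTS = ("pelvis", "femur", "tibia", "foot")
JOINT_ORDER = ("hip", "knee", "ankle")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort (defaults = main experiment)."""

    n_subjects: int = 300
    landmarks: dict = field(default_factory=lambda: {
        "pelvis": 120, "femur": 160, "tibia": 140, "foot": 100})
    femur_length: float = 450.0          # mm
    size_sd: float = 0.06                # isotropic size latent, sd of scale factor
    size_fraction: float = 0.60          # share of anatomical variance from size
    minor_fraction: float = 0.10         # share from the 4 minor shape latents
    sex_fraction: float = 0.30           # share from the planted sex offset
    male_fraction: float = 2.0 / 3.0     # 2:1 male:female
    alignment_coeffs: dict = field(default_factory=lambda: {
        "hip": (3.0, 2.0, 4.0), "knee": (4.0, 1.0, 1.5), "ankle": (3.0, 1.5, 1.5)})
    alignment_bound_deg: float = 10.0
    pose_profile: str = "scanner"        # "scanner" | "uniform"
    pose_limit_deg: float = 15.0
    scanner_pose_sd: dict = field(default_factory=lambda: {
        "hip": (2.0, 2.5, 5.0), "knee": (1.5, 0.8, 1.2), "ankle": (2.5, 2.5, 2.0)})
    asymmetry_sd: float = 0.3            # mm, left-bone landmark noise
    n_rescan_pairs: int = 40             # subject-side couples with a 2nd scan
    global_rot_sd_deg: float = 5.0
    global_trans_sd: float = 20.0
    sex_size_weight: float = 0.7         # share of sex variance via overall size
    sex_part_weights: dict = field(default_factory=lambda: {
        p: 1.0 for p in BONE_PARTS})
    seed: int = 0


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, radii, center) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = 2.0 * np.pi * i * (1.0 + 5 ** 0.5) / 2.0
    s = np.sqrt(1.0 - z ** 2)
    unit = np.stack([s * np.cos(theta), s * np.sin(theta), z], axis=1)
    return np.asarray(center, float) + unit * np.asarray(radii, float)


def _cylinder(n_rings: int, n_around: int, radius: float, axis_xy,
              z0: float, z1: float) -> np.ndarray:
    zs = np.linspace(z0, z1, n_rings)
    pts = []
    for k, z in enumerate(zs):
        for a in range(n_around):
            ang = 2 * np.pi * (a + 0.31 * k) / n_around  # helical offset
            pts.append([axis_xy[0] + radius * np.cos(ang),
                        axis_xy[1] + radius * np.sin(ang), z])
    return np.asarray(pts)


def _disk(n: int, radius: float, center) -> np.ndarray:
    i = np.arange(n)
    r = radius * np.sqrt((i + 0.5) / n)
    theta = 2.0 * np.pi * i * (1.0 + 5 ** 0.5) / 2.0
    cx, cy, cz = center
    z = cz + 2.0 * np.cos(3.0 * theta) * (r / radius)  # shallow relief
    return np.stack([cx + r * np.cos(theta), cy + r * np.sin(theta), z], axis=1)


@dataclass(eq=False)
class TemplateBundle:
    """Template bones, joint specs and the deformation-field basis."""

    bones: dict[str, LandmarkShape]
    joints: dict[str, JointSpec]
    groups: dict[str, np.ndarray]          # per-point anatomical group names
    fields: dict[str, dict[str, np.ndarray]]
    sex_fields: dict[str, np.ndarray]      # unit-normalized width features
    minor_amps: np.ndarray                 # mm per latent sd, per minor field
    sex_gains: dict[str, float]            # mm gain on the width features
    sex_size_delta: float = 0.0            # sex shift of the global scale factor
    minor_names: tuple[str, ...] = ()
    config: GeneratorConfig = field(default_factory=GeneratorConfig)


def _bone_clouds(cfg: GeneratorConfig):
    u = cfg.femur_length / 450.0
    lm = cfg.landmarks
    clouds: dict[str, list[tuple[str, np.ndarray]]] = {}

    n = lm["pelvis"]
    n_ace, n_il = max(4, n // 4), max(4, (5 * n) // 12)
    n_pub = n - n_ace - n_il
    clouds["pelvis"] = [
        ("acetabulum", _fibonacci_sphere(n_ace, (26 * u,) * 3, (0, 0, 0))),
        ("ilium", _fibonacci_sphere(n_il, (40 * u, 60 * u, 70 * u), (0, 35 * u, 95 * u))),
        ("pubis", _fibonacci_sphere(n_pub, (30 * u, 45 * u, 22 * u), (15 * u, 60 * u, -15 * u))),
    ]
    n = lm["femur"]
    n_head, n_shaft = max(4, n // 4), max(8, n // 2)
    n_cond = n - n_head - n_shaft
    rings = max(2, n_shaft // 4)
    clouds["femur"] = [
        ("head", _fibonacci_sphere(n_head, (24 * u,) * 3, (0, 0, 0))),
        ("shaft", _cylinder(rings, -(-n_shaft // rings), 15 * u, (0, -40 * u),
                            -70 * u, -420 * u)[:n_shaft]),
        ("condyles", np.vstack([
            _fibonacci_sphere(n_cond - n_cond // 2, (21 * u,) * 3, (0, -22 * u, -450 * u)),
            _fibonacci_sphere(n_cond // 2, (21 * u,) * 3, (0, -58 * u, -450 * u))])),
    ]
    n = lm["tibia"]
    n_plat, n_mort = max(4, (2 * n) // 7), max(4, (3 * n) // 14)
    n_shaft = n - n_plat - n_mort
    rings = max(2, n_shaft // 5)
    clouds["tibia"] = [
        ("plateau", _disk(n_plat, 30 * u, (0, -40 * u, -458 * u))),
        ("shaft", _cylinder(rings, -(-n_shaft // rings), 12 * u, (0, -40 * u),
                            -480 * u, -800 * u)[:n_shaft]),
        ("mortise", _fibonacci_sphere(n_mort, (16 * u,) * 3, (0, -40 * u, -820 * u))),
    ]
    n = lm["foot"]
    n_hind = max(4, (2 * n) // 5)
    clouds["foot"] = [
        ("hindfoot", _fibonacci_sphere(n_hind, (32 * u, 24 * u, 20 * u),
                                       (5 * u, -40 * u, -850 * u))),
        ("forefoot", _fibonacci_sphere(n - n_hind, (85 * u, 32 * u, 14 * u),
                                       (95 * u, -40 * u, -862 * u))),
    ]
    return clouds, u


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v


def _pure_shape(field: np.ndarray, ref_centered: np.ndarray) -> np.ndarray:
    """Remove the rigid components (translation + infinitesimal rotations
    about the bone centroid) from a deformation field, so Procrustes
    alignment cannot absorb any of its variance."""
    f = field - field.mean(axis=0)
    basis = []
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        r = np.cross(np.broadcast_to(e, ref_centered.shape), ref_centered)
        for b in basis:
            r = r - (r * b).sum() * b
        n = np.linalg.norm(r)
        if n > 1e-12:
            basis.append(r / n)
    for b in basis:
        f = f - (f * b).sum() * b
    return f


def make_template(config: GeneratorConfig | None = None) -> TemplateBundle:
    """Deterministic parametric bone templates, joints and deformation basis.

    Template frame: +X anterior, +Y subject-left, +Z superior; origin at the
    hip center; a right limb.  Field amplitudes are calibrated analytically
    so the size latent, the four minor latents and the sex offset contribute
    ``size_fraction`` / ``minor_fraction`` / ``sex_fraction`` of the total
    anatomical (landmark-displacement) variance.
    """
    cfg = config or GeneratorConfig()
    clouds, u = _bone_clouds(cfg)

    bones: dict[str, LandmarkShape] = {}
    groups: dict[str, np.ndarray] = {}
    for part, segs in clouds.items():
        coords = np.vstack([c for _, c in segs])
        grp = np.concatenate([[g] * len(c) for g, c in segs])
        ids = np.array([f"{part}_{g}_{i:03d}" for i, g in enumerate(grp)])
        bones[part] = LandmarkShape(coords, ids, np.array([part] * len(ids)),
                                    side="right", frame="template")
        groups[part] = grp

    def gids(part, group):
        return bones[part].point_ids[groups[part] == group]

    joints = {
        "hip": JointSpec("hip", "pelvis", "femur", gids("femur", "head"),
                         joint_type="spherical",
                         distal_chain=("femur", "tibia", "foot")),
        "knee": JointSpec("knee", "femur", "tibia", gids("femur", "condyles"),
                          joint_type="hinge-like",
                          distal_chain=("tibia", "foot")),
        "ankle": JointSpec("ankle", "tibia", "foot", gids("tibia", "mortise"),
                           joint_type="hinge-like", distal_chain=("foot",)),
    }
    for j in joints.values():
        owner = "femur" if j.name in ("hip", "knee") else "tibia"
        j.template_center = j.center(bones[owner])

    # ---- deformation basis ------------------------------------------------
    minor_names = ("length", "shaft_radius", "knee_width", "pelvis_size")
    fields: dict[str, dict[str, np.ndarray]] = {p: {} for p in BONE_PARTS}
    for part, shape in bones.items():
        xyz = shape.coords
        g = groups[part]
        f = {name: np.zeros_like(xyz) for name in minor_names}
        f["length"][:, 2] = xyz[:, 2] / cfg.femur_length  # longitudinal stretch
        if part in ("femur", "tibia"):
            m = g == "shaft"
            radial = xyz[m, :2] - np.array([0.0, -40.0 * u])
            f["shaft_radius"][m, :2] = radial / np.maximum(
                np.linalg.norm(radial, axis=1, keepdims=True), 1e-9)
        if part == "femur":
            m = g == "condyles"
            f["knee_width"][m, 1] = np.sign(xyz[m, 1] + 40.0 * u)
        if part == "tibia":
            m = g == "plateau"
            f["knee_width"][m, 1] = (xyz[m, 1] + 40.0 * u) / (30.0 * u)
        if part == "pelvis":
            f["pelvis_size"] = (xyz - xyz.mean(axis=0)) / 100.0
        ref = xyz - xyz.mean(axis=0)
        fields[part] = {name: _pure_shape(v, ref) for name, v in f.items()}

    # sex width features: wider knee/ankle/hindfoot, narrower pelvis in males
    # (the dominant, size-borne share of the sex effect acts on the global
    #  scale factor instead; see the calibration below)
    sex_fields: dict[str, np.ndarray] = {}
    for part, shape in bones.items():
        xyz = shape.coords
        g = groups[part]
        feat = np.zeros_like(xyz)
        if part == "pelvis":
            feat[:, 1] = -(xyz[:, 1] - xyz[:, 1].mean())  # narrower inlet
        elif part == "femur":
            feat = fields[part]["knee_width"] + 0.5 * fields[part]["shaft_radius"]
        elif part == "tibia":
            feat = fields[part]["knee_width"].copy()
            m = g == "mortise"
            feat[m, 1] += (xyz[m, 1] + 40.0 * u) / (16.0 * u)
        elif part == "foot":
            m = g == "hindfoot"
            feat[m, 1] = (xyz[m, 1] + 40.0 * u) / (24.0 * u)
        # pure shape contrast, orthogonal to the bone's size direction: the
        # size-borne sex share acts via the global scale factor instead, so
        # the planted variances add exactly and survive Procrustes alignment
        size_dir = xyz - xyz.mean(axis=0)
        feat = _pure_shape(feat, size_dir)
        feat -= (feat * size_dir).sum() / (size_dir ** 2).sum() * size_dir
        sex_fields[part] = _unit(feat)

    # ---- variance calibration (linearized, translation removed) ----------
    def csq(a: np.ndarray) -> float:
        return float(((a - a.mean(axis=0)) ** 2).sum())

    c_sq = {p: csq(bones[p].coords) for p in BONE_PARTS}
    v_size = {p: cfg.size_sd ** 2 * c_sq[p] for p in BONE_PARTS}
    total = sum(v_size.values()) / cfg.size_fraction if cfg.size_fraction > 0 else 0.0
    minor_amps = np.zeros(len(minor_names))
    if total > 0 and cfg.minor_fraction > 0:
        for j, name in enumerate(minor_names):
            norm2 = sum(csq(fields[p][name]) for p in BONE_PARTS)
            if norm2 > 0:
                target = cfg.minor_fraction * total / len(minor_names)
                minor_amps[j] = np.sqrt(target / norm2)
    v_minor = {p: sum(minor_amps[j] ** 2 * csq(fields[p][n])
                      for j, n in enumerate(minor_names)) for p in BONE_PARTS}
    var_label = 4.0 * cfg.male_fraction * (1.0 - cfg.male_fraction)
    base = {p: v_size[p] + v_minor[p] for p in BONE_PARTS}
    w = {p: cfg.sex_part_weights.get(p, 0.0) for p in BONE_PARTS}
    wsum = sum(w[p] * base[p] for p in BONE_PARTS)
    sex_gains = {p: 0.0 for p in BONE_PARTS}
    delta = 0.0
    if cfg.sex_fraction > 0 and wsum > 0 and var_label > 0:
        v_sex_total = cfg.sex_fraction / (1.0 - cfg.sex_fraction) * sum(base.values())
        # size-borne share of the sex effect: a +/- delta shift of the global
        # scale factor, so males are systematically larger
        delta = float(np.sqrt(cfg.sex_size_weight * v_sex_total /
                              (var_label * sum(c_sq.values()))))
        for p in BONE_PARTS:
            target_p = v_sex_total * w[p] * base[p] / wsum
            width_p = max(target_p - delta ** 2 * var_label * c_sq[p], 0.0)
            sex_gains[p] = float(np.sqrt(width_p / var_label))

    return TemplateBundle(bones=bones, joints=joints, groups=groups,
                          fields=fields, sex_fields=sex_fields,
                          minor_amps=minor_amps, sex_gains=sex_gains,
                          sex_size_delta=delta, minor_names=minor_names,
                          config=cfg)


# ---------------------------------------------------------------------------
# Pose application
# ---------------------------------------------------------------------------

def apply_pose(construct: LandmarkShape, joint: JointSpec,
               angles: PoseAngles | np.ndarray) -> LandmarkShape:
    """Rotate the joint's distal chain rigidly about the idealized center.

    The center is the centroid of the joint's articular landmarks evaluated
    on this construct, so it follows subject size and prior rotations; the
    proximal part is untouched.
    """
    parts = [p for p in joint.distal_chain if p in construct.parts]
    if not parts:
        raise KeyError(f"construct has no distal parts for joint {joint.name}")
    center = joint.center(construct)
    rot = rotation_from_euler(angles)
    coords = construct.coords.copy()
    mask = np.isin(construct.part_labels, parts)
    coords[mask] = (coords[mask] - center) @ rot.T + center
    return construct.with_coords(coords)


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class SyntheticSubject:
    """Ground-truth carrier: anatomy, alignment and every scan of a subject.

    ``bones[side]`` are the bone landmark sets in that side's own frame;
    ``neutral_rf``/``zero_rf`` are the neutrally-aligned and the unrotated
    full-limb assemblies in the right (template) frame, for both sides, used
    as measurement controls.
    """

    subject_id: int
    sex: int
    latents: np.ndarray
    bones: dict[str, dict[str, LandmarkShape]]
    neutral_rf: dict[str, LandmarkShape]
    zero_rf: dict[str, LandmarkShape]
    neutral_angles: dict[str, np.ndarray]
    scans: list[ScanRecord] = field(default_factory=list)
    pose_angles: dict = field(default_factory=dict)  # (side, scan_idx) -> {joint: (3,)}


@dataclass(eq=False)
class SyntheticPopulation:
    subjects: list[SyntheticSubject]
    template: TemplateBundle
    config: GeneratorConfig

    @property
    def joints(self) -> dict[str, JointSpec]:
        return self.template.joints

    @property
    def bone_parts(self) -> tuple[str, ...]:
        return BONE_PARTS

    def scan_records(self) -> list[ScanRecord]:
        return [rec for s in self.subjects for rec in s.scans]

    def rescan_pairs(self) -> list[tuple[ScanRecord, ScanRecord]]:
        pairs = []
        for s in self.subjects:
            by_side: dict[str, list[ScanRecord]] = {}
            for rec in s.scans:
                by_side.setdefault(rec.side, []).append(rec)
            for recs in by_side.values():
                if len(recs) >= 2:
                    pairs.append((recs[0], recs[1]))
        return pairs

    def joint_construct(self, construct: LandmarkShape, joint_name: str,
                        ) -> LandmarkShape:
        joint = self.joints[joint_name]
        return construct.extract_parts(list(joint.parts))


def size_driver(tpl: TemplateBundle, z: np.ndarray, sex: int) -> float:
    """Apparent-size scalar (in size-latent sd units) of a subject.

    Combines the size latent with the size-borne sex shift, i.e. the overall
    scale of the subject's bones expressed in latent units — the single
    shape feature that drives neutral alignment.
    """
    cfg = tpl.config
    if cfg.size_sd <= 0:  # no size information in shape: alignment constant
        return 0.0
    return float(z[0] + tpl.sex_size_delta / cfg.size_sd * sex)


def _subject_bones_rf(tpl: TemplateBundle, z: np.ndarray, sex: int,
                      ) -> dict[str, np.ndarray]:
    """Right-frame bone coordinates for latent vector z and sex label."""
    cfg = tpl.config
    out = {}
    scale = 1.0 + cfg.size_sd * z[0] + tpl.sex_size_delta * sex
    for part, shape in tpl.bones.items():
        disp = np.zeros_like(shape.coords)
        for j, name in enumerate(tpl.minor_names):
            disp += tpl.minor_amps[j] * z[1 + j] * tpl.fields[part][name]
        disp += tpl.sex_gains[part] * sex * tpl.sex_fields[part]
        out[part] = scale * (shape.coords + disp)
    return out


def neutral_alignment_angles(tpl: TemplateBundle, z: np.ndarray, sex: int,
                             ) -> dict[str, np.ndarray]:
    """Bounded affine map from apparent size to per-joint neutral angles.

    Alignment is a deterministic function of bone shape: joint angles scale
    with the subject's overall size (clipped to ``alignment_bound_deg``).
    """
    cfg = tpl.config
    u = size_driver(tpl, z, sex)
    out = {}
    for name in JOINT_ORDER:
        coeffs = np.asarray(cfg.alignment_coeffs[name], float)
        out[name] = np.clip(coeffs * u, -cfg.alignment_bound_deg,
                            cfg.alignment_bound_deg)
    return out


def _assemble(tpl: TemplateBundle, bone_coords: dict[str, np.ndarray],
              angles: dict[str, np.ndarray] | None) -> LandmarkShape:
    coords = np.vstack([bone_coords[p] for p in BONE_PARTS])
    ids = np.concatenate([tpl.bones[p].point_ids for p in BONE_PARTS])
    labels = np.concatenate([tpl.bones[p].part_labels for p in BONE_PARTS])
    construct = LandmarkShape(coords, ids, labels, side="right", frame="raw")
    if angles is not None:
        for name in JOINT_ORDER:
            construct = apply_pose(construct, tpl.joints[name], angles[name])
    return construct


def _draw_pose(cfg: GeneratorConfig, rng: np.random.Generator,
               ) -> dict[str, np.ndarray]:
    out = {}
    for name in JOINT_ORDER:
        if cfg.pose_profile == "uniform":
            a = rng.uniform(-cfg.pose_limit_deg, cfg.pose_limit_deg, 3)
        else:
            sd = np.asarray(cfg.scanner_pose_sd[name], float)
            a = np.clip(rng.normal(0.0, sd), -cfg.pose_limit_deg, cfg.pose_limit_deg)
        out[name] = a
    return out


def _global_motion(cfg: GeneratorConfig, rng: np.random.Generator,
                   coords: np.ndarray) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.normal(0.0, cfg.global_rot_sd_deg))
    rot = Rotation.from_rotvec(axis * ang).as_matrix()
    trans = rng.normal(0.0, cfg.global_trans_sd, 3)
    return coords @ rot.T + trans


def sample_population(config: GeneratorConfig | None = None,
                      ) -> SyntheticPopulation:
    """Draw a full cohort: subjects i.i.d., both sides, rescan couples."""
    cfg = config or GeneratorConfig()
    if cfg.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    tpl = make_template(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(5)
    rng_lat, rng_sex, rng_asym, rng_pose, rng_global = \
        (np.random.default_rng(s) for s in streams)

    z_all = rng_lat.standard_normal((cfg.n_subjects, 1 + len(tpl.minor_names)))
    z_all[:, 0] = np.clip(z_all[:, 0], -3.0, 3.0)
    sex_all = np.where(rng_sex.random(cfg.n_subjects) < cfg.male_fraction, 1, -1)
    n_rescan_subjects = cfg.n_rescan_pairs // 2

    subjects = []
    for i in range(cfg.n_subjects):
        z, sex = z_all[i], int(sex_all[i])
        right = _subject_bones_rf(tpl, z, sex)
        left_rf = {p: right[p] + cfg.asymmetry_sd * rng_asym.normal(size=right[p].shape)
                   for p in BONE_PARTS}
        angles = neutral_alignment_angles(tpl, z, sex)

        bones_rf = {"right": right, "left": left_rf}
        bones, neutral_rf, zero_rf = {}, {}, {}
        for side in ("right", "left"):
            bc = bones_rf[side]
            zero_rf[side] = _assemble(tpl, bc, None)
            neutral_rf[side] = _assemble(tpl, bc, angles)
            side_bones = {}
            for p in BONE_PARTS:
                s = tpl.bones[p].with_coords(bc[p], frame="raw")
                side_bones[p] = s if side == "right" else mirror(s)
            bones[side] = side_bones

        subj = SyntheticSubject(subject_id=i, sex=sex, latents=z.copy(),
                                bones=bones, neutral_rf=neutral_rf,
                                zero_rf=zero_rf, neutral_angles=angles)
        n_scans = 2 if i < n_rescan_subjects else 1
        for side in ("right", "left"):
            for k in range(n_scans):
                pose = _draw_pose(cfg, rng_pose)
                posed = neutral_rf[side]
                for name in JOINT_ORDER:
                    posed = apply_pose(posed, tpl.joints[name], pose[name])
                if side == "left":
                    posed = mirror(posed)
                world = _global_motion(cfg, rng_global, posed.coords)
                rec = ScanRecord(i, side, k, posed.with_coords(world))
                subj.scans.append(rec)
                subj.pose_angles[(side, k)] = pose
        subjects.append(subj)
    return SyntheticPopulation(subjects=subjects, template=tpl, config=cfg)


# ---------------------------------------------------------------------------
# Mock validation sets
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class MockSet:
    """K mock shapes along a model's first mode, pose-corrupted, with controls."""

    controls: list[LandmarkShape]
    posed: list[LandmarkShape]
    angles: dict[str, np.ndarray]   # joint -> (K, 3) applied angles, degrees
    joints: list[JointSpec]
    seed: int


def make_mock_set(model: ShapeModel, joints: list[JointSpec] | JointSpec,
                  K: int = 1000, limit_deg: float = 15.0,
                  seed: int = 0) -> MockSet:
    """Sample K shapes from the mean and first PC, then corrupt their pose.

    Mode-1 weights are drawn Normal(0, lambda_1); each shape then receives
    independent rotations uniform on [-limit, +limit] degrees per axis
    through each idealized joint present in the construct.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if isinstance(joints, JointSpec):
        joints = [joints]
    rng = np.random.default_rng(seed)
    b1 = rng.normal(0.0, np.sqrt(model.eigenvalues[0]), K)
    angles = {j.name: rng.uniform(-limit_deg, limit_deg, (K, 3)) for j in joints}
    controls, posed = [], []
    for k in range(K):
        b = np.zeros(model.t)
        b[0] = b1[k]
        control = reconstruct(model, b)
        shape = control
        for j in joints:
            shape = apply_pose(shape, j, angles[j.name][k])
        controls.append(control)
        posed.append(shape)
    return MockSet(controls=controls, posed=posed, angles=angles,
                   joints=list(joints), seed=seed)
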