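"""Sexual dimorphism on pose-corrected shape models.

Quantifies the sex-shape relationship in a model's score space three ways:
canonical correlation (strength of the statistical association), explained
variance by one-component PLSR (predictive share of shape variance carried
by sex), and per-landmark effect/significance maps obtained from amplified
male/female canonical reconstructions and permutation tests with
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .geometry import LandmarkShape
from .latent_regression import fit_cca, plsr_explained_variance
from .shape_model import ShapeModel, reconstruct


@dataclass(eq=False)
class DimorphismResult:
    """Sex-shape association summary for one shape model."""

    r: float
    x_direction: np.ndarray          # canonical direction in PC-score space
    p_value: float
    percent_variance: float          # PLSR explained variance, 0-100
    n_pcs: int
    mean_score_male: float
    mean_score_female: float
    size_corrected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r outside [0, 1]")
        if not 0.0 <= self.percent_variance <= 100.0 + 1e-9:
            raise ValueError("percent outside [0, 100]")


def _cca_r_fast(q: np.ndarray, yc: np.ndarray) -> float:
    """Multiple correlation of yc with span(Q), Q orthonormal."""
    denom = np.linalg.norm(yc)
    return 0.0 if denom == 0 else float(np.linalg.norm(q.T @ yc) / denom)


def sex_shape_analysis(model: ShapeModel, scores: np.ndarray, sex: np.ndarray,
                       n_pcs: int = 20, n_perm: int = 1000,
                       seed: int = 0) -> DimorphismResult:
    """CCA correlation, permutation p-value and PLSR explained variance.

    ``scores`` are the model's training scores (rows = samples), ``sex``
    the +1 (male) / -1 (female) labels.  Only the first ``n_pcs`` principal
    components enter the analysis.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    sex = np.asarray(sex, float).reshape(-1)
    if np.unique(sex).size < 2:
        raise ValueError("both sexes must be present")
    n_pcs = int(min(n_pcs, scores.shape[1], model.t))
    x = scores[:, :n_pcs]
    cca = fit_cca(x, sex)
    percent = plsr_explained_variance(x, sex)

    xc = x - x.mean(axis=0)
    q, _ = np.linalg.qr(xc)
    yc = sex - sex.mean()
    r_obs = _cca_r_fast(q, yc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _cca_r_fast(q, rng.permutation(yc)) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)

    u = xc @ cca.x_direction
    return DimorphismResult(r=cca.r, x_direction=cca.x_direction, p_value=p,
                            percent_variance=percent, n_pcs=n_pcs,
                            mean_score_male=float(u[sex > 0].mean()),
                            mean_score_female=float(u[sex < 0].mean()))


def sex_effect_shapes(model: ShapeModel, result: DimorphismResult,
                      amplification: float = 2.0, size_correct: bool = False,
                      ) -> tuple[LandmarkShape, LandmarkShape, np.ndarray]:
    """Amplified male/female effect shapes and the per-landmark displacement map.

    Reconstructs the model at +/- ``amplification`` times the mean male and
    female canonical scores along the canonical direction.  With
    ``size_correct`` both shapes are rescaled to a common centroid size
    before differencing, removing the overall-size component of the effect.
    """
    if amplification < 0:
        raise ValueError("amplification must be >= 0")

    def shape_at(mean_u: float) -> LandmarkShape:
        b = np.zeros(model.t)
        b[:result.n_pcs] = amplification * mean_u * result.x_direction
        return reconstruct(model, b)

    male = shape_at(result.mean_score_male)
    female = shape_at(result.mean_score_female)
    if size_correct:
        target = 0.5 * (male.centroid_size + female.centroid_size)
        male = male.with_coords(
            male.centroid + (male.coords - male.centroid) * target / male.centroid_size)
        female = female.with_coords(
            female.centroid + (female.coords - female.centroid) * target / female.centroid_size)
    displacement = np.linalg.norm(male.coords - female.coords, axis=1)
    return male, female, displacement


def landmark_significance(shapes, sex: np.ndarray, n_perm: int = 1000,
                          seed: int = 0, alpha: float = 0.05):
    """Per-landmark permutation test of the male/female mean displacement.

    The statistic per landmark is the Euclidean distance between the sex
    group means of that landmark's coordinates; labels are permuted jointly
    across landmarks and p-values corrected by Benjamini-Hochberg FDR.
    Returns ``(p_raw, p_fdr, significant_mask)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(shapes, (list, tuple)):
        data = np.stack([s.coords for s in shapes])
    else:
        data = np.asarray(shapes, float)
    sex = np.asarray(sex)
    m, n_lm, _ = data.shape
    male = sex > 0
    if male.all() or not male.any():
        raise ValueError("both sexes must be present")
    flat = data.reshape(m, -1)
    n_m, n_f = int(male.sum()), int((~male).sum())

    def stat(mask: np.ndarray) -> np.ndarray:
        diff = flat[mask].mean(axis=0) - flat[~mask].mean(axis=0)
        return np.linalg.norm(diff.reshape(n_lm, 3), axis=1)

    obs = stat(male)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_lm)
    for _ in range(n_perm):
        perm = rng.permutation(male)
        exceed += stat(perm) >= obs - 1e-12
    p_raw = (1 + exceed) / (n_perm + 1)
    reject, p_fdr, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    return p_raw, p_fdr, reject
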