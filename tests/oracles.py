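"""Independent oracles used by the test suite.

Deliberately avoid the code paths they check: the Procrustes oracle is an
SVD-free brute-force search over a nested rotation grid, and the rotation
oracle composes rotations by hand-rolled quaternion products.
"""

import numpy as np


def _euler_matrix(f, a, e):
    """Intrinsic Y-X-Z rotation built from explicit elementary matrices."""
    cf, sf = np.cos(f), np.sin(f)
    ca, sa = np.cos(a), np.sin(a)
    ce, se = np.cos(e), np.sin(e)
    ry = np.array([[cf, 0, sf], [0, 1, 0], [-sf, 0, cf]])
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    rz = np.array([[ce, -se, 0], [se, ce, 0], [0, 0, 1]])
    return ry @ rx @ rz


def grid_procrustes_rmse(source: np.ndarray, target: np.ndarray,
                         coarse_deg: float = 12.0, n_refine: int = 4) -> float:
    """Minimum rigid-superimposition RMSE by nested grid search (no SVD)."""
    a = source - source.mean(axis=0)
    b = target - target.mean(axis=0)

    def rmse(f, al, e):
        r = _euler_matrix(f, al, e)
        return np.sqrt(((a @ r.T - b) ** 2).sum(axis=1).mean())

    step = np.deg2rad(coarse_deg)
    fs = np.arange(-np.pi, np.pi, step)
    als = np.arange(-np.pi / 2, np.pi / 2 + 1e-9, step)
    es = np.arange(-np.pi, np.pi, step)
    best = (np.inf, 0.0, 0.0, 0.0)
    for f in fs:
        for al in als:
            for e in es:
                v = rmse(f, al, e)
                if v < best[0]:
                    best = (v, f, al, e)
    for _ in range(n_refine):
        lo = step
        step /= 4.0
        _, f0, a0, e0 = best
        grid = np.arange(-lo, lo + 1e-12, step)
        for df in grid:
            for da in grid:
                for de in grid:
                    v = rmse(f0 + df, a0 + da, e0 + de)
                    if v < best[0]:
                        best = (v, f0 + df, a0 + da, e0 + de)
    return best[0]


# -- quaternion oracle -------------------------------------------------------

def _quat_mul(q, p):
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = p
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _quat_axis(axis, angle):
    q = np.zeros(4)
    q[0] = np.cos(angle / 2.0)
    q[1 + axis] = np.sin(angle / 2.0)
    return q


def _quat_to_matrix(q):
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quaternion_rotation(flex_deg, abd_deg, endo_deg):
    """Intrinsic Y-X-Z rotation composed by quaternion products."""
    qy = _quat_axis(1, np.deg2rad(flex_deg))
    qx = _quat_axis(0, np.deg2rad(abd_deg))
    qz = _quat_axis(2, np.deg2rad(endo_deg))
    return _quat_to_matrix(_quat_mul(_quat_mul(qy, qx), qz))
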