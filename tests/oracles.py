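"""Independent oracles for the spherical geometry, used only by tests.

These share no code with the package's optimisation-based solvers:

* ``enclosing_radius_oracle`` — exhaustive combinatorial search on S^2.  The
  minimax center is supported by at most three points; candidate centers are
  therefore every point, every pair's geodesic midpoint, and both
  circumcenters of every triple, and the answer is the smallest covering
  radius over all candidates.
* ``spherical_sd_oracle`` — dense Fibonacci-grid search over S^2 with local
  grid refinement around the best cell; no gradient-based optimisation.
"""

import numpy as np


def _max_angle_deg(D: np.ndarray, c: np.ndarray) -> float:
    half = np.linalg.norm(D - c, axis=1) / 2.0
    return float(np.degrees(2.0 * np.arcsin(np.clip(np.max(half), 0.0, 1.0))))


def enclosing_radius_oracle(D: np.ndarray) -> float:
    n = D.shape[0]
    if n == 1:
        return 0.0
    cands = [D[i] for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            s = D[i] + D[j]
            ns = np.linalg.norm(s)
            if ns > 1e-12:
                cands.append(s / ns)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                c = np.cross(D[i] - D[j], D[j] - D[k])
                nc = np.linalg.norm(c)
                if nc > 1e-12:
                    cands.append(c / nc)
                    cands.append(-c / nc)
    return min(_max_angle_deg(D, c) for c in cands)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _rms_deg(D: np.ndarray, centers: np.ndarray) -> np.ndarray:
    cos = np.clip(centers @ D.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    return np.sqrt(np.mean(ang**2, axis=1))


def spherical_sd_oracle(D: np.ndarray, n_grid: int = 20000) -> float:
    grid = _fibonacci_sphere(n_grid)
    vals = _rms_deg(D, grid)
    best = grid[int(np.argmin(vals))]
    # local refinement: shrinking tangent-plane grids around the best cell
    scale = 2.0 * np.pi / np.sqrt(n_grid)
    for _ in range(8):
        offsets = np.mgrid[-2:3, -2:3].reshape(2, -1).T * (scale / 2.0)
        # tangent basis at best
        a = np.eye(3)[int(np.argmin(np.abs(best)))]
        t1 = np.cross(best, a)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(best, t1)
        local = best + offsets[:, :1] * t1 + offsets[:, 1:] * t2
        local /= np.linalg.norm(local, axis=1)[:, None]
        vals = _rms_deg(D, local)
        best = local[int(np.argmin(vals))]
        scale /= 2.0
    return float(np.min(vals))
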