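"""Directional geometry on the unit sphere.

Temporal change of an expression trajectory is summarised as a set of unit
vectors ("center-projected directions"): each later time point is projected
from a chosen center point onto the unit sphere.  Two spread measures are
computed for such a set:

* the **smallest enclosing spherical circle** (minimal cap): the center on
  the sphere minimising the *maximum* angular distance to the directions,
  and its radius;
* the **spherical standard deviation**: the center minimising the
  *root-mean-square* angular distance, and that minimised RMS.

Both are solved as constrained minimisation problems on S^(d-1).  For the
enclosing circle, whenever the directions fit inside an open hemisphere the
problem is convex and is solved exactly through its dual: the optimal cap
center is the normalised minimum-norm point of the convex hull of the
directions, and the radius is the arccos of that norm (max-min duality over
the unit ball).  The primal minimax solve is still run as a polish /
certificate, and configurations that do not fit a hemisphere fall back to a
multi-start constrained minimisation: for S^2 the eight octant points
(+-1/sqrt(3), +-1/sqrt(3), +-1/sqrt(3)), the normalised mean and a batch of
seeded random starts; in higher dimension the normalised mean, every input
direction and 32 seeded random starts (octant enumeration is infeasible
there).

All angles are reported in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .exceptions import (
    DegenerateDataError,
    UndefinedDirectionError,
    ValidationError,
)
from .pca import PCProjection

__all__ = [
    "DirectionSet",
    "EnclosingCircle",
    "SphericalSpread",
    "direction",
    "angular_distance",
    "center_projected_directions",
    "min_enclosing_circle",
    "spherical_sd",
    "discrimination",
]

_UNIT_TOL = 1e-6
# cos is clipped away from +-1 so arccos gradients stay finite
_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class DirectionSet:
    """Unit vectors on S^(d-1) obtained by projecting a trajectory from a center."""

    directions: np.ndarray  # (n, d)
    center_label: int | None = None
    labels: tuple = ()
    ambient_dim: int = field(default=0)

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValidationError("directions must be unit vectors (tolerance 1e-9)")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "ambient_dim", d.shape[1])

    def __len__(self) -> int:
        return self.directions.shape[0]


@dataclass(frozen=True)
class EnclosingCircle:
    """Smallest spherical circle (cap boundary) containing a direction set."""

    center: np.ndarray
    radius_deg: float


@dataclass(frozen=True)
class SphericalSpread:
    """RMS-optimal center and spherical standard deviation in degrees."""

    sd_center: np.ndarray
    sd_deg: float


def direction(a, b) -> np.ndarray:
    """Unit vector from point ``a`` through point ``b``: (b - a)/|b - a|."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    disp = b - a
    n = float(np.linalg.norm(disp))
    if n < 1e-12:
        raise UndefinedDirectionError("direction undefined: points coincide")
    return disp / n


def angular_distance(u, v) -> float:
    """Angle between two unit vectors, in degrees (in [0, 180])."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    for name, w in (("u", u), ("v", v)):
        if abs(np.linalg.norm(w) - 1.0) > _UNIT_TOL:
            raise ValidationError(f"{name} is not a unit vector (norm {np.linalg.norm(w):.6g})")
    half_chord = np.linalg.norm(u - v) / 2.0
    return float(np.degrees(2.0 * np.arcsin(np.clip(half_chord, 0.0, 1.0))))


def center_projected_directions(proj: PCProjection, center_label: int) -> DirectionSet:
    """Project every time point after ``center_label`` from the center point.

    The center point's coordinates play the role of the sphere center; each
    subsequent time point defines one direction, so a series running from the
    center day through n-1 later days yields n-1 directions.  Time points
    earlier than the center day (e.g. the day-0 naive point when projecting an
    injury series from day 1) are not projected.
    """
    days = list(proj.days)
    if center_label not in days:
        raise ValidationError(f"center day {center_label} not in series days {days}")
    coords = np.asarray(proj.coordinates, dtype=float)
    c = coords[days.index(center_label)]
    later = [(day, coords[i]) for i, day in enumerate(days) if day > center_label]
    if not later:
        raise ValidationError(f"no time points after center day {center_label}")
    dirs = []
    for day, point in later:
        try:
            dirs.append(direction(c, point))
        except UndefinedDirectionError as exc:
            raise UndefinedDirectionError(
                f"day {day} coincides with the center point (day {center_label})"
            ) from exc
    return DirectionSet(
        directions=np.array(dirs),
        center_label=center_label,
        labels=tuple(day for day, _ in later),
    )


# ---------------------------------------------------------------------------
# smallest enclosing spherical circle


def _as_direction_array(obj) -> np.ndarray:
    if isinstance(obj, DirectionSet):
        return obj.directions
    d = np.atleast_2d(np.asarray(obj, dtype=float))
    norms = np.linalg.norm(d, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValidationError("directions must be unit vectors")
    return d / norms[:, None]


def _max_angle(D: np.ndarray, c: np.ndarray) -> float:
    # chord-based formula: accurate near 0 where arccos(dot) loses precision
    chords = np.linalg.norm(D - c, axis=1)
    return float(2.0 * np.arcsin(np.clip(np.max(chords) / 2.0, 0.0, 1.0)))


def _min_norm_hull_point(D: np.ndarray) -> np.ndarray:
    """Minimum-norm point of the convex hull of the rows of ``D`` (small QP)."""
    n = D.shape[0]
    G = D @ D.T
    x0 = np.full(n, 1.0 / n)

    def fun(lam):
        return float(lam @ G @ lam)

    def jac(lam):
        return 2.0 * (G @ lam)

    res = minimize(
        fun,
        x0,
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda l: l.sum() - 1.0,
                      "jac": lambda l: np.ones(n)}],
        options={"ftol": 1e-16, "maxiter": 200},
    )
    lam = np.clip(res.x, 0.0, None)
    s = lam.sum()
    if s <= 0:
        return np.zeros(D.shape[1])
    return (lam / s) @ D


def _maximin_polish(D: np.ndarray, c0: np.ndarray) -> np.ndarray:
    """One primal solve: maximise the minimum dot product over the sphere.

    Variables are (c, s); maximising s subject to c.d_i >= s and |c| = 1 is
    the minimax cap problem with s = cos(radius).  Linear dependence on s
    keeps the problem well conditioned even for very tight direction sets.
    """
    n, d = D.shape
    s0 = float(np.min(D @ c0))
    x0 = np.concatenate([c0, [s0]])
    obj_jac = np.zeros(d + 1)
    obj_jac[d] = -1.0
    ineq_jac = np.hstack([D, -np.ones((n, 1))])
    cons = [
        {"type": "ineq", "fun": lambda x: D @ x[:d] - x[d],
         "jac": lambda x: ineq_jac},
        {"type": "eq", "fun": lambda x: x[:d] @ x[:d] - 1.0,
         "jac": lambda x: np.concatenate([2.0 * x[:d], [0.0]])},
    ]
    res = minimize(
        lambda x: -x[d],
        x0,
        jac=lambda x: obj_jac,
        method="SLSQP",
        constraints=cons,
        options={"ftol": 1e-14, "maxiter": 500},
    )
    c = res.x[:d]
    nc = np.linalg.norm(c)
    if nc < 1e-12 or not np.all(np.isfinite(c)):
        return c0
    return c / nc


def _octant_points() -> np.ndarray:
    signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
                     dtype=float)
    return signs / np.sqrt(3.0)


def _multistart_centers(D: np.ndarray, n_random_starts: int, random_state: int) -> list[np.ndarray]:
    n, d = D.shape
    starts: list[np.ndarray] = []
    mean = D.mean(axis=0)
    nm = np.linalg.norm(mean)
    starts.append(mean / nm if nm > 1e-12 else D[0])
    if d == 3:
        starts.extend(_octant_points())
        n_rand = n_random_starts
    else:
        starts.extend(D)
        n_rand = max(n_random_starts, 32)
    rng = np.random.default_rng(random_state)
    g = rng.standard_normal((n_rand, d))
    starts.extend(g / np.linalg.norm(g, axis=1)[:, None])
    return starts


def min_enclosing_circle(
    directions,
    *,
    n_random_starts: int = 8,
    random_state: int = 0,
) -> EnclosingCircle:
    """Smallest spherical circle on S^(d-1) containing all directions.

    Exact (certified by convex duality) whenever the directions fit inside an
    open hemisphere; otherwise the best center over the multi-start
    constrained minimisation described in the module docstring.  The returned
    radius is always the true maximum angle from the returned center, so it
    is a valid covering radius regardless of solver path.
    """
    D = _as_direction_array(directions)
    n, d = D.shape
    if n == 0:
        raise ValidationError("empty direction set")
    if n == 1:
        return EnclosingCircle(center=D[0].copy(), radius_deg=0.0)

    candidates: list[np.ndarray] = []
    certified = False
    u = _min_norm_hull_point(D)
    nu = float(np.linalg.norm(u))
    if nu > 1e-7:
        # hemispheric case: by convex duality the optimal center is the
        # normalised minimum-norm hull point and the radius is arccos|u|
        c0 = u / nu
        candidates.append(c0)
        lower = np.arccos(np.clip(nu, -1.0, 1.0))
        if _max_angle(D, c0) - lower > 1e-9:
            c1 = _maximin_polish(D, c0)
            candidates.append(c1)
            certified = _max_angle(D, c1) - lower <= 1e-7
        else:
            certified = True
    if not certified:
        # directions do not fit an open hemisphere (or the certificate did
        # not close): the problem is non-convex and multi-start is required
        for s in _multistart_centers(D, n_random_starts, random_state):
            candidates.append(_maximin_polish(D, s))

    best = min(candidates, key=lambda c: _max_angle(D, c))
    return EnclosingCircle(center=best, radius_deg=float(np.degrees(_max_angle(D, best))))


# ---------------------------------------------------------------------------
# spherical standard deviation


def _rms_angles_sq(c: np.ndarray, D: np.ndarray) -> float:
    # chord-based evaluation: exact at 0 where clipped arccos saturates
    half = np.clip(np.linalg.norm(D - c, axis=1) / 2.0, 0.0, 1.0)
    theta = 2.0 * np.arcsin(half)
    return float(theta @ theta)


def _rms_objective(x: np.ndarray, D: np.ndarray):
    nx = np.linalg.norm(x)
    c = x / nx
    u = np.clip(D @ c, -_CLIP, _CLIP)
    theta = np.arccos(u)
    f = float(theta @ theta)
    grad_c = -2.0 * ((theta / np.sqrt(1.0 - u * u)) @ D)
    grad_x = (grad_c - (grad_c @ c) * c) / nx
    return f, grad_x


def spherical_sd(
    directions,
    *,
    n_random_starts: int = 4,
    random_state: int = 0,
) -> SphericalSpread:
    """Center minimising the RMS angular distance, and that RMS in degrees."""
    D = _as_direction_array(directions)
    n, d = D.shape
    if n == 0:
        raise ValidationError("empty direction set")
    if n == 1:
        return SphericalSpread(sd_center=D[0].copy(), sd_deg=0.0)

    starts: list[np.ndarray] = []
    mean = D.mean(axis=0)
    nm = np.linalg.norm(mean)
    starts.append(mean / nm if nm > 1e-12 else D[0])
    if d == 3:
        starts.extend(_octant_points())
    starts.extend(D)
    rng = np.random.default_rng(random_state)
    g = rng.standard_normal((n_random_starts, d))
    starts.extend(g / np.linalg.norm(g, axis=1)[:, None])

    best_c, best_f = None, np.inf
    for s in starts:
        res = minimize(
            _rms_objective,
            s,
            args=(D,),
            jac=True,
            method="L-BFGS-B",
            options={"gtol": 1e-12, "ftol": 1e-15, "maxiter": 500},
        )
        x = res.x
        nx = np.linalg.norm(x)
        if nx < 1e-12 or not np.all(np.isfinite(x)):
            continue
        c = x / nx
        f = _rms_angles_sq(c, D)
        if f < best_f:
            best_f, best_c = f, c
    if best_c is None:  # pragma: no cover - defensive
        raise DegenerateDataError("spherical SD optimisation failed to produce a center")
    sd = np.degrees(np.sqrt(best_f / n))
    return SphericalSpread(sd_center=best_c, sd_deg=float(sd))


def discrimination(a: DirectionSet, b: DirectionSet) -> float:
    """Angular separation of the two RMS centers over the larger spherical SD.

    Dimensionless; large values mean the two trajectories point in clearly
    distinct directions relative to their own spread.
    """
    sa = spherical_sd(a)
    sb = spherical_sd(b)
    m = max(sa.sd_deg, sb.sd_deg)
    if m < 1e-12:
        raise DegenerateDataError(
            "both spherical SDs are zero: discrimination is undefined (infinite)"
        )
    return angular_distance(sa.sd_center, sb.sd_center) / m
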