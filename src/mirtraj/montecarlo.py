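"""Random-walk null models and Monte-Carlo P-values.

The null hypothesis for trajectory directionality is that the trajectory is
a random walk whose displacements are independent unit vectors drawn
uniformly from the sphere.  For each replicate walk the center-projected
directions (from the walk's first point through each subsequent point) are
formed and the minimal enclosing cap radius recorded; the P-value of an
observed radius is the fraction of null radii that are equal or smaller.

Two derived nulls, used where the observed statistic compares groups:

* **discrimination** — both groups are replaced by independent random walks
  of the observed sizes and the discrimination recomputed per replicate; the
  P-value is the fraction of replicates at least as large as observed.
* **proximity** — only the test trajectory is randomized, the reference
  group's RMS center held fixed; the P-value is the fraction of replicate
  angles no larger than the observed angle.

Empirical fractions are reported plainly (no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .spherical import (
    DirectionSet,
    angular_distance,
    min_enclosing_circle,
    spherical_sd,
)

__all__ = [
    "NullDistribution",
    "random_unit_vector",
    "random_unit_vectors",
    "random_walk",
    "walk_directions",
    "null_radius_distribution",
    "null_discrimination_distribution",
    "null_proximity_distribution",
    "p_value_directionality",
    "p_value_discrimination",
    "p_value_proximity",
]


@dataclass(frozen=True)
class NullDistribution:
    """Monte-Carlo replicate values of one statistic under the random-walk null."""

    statistic_name: str  # radius | discrimination | proximity_angle
    samples: np.ndarray
    n_reps: int
    n_directions: int
    ambient_dim: int
    seed: int | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.shape != (self.n_reps,):
            raise ValidationError(
                f"expected {self.n_reps} samples, got shape {samples.shape}"
            )
        object.__setattr__(self, "samples", samples)

    def quantiles(self, qs=(0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99)) -> dict:
        return {f"q{q:g}": float(np.quantile(self.samples, q)) for q in qs}


def _resolve_rng(rng=None, seed=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def random_unit_vector(d: int, rng: np.random.Generator) -> np.ndarray:
    """One vector uniform on S^(d-1): normalised standard Gaussian draw."""
    return random_unit_vectors(1, d, rng)[0]


def random_unit_vectors(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    if d < 2:
        raise ValidationError(f"dimension must be >= 2, got {d}")
    g = rng.standard_normal((n, d))
    norms = np.linalg.norm(g, axis=1)
    # a zero draw has probability 0; redraw defensively
    while np.any(norms < 1e-12):  # pragma: no cover
        bad = norms < 1e-12
        g[bad] = rng.standard_normal((int(bad.sum()), d))
        norms = np.linalg.norm(g, axis=1)
    return g / norms[:, None]


def random_walk(n_points: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Walk of ``n_points`` points starting at the origin with unit steps."""
    if n_points < 2:
        raise ValidationError(f"a walk needs at least 2 points, got {n_points}")
    steps = random_unit_vectors(n_points - 1, d, rng)
    walk = np.vstack([np.zeros(d), np.cumsum(steps, axis=0)])
    return walk


def walk_directions(walk: np.ndarray) -> np.ndarray:
    """Directions from the walk's first point through each subsequent point."""
    disp = walk[1:] - walk[0]
    norms = np.linalg.norm(disp, axis=1)
    if np.any(norms < 1e-12):  # pragma: no cover - probability 0
        raise ValidationError("walk returned to its starting point")
    return disp / norms[:, None]


def null_radius_distribution(
    n_directions: int,
    d: int = 3,
    n_reps: int = 10000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> NullDistribution:
    """Minimal enclosing cap radii of ``n_reps`` random-walk direction sets."""
    if n_directions < 1:
        raise ValidationError("n_directions must be >= 1")
    rng = _resolve_rng(rng, seed)
    radii = np.empty(n_reps)
    for i in range(n_reps):
        walk = random_walk(n_directions + 1, d, rng)
        radii[i] = min_enclosing_circle(walk_directions(walk)).radius_deg
    return NullDistribution(
        statistic_name="radius",
        samples=radii,
        n_reps=n_reps,
        n_directions=n_directions,
        ambient_dim=d,
        seed=seed,
    )


def p_value_directionality(observed_radius_deg: float, null: NullDistribution) -> float:
    """Fraction of null radii equal or smaller than the observed radius."""
    if null.statistic_name != "radius":
        raise ValidationError(
            f"expected a radius null, got {null.statistic_name!r}"
        )
    return float(np.mean(null.samples <= observed_radius_deg))


def null_discrimination_distribution(
    n_dirs_a: int,
    n_dirs_b: int,
    d: int = 3,
    n_reps: int = 10000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> NullDistribution:
    """Discriminations between two independent random walks, per replicate."""
    rng = _resolve_rng(rng, seed)
    values = np.empty(n_reps)
    for i in range(n_reps):
        da = walk_directions(random_walk(n_dirs_a + 1, d, rng))
        db = walk_directions(random_walk(n_dirs_b + 1, d, rng))
        sa = spherical_sd(da)
        sb = spherical_sd(db)
        m = max(sa.sd_deg, sb.sd_deg)
        values[i] = angular_distance(sa.sd_center, sb.sd_center) / m
    return NullDistribution(
        statistic_name="discrimination",
        samples=values,
        n_reps=n_reps,
        n_directions=n_dirs_a + n_dirs_b,
        ambient_dim=d,
        seed=seed,
    )


def p_value_discrimination(
    observed: float,
    n_dirs_a: int,
    n_dirs_b: int,
    d: int = 3,
    n_reps: int = 10000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    null: NullDistribution | None = None,
) -> float:
    """One-sided P on large discrimination: fraction of replicates >= observed."""
    if observed < 0:
        raise ValidationError("observed discrimination must be >= 0")
    if null is None:
        null = null_discrimination_distribution(n_dirs_a, n_dirs_b, d, n_reps, rng, seed)
    elif null.statistic_name != "discrimination":
        raise ValidationError(f"expected a discrimination null, got {null.statistic_name!r}")
    return float(np.mean(null.samples >= observed))


def _reference_center(reference) -> np.ndarray:
    if isinstance(reference, DirectionSet):
        return spherical_sd(reference).sd_center
    ref = np.asarray(reference, dtype=float)
    if ref.ndim == 2:
        return spherical_sd(ref).sd_center
    n = np.linalg.norm(ref)
    if abs(n - 1.0) > 1e-6:
        raise ValidationError("reference center must be a unit vector")
    return ref / n


def null_proximity_distribution(
    n_dirs: int,
    d: int,
    reference,
    n_reps: int = 10000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> NullDistribution:
    """Angles from random-walk RMS centers to a fixed reference center."""
    rng = _resolve_rng(rng, seed)
    ref = _reference_center(reference)
    if ref.shape[0] != d:
        raise ValidationError(
            f"reference dimension {ref.shape[0]} does not match d={d}"
        )
    angles = np.empty(n_reps)
    for i in range(n_reps):
        dirs = walk_directions(random_walk(n_dirs + 1, d, rng))
        angles[i] = angular_distance(spherical_sd(dirs).sd_center, ref)
    return NullDistribution(
        statistic_name="proximity_angle",
        samples=angles,
        n_reps=n_reps,
        n_directions=n_dirs,
        ambient_dim=d,
        seed=seed,
    )


def p_value_proximity(
    obs_angle_deg: float,
    n_dirs: int,
    d: int,
    reference,
    n_reps: int = 10000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    null: NullDistribution | None = None,
) -> float:
    """Fraction of null replicate angles no larger than the observed angle."""
    if not 0.0 <= obs_angle_deg <= 180.0:
        raise ValidationError("observed angle must be in [0, 180] degrees")
    if null is None:
        null = null_proximity_distribution(n_dirs, d, reference, n_reps, rng, seed)
    elif null.statistic_name != "proximity_angle":
        raise ValidationError(f"expected a proximity null, got {null.statistic_name!r}")
    return float(np.mean(null.samples <= obs_angle_deg))
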