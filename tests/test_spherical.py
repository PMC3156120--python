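import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirtraj.exceptions import (
    DegenerateDataError,
    UndefinedDirectionError,
    ValidationError,
)
from mirtraj.pca import PCProjection
from mirtraj.spherical import (
    DirectionSet,
    angular_distance,
    center_projected_directions,
    direction,
    discrimination,
    min_enclosing_circle,
    spherical_sd,
)
from oracles import enclosing_radius_oracle, spherical_sd_oracle


def rotate_2d(u, angle_deg, axis_a=0, axis_b=1):
    """Rotate a 3-vector by angle_deg in the (axis_a, axis_b) coordinate plane."""
    r = np.radians(angle_deg)
    out = np.array(u, dtype=float)
    a, b = out[axis_a], out[axis_b]
    out[axis_a] = np.cos(r) * a - np.sin(r) * b
    out[axis_b] = np.sin(r) * a + np.cos(r) * b
    return out


def random_directions(rng, n, d=3, spread=None):
    if spread is None:
        g = rng.standard_normal((n, d))
    else:
        mu = rng.standard_normal(d)
        g = mu + spread * rng.standard_normal((n, d))
    return g / np.linalg.norm(g, axis=1)[:, None]


class TestDirection:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 0, 0), (2, 0, 0), (1, 0, 0)),
            ((1, 1, 1), (1, 1, 2), (0, 0, 1)),
            ((1.0, -2.0), (4.0, 2.0), (0.6, 0.8)),
        ],
    )
    def test_unit_displacement(self, a, b, expected):
        assert direction(a, b) == pytest.approx(np.array(expected))

    def test_coincident_points_are_rejected(self):
        with pytest.raises(UndefinedDirectionError):
            direction((1.0, 2.0, 3.0), (1.0, 2.0, 3.0))


class TestAngularDistance:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (-1, 0, 0), 180.0),
            ((0, 0, 1), (0, np.sin(np.radians(30)), np.cos(np.radians(30))), 30.0),
        ],
    )
    def test_reference_angles(self, u, v, expected):
        assert angular_distance(u, v) == pytest.approx(expected, abs=1e-9)
        assert angular_distance(v, u) == pytest.approx(expected, abs=1e-9)

    def test_non_unit_input_is_rejected(self):
        with pytest.raises(ValidationError):
            angular_distance((2.0, 0.0, 0.0), (1.0, 0.0, 0.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_output_range(self, seed):
        rng = np.random.default_rng(seed)
        u, v = random_directions(rng, 2, d=int(rng.integers(2, 8)))
        assert 0.0 <= angular_distance(u, v) <= 180.0


class TestCenterProjectedDirections:
    def _proj(self, days, coords, label="series"):
        return PCProjection(label=label, days=tuple(days), coordinates=np.asarray(coords, float))

    def test_sham_like_series_gives_seven_directions(self, rng):
        coords = rng.standard_normal((8, 3))
        ds = center_projected_directions(self._proj([0, 1, 3, 5, 7, 14, 21, 30], coords), 0)
        assert len(ds) == 7
        assert ds.labels == (1, 3, 5, 7, 14, 21, 30)

    def test_injury_series_from_day1_gives_six_directions(self, rng):
        # the day-0 naive point precedes the center and is not projected
        coords = rng.standard_normal((8, 3))
        ds = center_projected_directions(self._proj([0, 1, 3, 5, 7, 14, 21, 30], coords), 1)
        assert len(ds) == 6
        assert ds.labels == (3, 5, 7, 14, 21, 30)

    def test_two_point_series(self):
        ds = center_projected_directions(self._proj([0, 3], [[0, 0, 0], [0, 2, 0]]), 0)
        assert len(ds) == 1
        assert ds.directions[0] == pytest.approx([0, 1, 0])

    def test_coincident_point_names_the_day(self):
        coords = [[0, 0, 0], [1, 0, 0], [0, 0, 0]]
        with pytest.raises(UndefinedDirectionError, match="day 5"):
            center_projected_directions(self._proj([0, 1, 5], coords), 0)

    def test_missing_center_day(self, rng):
        with pytest.raises(ValidationError):
            center_projected_directions(
                self._proj([0, 1], rng.standard_normal((2, 3))), 2
            )

    def test_directions_are_unit(self, rng):
        coords = 10 * rng.standard_normal((5, 3))
        ds = center_projected_directions(self._proj([0, 1, 2, 3, 4], coords), 0)
        assert np.linalg.norm(ds.directions, axis=1) == pytest.approx(np.ones(4))


class TestMinEnclosingCircle:
    def test_single_direction(self):
        c = min_enclosing_circle(np.array([[0.0, 0.0, 1.0]]))
        assert c.radius_deg == 0.0
        assert c.center == pytest.approx([0, 0, 1])

    def test_two_orthogonal_directions(self):
        c = min_enclosing_circle(np.array([[1.0, 0, 0], [0, 1.0, 0]]))
        assert c.radius_deg == pytest.approx(45.0, abs=1e-7)
        assert c.center == pytest.approx(np.array([1, 1, 0]) / np.sqrt(2), abs=1e-7)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            min_enclosing_circle(np.empty((0, 3)))

    @pytest.mark.parametrize("spread", [None, 0.3])
    def test_matches_combinatorial_oracle(self, rng, spread):
        for _ in range(100):
            n = int(rng.integers(1, 9))
            D = random_directions(rng, n, spread=spread)
            circle = min_enclosing_circle(D)
            assert circle.radius_deg == pytest.approx(
                enclosing_radius_oracle(D), abs=1e-6
            )

    def test_radius_covers_all_points(self, rng):
        for _ in range(50):
            D = random_directions(rng, int(rng.integers(2, 9)))
            circle = min_enclosing_circle(D)
            worst = max(angular_distance(circle.center, u) for u in D)
            assert worst <= circle.radius_deg + 1e-6

    def test_rotation_invariance(self, rng):
        D = random_directions(rng, 7)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        r1 = min_enclosing_circle(D).radius_deg
        r2 = min_enclosing_circle(D @ q.T).radius_deg
        assert r1 == pytest.approx(r2, abs=1e-8)

    def test_high_dimension_agrees_with_low_rank_embedding(self, rng):
        # directions living in a 3-space of R^50 must give the S^2 answer
        D = random_directions(rng, 6, spread=0.4)
        basis, _ = np.linalg.qr(rng.standard_normal((50, 3)))
        embedded = D @ basis.T
        r_low = min_enclosing_circle(D).radius_deg
        r_high = min_enclosing_circle(embedded).radius_deg
        assert r_high == pytest.approx(r_low, abs=1e-6)


class TestSphericalSd:
    def test_identical_directions(self):
        D = np.tile(np.array([0.0, 1.0, 0.0]), (4, 1))
        s = spherical_sd(D)
        assert s.sd_deg == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("theta", [10.0, 40.0, 120.0])
    def test_two_directions_split_the_angle(self, theta):
        u = np.array([0.0, 0.0, 1.0])
        v = rotate_2d(u, theta, axis_a=2, axis_b=0)
        s = spherical_sd(np.array([u, v]))
        assert s.sd_deg == pytest.approx(theta / 2.0, abs=1e-6)
        mid = (u + v) / np.linalg.norm(u + v)
        assert abs(s.sd_center @ mid) == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_oracle(self, rng):
        for _ in range(12):
            D = random_directions(rng, int(rng.integers(2, 9)),
                                  spread=float(rng.uniform(0.2, 2.0)))
            s = spherical_sd(D)
            assert s.sd_deg == pytest.approx(spherical_sd_oracle(D), abs=0.1)

    def test_sd_never_exceeds_enclosing_radius(self, rng):
        for _ in range(200):
            D = random_directions(rng, int(rng.integers(1, 9)),
                                  spread=float(rng.uniform(0.1, 3.0)))
            sd = spherical_sd(D).sd_deg
            radius = min_enclosing_circle(D).radius_deg
            assert sd <= radius + 1e-6

    def test_rotation_invariance(self, rng):
        D = random_directions(rng, 6, spread=0.5)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        assert spherical_sd(D).sd_deg == pytest.approx(
            spherical_sd(D @ q.T).sd_deg, abs=1e-8
        )


class TestDiscrimination:
    def _cluster(self, axis_pair, half_angle):
        """Two points +-half_angle about an axis, within a coordinate plane."""
        base = np.zeros(3)
        base[axis_pair[0]] = 1.0
        return np.array([
            rotate_2d(base, half_angle, *axis_pair),
            rotate_2d(base, -half_angle, *axis_pair),
        ])

    def test_constructed_clusters(self):
        # two 2-point clusters, each +-5 deg about centers 90 deg apart
        a = DirectionSet(self._cluster((0, 1), 5.0))
        b = DirectionSet(self._cluster((1, 2), 5.0))
        assert discrimination(a, b) == pytest.approx(90.0 / 5.0, abs=1e-6)

    def test_identical_sets_give_zero(self, rng):
        D = random_directions(rng, 5, spread=0.5)
        a, b = DirectionSet(D), DirectionSet(D.copy())
        assert discrimination(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_matches_manual_composition(self, rng):
        da = DirectionSet(random_directions(rng, 6, spread=0.4))
        db = DirectionSet(random_directions(rng, 5, spread=0.4))
        sa, sb = spherical_sd(da), spherical_sd(db)
        expected = angular_distance(sa.sd_center, sb.sd_center) / max(sa.sd_deg, sb.sd_deg)
        assert discrimination(da, db) == pytest.approx(expected, rel=1e-9)

    def test_zero_spread_pair_is_undefined(self):
        a = DirectionSet(np.array([[1.0, 0, 0]]))
        b = DirectionSet(np.array([[0, 1.0, 0]]))
        with pytest.raises(DegenerateDataError):
            discrimination(a, b)

    def test_rotation_invariance(self, rng):
        da = random_directions(rng, 6, spread=0.4)
        db = random_directions(rng, 5, spread=0.4)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        d1 = discrimination(DirectionSet(da), DirectionSet(db))
        d2 = discrimination(DirectionSet(da @ q.T), DirectionSet(db @ q.T))
        assert d1 == pytest.approx(d2, abs=1e-8)
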