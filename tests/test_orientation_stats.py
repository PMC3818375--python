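import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fabricgait import synthetic_data as sd
from fabricgait.orientation_stats import (
    AxisOnSphere,
    StatsError,
    canonicalize_axis,
    exact_rank_sum,
    haversine_deg,
    permutation_test_median,
    permutation_test_sphere,
    spherical_centroid,
    stereo_invert,
    stereo_project,
    to_lonlat,
)

from conftest import axis_error_deg


# ---------------------------------------------------------------------------
# Independent brute-force oracles (deliberately simple, pure Python)


def brute_force_median_p(a, b):
    pool = list(a) + list(b)
    n, n_a = len(pool), len(a)
    obs = abs(float(np.median(a)) - float(np.median(b)))
    hits = total = 0
    for bits in range(2**n):
        if bin(bits).count("1") != n_a:
            continue
        ga = [pool[i] for i in range(n) if bits >> i & 1]
        gb = [pool[i] for i in range(n) if not bits >> i & 1]
        stat = abs(float(np.median(ga)) - float(np.median(gb)))
        total += 1
        if stat >= obs - 1e-12:
            hits += 1
    return hits / total


def brute_force_sphere_p(axes_a, axes_b, axial=True):
    def centroid(axes):
        m = np.mean([ax.xyz for ax in axes], axis=0)
        return m / np.linalg.norm(m)

    def dist(axes_a, axes_b):
        d = float(np.dot(centroid(axes_a), centroid(axes_b)))
        if axial:
            d = abs(d)
        return math.degrees(math.acos(max(-1.0, min(1.0, d))))

    pool = list(axes_a) + list(axes_b)
    n, n_a = len(pool), len(axes_a)
    obs = dist(axes_a, axes_b)
    hits = total = 0
    for bits in range(2**n):
        if bin(bits).count("1") != n_a:
            continue
        ga = [pool[i] for i in range(n) if bits >> i & 1]
        gb = [pool[i] for i in range(n) if not bits >> i & 1]
        total += 1
        if dist(ga, gb) >= obs - 1e-9:
            hits += 1
    return hits / total


def brute_force_rank_sum_p(a, b):
    from scipy.stats import rankdata

    pool = np.concatenate([a, b])
    n, n_a = len(pool), len(a)
    ranks = rankdata(pool)
    obs = abs(ranks[:n_a].sum() - n_a * (n + 1) / 2.0)
    hits = total = 0
    for comb in combinations(range(n), n_a):
        stat = abs(ranks[list(comb)].sum() - n_a * (n + 1) / 2.0)
        total += 1
        if stat >= obs - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Representation


class TestAxisRepresentation:
    def test_canonicalization_antipodal(self, rng):
        for _ in range(50):
            v = rng.normal(size=3)
            assert np.allclose(canonicalize_axis(v), canonicalize_axis(-v))

    def test_canonicalization_idempotent(self, rng):
        for _ in range(50):
            v = canonicalize_axis(rng.normal(size=3))
            assert np.allclose(canonicalize_axis(v), v)

    def test_lonlat_conventions(self):
        # posterior = +x at longitude 0, lateral = +y at 90, distal pole at
        # latitude 90
        assert to_lonlat([1, 0, 0]) == pytest.approx((0.0, 0.0))
        assert to_lonlat([0, 1, 0]) == pytest.approx((90.0, 0.0))
        assert to_lonlat([-1, 0, 0]) == pytest.approx((180.0, 0.0))
        assert to_lonlat([0, 0, 1])[1] == pytest.approx(90.0)

    def test_pole_projects_to_origin(self):
        assert stereo_project(0.0, 90.0) == pytest.approx((0.0, 0.0))

    def test_equator_projects_to_unit_circle(self):
        x, y = stereo_project(30.0, 0.0)
        assert math.hypot(x, y) == pytest.approx(1.0)

    def test_projection_round_trip(self, rng):
        for _ in range(100):
            ax = AxisOnSphere.from_vector(rng.normal(size=3))
            lon, lat = ax.lonlat
            lon2, lat2 = stereo_invert(*stereo_project(lon, lat))
            assert abs(lat - lat2) < 1e-9
            assert min(abs(lon - lon2), 360 - abs(lon - lon2)) < 1e-9

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            to_lonlat([0, 0, 0])


class TestHaversine:
    def test_quarter_circle(self):
        a = AxisOnSphere.from_lonlat(0, 0)
        b = AxisOnSphere.from_lonlat(90, 0)
        assert haversine_deg(a, b) == pytest.approx(90.0)

    def test_identical_zero(self):
        c = AxisOnSphere.from_lonlat(123, 45)
        assert haversine_deg(c, c) == 0.0

    def test_axial_antipodal_zero(self):
        a = AxisOnSphere.from_lonlat(10, 0)
        b = AxisOnSphere.from_lonlat(190, 0)
        assert haversine_deg(a, b, axial=True) == pytest.approx(0.0, abs=1e-9)

    def test_matches_arccos_dot(self, rng):
        for _ in range(200):
            a = AxisOnSphere.from_vector(rng.normal(size=3))
            b = AxisOnSphere.from_vector(rng.normal(size=3))
            want = math.degrees(
                math.acos(max(-1.0, min(1.0, float(np.dot(a.xyz, b.xyz)))))
            )
            assert haversine_deg(a, b) == pytest.approx(want, abs=1e-9)


class TestCentroid:
    def test_single_axis_identity(self):
        ax = AxisOnSphere.from_lonlat(42, 33)
        assert np.allclose(spherical_centroid([ax]).xyz, ax.xyz)

    def test_symmetric_pair(self):
        a = AxisOnSphere.from_vector([math.sin(math.radians(10)), 0, math.cos(math.radians(10))])
        b = AxisOnSphere.from_vector([-math.sin(math.radians(10)), 0, math.cos(math.radians(10))])
        cen = spherical_centroid([a, b])
        assert axis_error_deg(cen.xyz, [0, 0, 1]) < 1e-6

    def test_watson_sample_convergence(self):
        axes = sd.sample_axes([0, 0, 1], 20, 500, seed=0)
        assert axis_error_deg(spherical_centroid(axes).xyz, [0, 0, 1]) < 3.0


# ---------------------------------------------------------------------------
# Permutation tests vs oracles


class TestMedianPermutation:
    def test_three_vs_three_enumeration(self):
        # oracle-verified: 4 of 20 allocations reach |dmedian| >= 9
        # ({1,2,3}, {1,2,10} and their complements), so p = 0.20
        a, b = [1, 2, 3], [10, 11, 12]
        res = permutation_test_median(a, b)
        assert res.mode == "exhaustive"
        assert res.n_allocations == 20
        assert res.observed == 9.0
        assert res.p_value == pytest.approx(brute_force_median_p(a, b)) == 0.20

    def test_identical_groups(self):
        res = permutation_test_median([5, 5, 5], [5, 5, 5])
        assert res.observed == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("na,nb", [(2, 3), (3, 3), (4, 3), (5, 5), (4, 6)])
    def test_matches_brute_force(self, rng, na, nb):
        a = rng.normal(size=na).tolist()
        b = rng.normal(0.5, 1.0, size=nb).tolist()
        res = permutation_test_median(a, b)
        assert res.p_value == pytest.approx(brute_force_median_p(a, b))

    def test_monte_carlo_within_binomial_interval(self, rng):
        a = rng.normal(size=6).tolist()
        b = rng.normal(1.0, 1.0, size=6).tolist()
        exact = permutation_test_median(a, b).p_value
        mc = permutation_test_median(a, b, max_exact=1, n_draws=10_000, seed=3)
        assert mc.mode == "monte_carlo"
        half_width = 2.576 * math.sqrt(exact * (1 - exact) / 10_000)
        assert abs(mc.p_value - exact) <= half_width + 2e-4

    def test_label_symmetry(self, rng):
        a = rng.normal(size=5).tolist()
        b = rng.normal(size=4).tolist()
        assert (
            permutation_test_median(a, b).p_value
            == permutation_test_median(b, a).p_value
        )

    def test_empty_group_errors(self):
        with pytest.raises(StatsError):
            permutation_test_median([], [1.0])


class TestSpherePermutation:
    @pytest.fixture
    def clusters(self):
        a = sd.sample_axes([0, 0, 1], 500, 3, seed=0)
        t = math.radians(40)
        b = sd.sample_axes([math.sin(t), 0, math.cos(t)], 500, 3, seed=1)
        return a, b

    def test_two_tight_clusters(self, clusters):
        a, b = clusters
        res = permutation_test_sphere(a, b)
        assert res.mode == "exhaustive"
        assert res.n_allocations == 20
        assert res.p_value == pytest.approx(2 / 20)

    def test_matches_brute_force(self, clusters):
        a, b = clusters
        res = permutation_test_sphere(a, b)
        assert res.p_value == pytest.approx(brute_force_sphere_p(a, b))

    @pytest.mark.parametrize("na,nb", [(2, 4), (3, 4), (4, 4)])
    def test_matches_brute_force_diffuse(self, na, nb):
        a = sd.sample_axes([0.2, 0.1, 0.97], 5, na, seed=na)
        b = sd.sample_axes([0.5, 0.5, 0.7], 5, nb, seed=10 + nb)
        res = permutation_test_sphere(a, b)
        assert res.p_value == pytest.approx(brute_force_sphere_p(a, b))

    def test_label_symmetry(self, clusters):
        a, b = clusters
        assert (
            permutation_test_sphere(a, b).p_value
            == permutation_test_sphere(b, a).p_value
        )

    def test_outlier_exclusion_option(self, clusters):
        a, b = clusters
        outlier = AxisOnSphere.from_lonlat(91.5, 9.3)
        res_with = permutation_test_sphere(a + [outlier], b)
        res_without = permutation_test_sphere(a + [outlier], b, exclude_a=[3])
        assert res_without.p_value == permutation_test_sphere(a, b).p_value
        assert res_with.p_value != res_without.p_value

    def test_too_small_group_errors(self):
        a = sd.sample_axes([0, 0, 1], 5, 1, seed=0)
        b = sd.sample_axes([0, 0, 1], 5, 3, seed=1)
        with pytest.raises(StatsError):
            permutation_test_sphere(a, b)


class TestExactRankSum:
    def test_textbook_case(self):
        assert exact_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.10)

    def test_identical_samples(self):
        assert exact_rank_sum([3, 3, 3], [3, 3, 3]) == 1.0

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (5, 5)])
    def test_matches_brute_force(self, rng, na, nb):
        a = rng.normal(size=na)
        b = rng.normal(0.8, 1.0, size=nb)
        assert exact_rank_sum(a, b) == pytest.approx(brute_force_rank_sum_p(a, b))

    def test_matches_brute_force_with_ties(self):
        a = [1.0, 2.0, 2.0, 5.0]
        b = [2.0, 3.0, 3.0]
        assert exact_rank_sum(a, b) == pytest.approx(brute_force_rank_sum_p(a, b))

    def test_agrees_with_normal_approximation(self, rng):
        from scipy.stats import ranksums

        a = rng.normal(size=15)
        b = rng.normal(0.7, 1.0, size=15)
        assert abs(exact_rank_sum(a, b) - ranksums(a, b).pvalue) < 0.02


# ---------------------------------------------------------------------------
# Hypothesis property tests


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=5),
       st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=5))
def test_median_p_bounds_and_symmetry(a, b):
    res = permutation_test_median(a, b)
    assert 1.0 / res.n_allocations <= res.p_value <= 1.0
    assert res.p_value == permutation_test_median(b, a).p_value


@settings(max_examples=50, deadline=None)
@given(st.tuples(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)))
def test_axis_canonical_form(v):
    import math as m

    if m.hypot(*v) < 1e-6:
        return
    c = canonicalize_axis(np.array(v))
    assert np.isclose(np.linalg.norm(c), 1.0)
    assert c[2] > 0 or (c[2] == 0 and (c[0] < 0 or (c[0] == 0 and c[1] >= 0)))
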