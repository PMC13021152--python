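"""Spatial summary statistics and the permutation clustering test.

The K, G and g estimators are checked against independent brute-force
double-loop implementations of the same formulas, and against each other via
the K'(r)/(2 pi r) ~ g(r) identity on CSR averages.
"""

import math

import numpy as np
import pandas as pd
import pytest

from spatialsim import (
    Window,
    nn_cooccurrence,
    nn_g,
    pair_correlation,
    permutation_envelope,
    permutation_test,
    ripleys_k,
)

WIN = Window(-1, 1, -1, 1)


# ---------------------------------------------------------------------------
# brute-force oracles: plain Python double loops, no shared code


def brute_k(pts, radii, win):
    n = len(pts)
    area = (win.xmax - win.xmin) * (win.ymax - win.ymin)
    out = []
    for r in radii:
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dx = abs(pts[i][0] - pts[j][0])
                dy = abs(pts[i][1] - pts[j][1])
                d = math.hypot(dx, dy)
                if d <= r:
                    w = area / ((win.xmax - win.xmin - dx) * (win.ymax - win.ymin - dy))
                    total += w
        out.append(area / (n * (n - 1)) * total)
    return out


def brute_g_nn(pts, radii, win):
    n = len(pts)
    out = []
    for r in radii:
        num = denom = 0
        for i in range(n):
            b = min(pts[i][0] - win.xmin, win.xmax - pts[i][0],
                    pts[i][1] - win.ymin, win.ymax - pts[i][1])
            if b <= r:
                continue
            denom += 1
            nnd = min(math.dist(pts[i], pts[j]) for j in range(n) if j != i)
            if nnd <= r:
                num += 1
        out.append(float("nan") if denom == 0 else num / denom)
    return out


def brute_pcf(pts, radii, win, bw):
    n = len(pts)
    area = (win.xmax - win.xmin) * (win.ymax - win.ymin)
    h = bw * math.sqrt(5)  # Epanechnikov support half-width from its sd
    out = []
    for r in radii:
        if r <= 0:
            out.append(float("nan"))
            continue
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dx = abs(pts[i][0] - pts[j][0])
                dy = abs(pts[i][1] - pts[j][1])
                d = math.hypot(dx, dy)
                if abs(r - d) <= h:
                    kern = 0.75 / h * (1 - ((r - d) / h) ** 2)
                    w = area / ((win.xmax - win.xmin - dx) * (win.ymax - win.ymin - dy))
                    total += kern * w
        out.append(total * area / (2 * math.pi * r * n * (n - 1)))
    return out


@pytest.fixture
def csr_patterns(rng):
    """200 CSR patterns at intensity 250 on the 2x2 window."""
    pats = []
    for _ in range(200):
        n = rng.poisson(1000)
        pats.append(np.column_stack([rng.uniform(-1, 1, n), rng.uniform(-1, 1, n)]))
    return pats


class TestOracleEquivalence:
    """Vectorized estimators equal naive double loops on 20-point instances."""

    @pytest.fixture
    def pts20(self, rng):
        return rng.uniform(-1, 1, size=(20, 2))

    def test_ripleys_k(self, pts20):
        radii = np.array([0.1, 0.3, 0.5, 0.9])
        got = ripleys_k(pts20, radii, WIN).estimate
        np.testing.assert_allclose(got, brute_k(pts20.tolist(), radii, WIN),
                                   rtol=1e-12)

    def test_nn_g(self, pts20):
        radii = np.array([0.05, 0.2, 0.5])
        got = nn_g(pts20, radii, WIN).estimate
        np.testing.assert_allclose(got, brute_g_nn(pts20.tolist(), radii, WIN),
                                   rtol=1e-12)

    def test_pair_correlation(self, pts20):
        radii = np.array([0.2, 0.4])
        got = pair_correlation(pts20, radii, WIN, bandwidth=0.1).estimate
        np.testing.assert_allclose(got, brute_pcf(pts20.tolist(), radii, WIN, 0.1),
                                   rtol=1e-12)


class TestRipleysK:
    def test_three_point_hand_case(self):
        # unit window; only the (p1, p2) pair lies within r = 0.15
        pts = np.array([[0.1, 0.5], [0.2, 0.5], [0.9, 0.5]])
        win = Window(0, 1, 0, 1)
        got = ripleys_k(pts, np.array([0.15]), win).estimate[0]
        expected = brute_k(pts.tolist(), [0.15], win)[0]
        assert got == expected
        assert got == pytest.approx((2 / 0.9) / 6)

    def test_zero_radius(self, rng):
        pts = rng.uniform(-1, 1, size=(30, 2))
        assert ripleys_k(pts, np.array([0.0, 0.2]), WIN).estimate[0] == 0.0

    def test_csr_closed_form(self, csr_patterns):
        vals = np.array([ripleys_k(p, np.array([0.25]), WIN).estimate[0]
                         for p in csr_patterns])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - np.pi * 0.25**2) < 3 * se

    def test_theoretical_column(self):
        r = np.array([0.1, 0.2])
        curve = ripleys_k(np.random.default_rng(0).uniform(-1, 1, (10, 2)), r, WIN)
        np.testing.assert_allclose(curve.theoretical, np.pi * r**2)

    def test_radii_beyond_half_window_rejected(self, rng):
        pts = rng.uniform(-1, 1, size=(10, 2))
        with pytest.raises(ValueError):
            ripleys_k(pts, np.array([1.5]), WIN)

    def test_single_point_gives_nan_curve(self):
        curve = ripleys_k(np.array([[0.0, 0.0]]), np.array([0.1]), WIN)
        assert np.isnan(curve.estimate).all()


class TestNnG:
    def test_two_point_cdf(self):
        # both points > 0.2 from every boundary, nearest-neighbour d = 0.1
        pts = np.array([[-0.05, 0.0], [0.05, 0.0]])
        got = nn_g(pts, np.array([0.05, 0.2]), WIN).estimate
        np.testing.assert_allclose(got, [0.0, 1.0])

    def test_zero_radius(self, rng):
        pts = rng.uniform(-1, 1, size=(30, 2))
        assert nn_g(pts, np.array([0.0, 0.1]), WIN).estimate[0] == 0.0

    def test_csr_closed_form(self, csr_patterns):
        vals = np.array([nn_g(p, np.array([0.03]), WIN).estimate[0]
                         for p in csr_patterns])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        expected = 1 - math.exp(-250 * math.pi * 0.03**2)
        assert abs(vals.mean() - expected) < 3 * se


class TestPairCorrelation:
    def test_zero_radius_missing(self, rng):
        pts = rng.uniform(-1, 1, size=(30, 2))
        est = pair_correlation(pts, np.array([0.0, 0.2]), WIN).estimate
        assert np.isnan(est[0]) and np.isfinite(est[1])

    def test_csr_reference_is_one(self, csr_patterns):
        radii = np.array([0.1, 0.2])
        vals = np.array([pair_correlation(p, radii, WIN).estimate
                         for p in csr_patterns])
        for col in range(2):
            se = vals[:, col].std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals[:, col].mean() - 1.0) < 3 * se

    def test_tight_cluster_exceeds_one(self, rng):
        pts = rng.normal(0, 0.05, size=(100, 2))
        val = pair_correlation(pts, np.array([0.05]), WIN).estimate[0]
        assert val > 1

    def test_k_derivative_identity(self, csr_patterns):
        """Central-difference K'(r) / (2 pi r) agrees with g(r) on CSR
        averages within 15% relative error."""
        radii = np.array([0.09, 0.1, 0.11, 0.19, 0.2, 0.21])
        ks, gs = [], []
        for p in csr_patterns[:100]:
            ks.append(ripleys_k(p, radii, WIN).estimate)
            gs.append(pair_correlation(p, np.array([0.1, 0.2]), WIN).estimate)
        kbar = np.mean(ks, axis=0)
        gbar = np.mean(gs, axis=0)
        for mid, (lo, hi) in zip((0.1, 0.2), ((0, 2), (3, 5))):
            deriv = (kbar[hi] - kbar[lo]) / 0.02
            g_from_k = deriv / (2 * np.pi * mid)
            idx = 0 if mid == 0.1 else 1
            assert abs(g_from_k - gbar[idx]) / gbar[idx] < 0.15


class TestEstimatorProperties:
    def test_translation_invariance(self, rng):
        pts = rng.uniform(-1, 1, size=(40, 2))
        radii = np.array([0.1, 0.3])
        shift = np.array([5.0, -3.0])
        win2 = Window(-1 + shift[0], 1 + shift[0], -1 + shift[1], 1 + shift[1])
        for fn in (ripleys_k, nn_g, pair_correlation):
            a = fn(pts, radii, WIN).estimate
            b = fn(pts + shift, radii, win2).estimate
            np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_translation_weights_at_least_one(self, rng):
        from spatialsim.stats import _PairData
        pts = rng.uniform(-1, 1, size=(25, 2))
        pd_ = _PairData(pts, WIN)
        off = ~np.eye(25, dtype=bool)
        assert (pd_.w[off] >= 1.0).all()
        # equality only for coincident points
        assert (pd_.w[off] > 1.0).all()
        both = np.vstack([pts[:1], pts[:1]])
        assert _PairData(both, WIN).w[0, 1] == 1.0


class TestPermutationTest:
    def make_clustered(self, rng, n=100, m=10):
        pts = rng.uniform(-1, 1, size=(n, 2))
        pts[:m] = rng.normal(0, 0.02, size=(m, 2))  # tight clump
        pos = np.zeros(n, dtype=bool)
        pos[:m] = True
        return pts, pos

    def test_extreme_clustering_minimum_p(self, rng):
        # observed K exceeds every permutation value: p = 1/101
        pts, pos = self.make_clustered(rng)
        res = permutation_test(pts, pos, WIN, np.array([0.1]), stats=("K",),
                               n_perm=100, rng=1)
        assert res["K"].p_value[0] == pytest.approx(1 / 101)

    def test_constant_marker_invariance(self, rng):
        # every permutation reproduces the observed set exactly
        pts = rng.uniform(-1, 1, size=(50, 2))
        pos = np.ones(50, dtype=bool)
        res = permutation_test(pts, pos, WIN, np.array([0.1, 0.2]),
                               n_perm=20, rng=2)
        for s in ("K", "G", "g"):
            np.testing.assert_allclose(res[s].degree_of_clustering, 0, atol=1e-12)
            np.testing.assert_allclose(res[s].p_value, 1.0)

    def test_positive_count_conserved_and_degree_definition(self, rng):
        pts, pos = self.make_clustered(rng)
        res = permutation_test(pts, pos, WIN, np.array([0.1]), n_perm=30, rng=3)
        for s, r in res.items():
            assert r.n_positive == pos.sum()
            np.testing.assert_allclose(
                r.degree_of_clustering, r.observed - r.null_mean)

    def test_too_few_positives_non_evaluable(self, rng):
        pts = rng.uniform(-1, 1, size=(30, 2))
        pos = np.zeros(30, dtype=bool)
        pos[0] = True
        res = permutation_test(pts, pos, WIN, np.array([0.1]), rng=4)
        assert not res["K"].evaluable
        assert np.isnan(res["K"].p_value).all()

    def test_fifty_radii_grid(self, rng):
        from spatialsim import default_radii
        pts, pos = self.make_clustered(rng, n=60, m=12)
        res = permutation_test(pts, pos, WIN, default_radii(), stats=("G",),
                               n_perm=5, rng=5)
        assert res["G"].radii.size == 50

    def test_envelope_wrapper_matches_marker_column(self, rng):
        pts, pos = self.make_clustered(rng)
        df = pd.DataFrame({"Sample": 1, "x": pts[:, 0], "y": pts[:, 1],
                           "Cell 1 Assignment": pos.astype(int)})
        res = permutation_envelope(df, "Cell 1 Assignment", "K",
                                   np.array([0.1]), WIN, n_perm=50, rng=6)
        assert res.stat == "K" and res.n_positive == pos.sum()
        assert res.significant(0.05).dtype == bool
        with pytest.raises(ValueError):
            permutation_envelope(df, "nope", "K", np.array([0.1]), WIN)


def test_nn_cooccurrence_basic():
    a = np.array([[0.0, 0.0], [0.5, 0.5]])
    b = np.array([[0.05, 0.0]])
    assert nn_cooccurrence(a, b, 0.1) == pytest.approx(0.5)
    assert math.isnan(nn_cooccurrence(a, np.empty((0, 2)), 0.1))
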