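"""The five statistics against independent brute-force oracles, their
null-model behavior, and the classification logic."""

import numpy as np
import pandas as pd
import pytest

from tumoroid.population import Population
from tumoroid.spatial_stats import (
    AssBand,
    CellTable,
    ExperimentalRanges,
    UndefinedStatistic,
    a_ss,
    a_ss_band,
    a_ss_scan,
    centrality_index,
    classify,
    compute_report,
    cross_section,
    entropy_index,
    morans_I,
    stem_percentage,
)
from tumoroid.synthetic_patterns import PatternSpec, gen_clustered, gen_random

RADIUS = 15.0


# -- brute-force oracles (direct double loops, no spatial index) ------------

def moran_oracle(table, radius=RADIUS):
    n = len(table)
    x = table.stem.astype(float)
    m = x.mean()
    z = x - m
    xy = table.xy
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and np.hypot(*(xy[i] - xy[j])) <= radius:
                w[i, j] = 1.0
    rowsums = w.sum(axis=1)
    for i in range(n):
        if rowsums[i] > 0:
            w[i] /= rowsums[i]
    W = w.sum()
    return n * (z @ w @ z) / (W * (z @ z))


def entropy_oracle(table, bins=64):
    stem_xy = table.xy[table.stem]
    dists = []
    for i in range(len(stem_xy)):
        for j in range(i + 1, len(stem_xy)):
            dists.append(np.hypot(*(stem_xy[i] - stem_xy[j])))
    diam = max(
        np.hypot(*(table.xy[i] - table.xy[j]))
        for i in range(len(table))
        for j in range(i + 1, len(table))
    )
    edges = np.linspace(0, diam, bins + 1)
    counts, _ = np.histogram(dists, bins=edges)
    p = counts[counts > 0] / counts.sum()
    return -(p * np.log(p)).sum()


def centrality_oracle(table):
    c = table.xy.mean(axis=0)
    ds = [np.hypot(*(p - c)) for p in table.xy[table.stem]]
    dd = [np.hypot(*(p - c)) for p in table.xy[~table.stem]]
    return np.mean(ds) / np.mean(dd)


def ass_oracle(table, r):
    xy = table.xy
    stem_idx = np.flatnonzero(table.stem)
    n_t, n_s = len(table), len(stem_idx)
    total = 0.0
    for i in stem_idx:
        ns = nt = 0
        for j in range(n_t):
            if j == i:
                continue
            if np.hypot(*(xy[i] - xy[j])) <= r:
                nt += 1
                if table.stem[j]:
                    ns += 1
        total += ns / nt if nt > 0 else 1.0
    return (n_t - 1) / (n_s * (n_s - 1)) * total


class TestOracleEquivalence:
    """Each statistic matches its direct double-loop oracle on tables of
    up to 300 cells."""

    @pytest.mark.parametrize("seed", range(3))
    def test_all_statistics(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(60, 300))
        xy = r.uniform(0, 150, size=(n, 2))
        stem = r.random(n) < 0.2
        stem[:3] = True
        stem[-3:] = False
        t = CellTable(xy[:, 0], xy[:, 1], stem)
        assert stem_percentage(t) == pytest.approx(100 * stem.mean(), rel=1e-12)
        assert morans_I(t) == pytest.approx(moran_oracle(t), rel=1e-9)
        assert entropy_index(t) == pytest.approx(entropy_oracle(t), rel=1e-9)
        assert centrality_index(t) == pytest.approx(centrality_oracle(t), rel=1e-9)
        for rad in (10.0, 25.0):
            assert a_ss(t, rad) == pytest.approx(ass_oracle(t, rad), rel=1e-9)


class TestStemPercentage:
    def test_arithmetic(self):
        t = CellTable(np.arange(100.0), np.zeros(100), np.arange(100) < 10)
        assert stem_percentage(t) == pytest.approx(10.0)

    def test_all_stem(self):
        t = CellTable(np.arange(5.0), np.zeros(5), np.ones(5, bool))
        assert stem_percentage(t) == 100.0

    def test_binomial_generator_mean(self):
        vals = [
            stem_percentage(gen_random(PatternSpec(n=800, stem_fraction=0.05, seed=s)))
            for s in range(30)
        ]
        assert np.mean(vals) == pytest.approx(5.0, abs=0.5)


class TestMoransI:
    def test_permutation_null_mean(self, small_random_table):
        """Mean over random label permutations equals -1/(N-1)."""
        t = small_random_table
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(600):
            stem = rng.permutation(t.stem)
            vals.append(morans_I(CellTable(t.x, t.y, stem)))
        expected = -1.0 / (len(t) - 1)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 4 * se + 1e-4

    def test_two_blobs_strongly_clustered(self, two_blob_table):
        assert morans_I(two_blob_table) > 0.9

    def test_alternating_line_negative(self):
        n = 40
        x = np.arange(n) * 10.0  # spacing 10 um < 15 um radius
        t = CellTable(x, np.zeros(n), np.arange(n) % 2 == 0)
        assert morans_I(t) < 0

    def test_bounded(self, small_random_table, two_blob_table):
        for t in (small_random_table, two_blob_table):
            assert -1 - 1e-9 <= morans_I(t) <= 1 + 1e-9

    def test_single_label_undefined(self):
        t = CellTable(np.arange(10.0), np.zeros(10), np.ones(10, bool))
        with pytest.raises(UndefinedStatistic):
            morans_I(t)

    def test_no_neighbors_undefined(self):
        t = CellTable(np.arange(4.0) * 1000, np.zeros(4), np.array([1, 0, 1, 0], bool))
        with pytest.raises(UndefinedStatistic):
            morans_I(t)


class TestEntropyIndex:
    def test_single_bin_degenerate(self):
        # tight stem cluster: all pairwise distances in the first bin
        xy = np.array([[0, 0], [1, 0], [0, 1], [500, 500]], dtype=float)
        t = CellTable(xy[:, 0], xy[:, 1], np.array([1, 1, 1, 0], bool))
        assert entropy_index(t) == pytest.approx(0.0)

    def test_uniform_occupancy_gives_log_k(self):
        # stem pair distances engineered to fall in 3 distinct bins, twice each
        # diagonal set by two far differentiated corner cells
        stems = np.array([[0.0, 0.0], [10.0, 0.0], [30.0, 0.0], [60.0, 0.0]])
        # pairwise distances: 10,30,60,20,50,30 -> with bins over [0, diag]
        t = CellTable(
            np.concatenate([stems[:, 0], [0, 90]]),
            np.concatenate([stems[:, 1], [0, 90 * 0]]),
            np.array([1, 1, 1, 1, 0, 0], bool),
        )
        # oracle equivalence is the binding check; exact uniform occupancy
        assert entropy_index(t) == pytest.approx(entropy_oracle(t), rel=1e-9)

    def test_hand_computed_four_points(self):
        # 4 stem points on a 3-4-5 rectangle; 6 pairwise distances: 3,4,5,5,4,3
        x = np.array([0.0, 3.0, 0.0, 3.0, 0.0, 100.0])
        y = np.array([0.0, 0.0, 4.0, 4.0, 50.0, 0.0])
        stem = np.array([1, 1, 1, 1, 0, 0], bool)
        t = CellTable(x, y, stem)
        # diagonal = hypot(100, 50) ~= 111.8; 64 bins of width 1.747
        # distances {3: x2, 4: x2, 5: x2} fall in bins 1, 2, 2 -> p = (2/6, 4/6)
        expected = -(2 / 6 * np.log(2 / 6) + 4 / 6 * np.log(4 / 6))
        assert entropy_index(t) == pytest.approx(expected, rel=1e-9)

    def test_bounds(self, small_random_table):
        h = entropy_index(small_random_table, bins=64)
        assert 0 <= h <= np.log(64)

    def test_too_few_stem_undefined(self):
        t = CellTable(np.arange(5.0), np.zeros(5), np.array([1, 0, 0, 0, 0], bool))
        with pytest.raises(UndefinedStatistic):
            entropy_index(t)


class TestCentralityIndex:
    def test_point_symmetric_pattern(self):
        """Stem and differentiated cells exchanged by point reflection
        through the center give ratio 1."""
        r = np.random.default_rng(2)
        half = r.uniform(-50, 50, size=(30, 2))
        xy = np.vstack([half, -half]) + 100.0
        stem = np.array([True] * 30 + [False] * 30)
        t = CellTable(xy[:, 0], xy[:, 1], stem)
        assert centrality_index(t) == pytest.approx(1.0, rel=1e-9)

    def test_stem_at_center(self):
        xy = np.array([[50.0, 50], [50, 50], [0, 0], [100, 100], [0, 100], [100, 0]])
        stem = np.array([1, 1, 0, 0, 0, 0], bool)
        t = CellTable(xy[:, 0], xy[:, 1], stem)
        assert centrality_index(t) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed(self):
        # centroid of the 6 points is (2, 0)
        x = np.array([0.0, 4.0, 1.0, 3.0, 2.0, 2.0])
        y = np.array([0.0, 0.0, 0.0, 0.0, 1.0, -1.0])
        stem = np.array([1, 1, 0, 0, 0, 0], bool)
        t = CellTable(x, y, stem)
        assert centrality_index(t) == pytest.approx(2.0 / 1.0, rel=1e-12)

    def test_single_label_undefined(self):
        t = CellTable(np.arange(4.0), np.zeros(4), np.ones(4, bool))
        with pytest.raises(UndefinedStatistic):
            centrality_index(t)


class TestAss:
    def test_all_stem_exactly_one(self):
        r = np.random.default_rng(1)
        xy = r.uniform(0, 50, size=(40, 2))
        t = CellTable(xy[:, 0], xy[:, 1], np.ones(40, bool))
        assert a_ss(t, 10.0) == pytest.approx(1.0, rel=1e-12)

    def test_permutation_mean_is_one(self):
        """Normalization identity at histology-like density (every cell has
        neighbors; the 0/0 convention then never fires)."""
        r = np.random.default_rng(11)
        n = 400
        xy = r.uniform(0, 180, size=(n, 2))  # ~0.012 cells/um^2, as in sections
        stem = np.zeros(n, bool)
        stem[:40] = True
        t = CellTable(xy[:, 0], xy[:, 1], stem)
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(500):
            s = rng.permutation(t.stem)
            vals.append(a_ss(CellTable(t.x, t.y, s), RADIUS))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.02)

    def test_isolated_cells_bias_permutation_mean_upward(self, small_random_table):
        """With isolated neighborhoods present, the 0/0 -> 1 convention
        shifts the permutation mean strictly above 1."""
        t = small_random_table
        rng = np.random.default_rng(0)
        vals = [
            a_ss(CellTable(t.x, t.y, rng.permutation(t.stem)), RADIUS) for _ in range(200)
        ]
        assert np.mean(vals) > 1.0

    def test_clustered_pattern_exceeds_one(self):
        """Two tight stem clusters in a sparse field, small radius."""
        r = np.random.default_rng(4)
        bg = r.uniform(0, 300, size=(200, 2))
        c1 = r.normal([60, 60], 3, size=(10, 2))
        c2 = r.normal([220, 220], 3, size=(10, 2))
        xy = np.vstack([bg, c1, c2])
        stem = np.array([False] * 200 + [True] * 20)
        t = CellTable(xy[:, 0], xy[:, 1], stem)
        assert a_ss(t, 12.0) > 1.0

    def test_isolated_focal_cells_contribute_one(self):
        # two stem cells far apart with no neighbors at all: every ratio is
        # the 0/0 convention = 1, and the normalization gives (Nt-1)/(Ns-1)/Ns*Ns
        t = CellTable(np.array([0.0, 1000.0]), np.zeros(2), np.ones(2, bool))
        assert a_ss(t, 5.0) == pytest.approx((2 - 1) / (2 * 1) * 2)

    def test_too_few_stem_undefined(self):
        t = CellTable(np.arange(5.0), np.zeros(5), np.array([1, 0, 0, 0, 0], bool))
        with pytest.raises(UndefinedStatistic):
            a_ss(t, 5.0)


class TestAssBand:
    def test_clustered_pattern_rejected(self):
        spec = PatternSpec(n=600, stem_fraction=0.08, extent=300, structure="clustered",
                           n_clusters=3, cluster_sd=10.0, seed=5)
        t = gen_clustered(spec)
        rng = np.random.default_rng(0)
        val = a_ss(t, 12.0)
        band = a_ss_band(t, 12.0, n_perm=400, rng=rng)
        assert val > 1.0 + band.q

    def test_coverage_on_random_labels(self):
        """The Chebyshev-style band over-covers: rejection under the null is
        rarer than alpha."""
        rng = np.random.default_rng(1)
        rejections = 0
        n_rep = 40
        for s in range(n_rep):
            t = gen_random(PatternSpec(n=250, stem_fraction=0.1, extent=200, seed=100 + s))
            if t.n_stem < 2:
                continue
            val = a_ss(t, RADIUS)
            band = a_ss_band(t, RADIUS, n_perm=150, rng=rng)
            if band.rejects(val) and not band.degenerate:
                rejections += 1
        assert rejections / n_rep <= 0.1  # alpha = 0.05, conservative band

    def test_q_stable_under_more_permutations(self, small_random_table):
        t = small_random_table
        b1 = a_ss_band(t, RADIUS, n_perm=500, rng=np.random.default_rng(0))
        b2 = a_ss_band(t, RADIUS, n_perm=1000, rng=np.random.default_rng(1))
        assert b1.q == pytest.approx(b2.q, rel=0.25)

    def test_degenerate_band_flagged(self):
        t = CellTable(np.array([0.0, 500.0, 1000.0]), np.zeros(3), np.array([1, 1, 0], bool))
        band = a_ss_band(t, 5.0, n_perm=100)
        assert band.degenerate and band.q == 0.0


class TestAssScan:
    def test_tight_cluster_rejected_only_at_small_r(self):
        r = np.random.default_rng(6)
        bg = r.uniform(0, 400, size=(300, 2))
        cl = r.normal([200, 200], 5, size=(25, 2))
        xy = np.vstack([bg, cl])
        stem = np.array([False] * 300 + [True] * 25)
        t = CellTable(xy[:, 0], xy[:, 1], stem)
        curve, r_accept = a_ss_scan(t, [10, 40, 120, 250], n_perm=300,
                                    rng=np.random.default_rng(0))
        assert bool(curve.iloc[0]["rejected"])
        assert np.isfinite(r_accept)

    def test_csr_pattern_rarely_rejected(self):
        t = gen_random(PatternSpec(n=400, stem_fraction=0.1, extent=300, seed=9))
        curve, r_accept = a_ss_scan(t, [10, 30, 60], n_perm=300, rng=np.random.default_rng(0))
        assert curve["rejected"].sum() <= 1

    def test_larger_clusters_larger_rejection_radius(self):
        """Wider stem clusters stay significantly aggregated out to larger radii."""
        def accept_radius(sd, seed):
            spec = PatternSpec(n=900, stem_fraction=0.07, extent=400,
                               structure="clustered", n_clusters=1, cluster_sd=sd, seed=seed)
            t = gen_clustered(spec)
            grid = [5, 10, 20, 40, 80, 160, 320]
            _, r_acc = a_ss_scan(t, grid, n_perm=200, rng=np.random.default_rng(seed))
            return 640.0 if np.isnan(r_acc) else r_acc
        small = np.mean([accept_radius(5.0, s) for s in range(4)])
        large = np.mean([accept_radius(40.0, s) for s in range(4)])
        assert large > small


class TestClassify:
    @pytest.mark.parametrize(
        "value,band,expected",
        [
            (2.8, (2.8, 11.2), "within"),  # boundary inclusive
            (11.2, (2.8, 11.2), "within"),
            (12.0, (2.8, 11.2), "above"),
            (0.05, (0.09, 0.48), "below"),
        ],
    )
    def test_bands(self, value, band, expected):
        assert classify(value, band) == expected

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            classify(1.0, (2.0, 1.0))


class TestInvariances:
    def test_rigid_motion_invariance(self, small_random_table):
        """All five statistics are unchanged by global translation+rotation."""
        t = small_random_table
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy2 = t.xy @ R.T + np.array([37.0, -12.0])
        t2 = CellTable(xy2[:, 0], xy2[:, 1], t.stem)
        assert stem_percentage(t2) == stem_percentage(t)
        assert morans_I(t2) == pytest.approx(morans_I(t), rel=1e-9)
        assert entropy_index(t2) == pytest.approx(entropy_index(t), rel=1e-6)
        assert centrality_index(t2) == pytest.approx(centrality_index(t), rel=1e-9)
        assert a_ss(t2, RADIUS) == pytest.approx(a_ss(t, RADIUS), rel=1e-9)


class TestCrossSection:
    def make_pop(self, z_values, radii_volume=1.0):
        n = len(z_values)
        pos = np.column_stack([np.full(n, 40.0), np.full(n, 40.0), z_values])
        return Population(
            positions=pos,
            volume=np.full(n, radii_volume),
            is_stem=np.ones(n, bool),
            M=np.zeros((n, 3)),
            P=np.zeros((n, 3)),
        )

    def test_cell_on_plane_included(self):
        pop = self.make_pop([40.0])
        t = cross_section(pop, 0.5)
        assert len(t) == 1

    def test_boundary_rule(self):
        r1 = 0.6203504909  # radius of V = 1
        pop = self.make_pop([40.0 + 1.01 * r1, 40.0 + 0.99 * r1])
        t = cross_section(pop, 0.5)
        assert len(t) == 1

    def test_micron_conversion(self):
        pop = self.make_pop([40.0])
        t = cross_section(pop, 0.5)
        assert t.x[0] == pytest.approx(40.0 * 6.4)


class TestComputeReport:
    def test_report_classification_consistency(self, small_random_table):
        rep = compute_report(small_random_table)
        assert set(rep.classification) == {"percentage", "morans_i", "entropy", "centrality"}
        for key, cls in rep.classification.items():
            band = getattr(ExperimentalRanges(), key)
            assert classify(getattr(rep, key), band) == cls
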