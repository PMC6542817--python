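from types import SimpleNamespace

import numpy as np
import pytest
from scipy.spatial import Delaunay
from scipy.spatial.distance import cdist

from tesseloc import (
    LocalizationSet,
    build_tessellation,
    classify,
    pair_densities,
)
from tesseloc.classification import (
    PairDescriptorTable,
    build_triangle_set,
    edge_correct,
)
from tesseloc.errors import ConfigError


def make_pairs(x_A, y_A, x_B=None, y_B=None):
    x_A = np.asarray(x_A, float)
    y_A = np.asarray(y_A, float)
    x_B = x_A if x_B is None else np.asarray(x_B, float)
    y_B = y_A if y_B is None else np.asarray(y_B, float)
    return PairDescriptorTable(
        x_A=x_A, y_A=y_A, partner_A=np.zeros(x_A.size, int),
        x_B=x_B, y_B=y_B, partner_B=np.zeros(x_B.size, int),
    )


class TestPairDensities:
    def test_jittered_copy_pairs_to_itself(self, rng):
        pts = rng.random((200, 2)) * 1000
        jit = pts + rng.normal(scale=0.1, size=pts.shape)
        mA = build_tessellation(LocalizationSet(pts))
        mB = build_tessellation(LocalizationSet(jit))
        p = pair_densities(mA, mB)
        np.testing.assert_array_equal(p.partner_A, np.arange(200))
        # own and partner densities agree except where the 0.1 nm jitter
        # flips the neighborhood topology right at the field border
        ok = (p.x_A > 0) & (p.y_A > 0)
        close = np.abs(p.x_A[ok] - p.y_A[ok]) <= 0.2 * p.x_A[ok]
        assert close.mean() > 0.95

    def test_minimal_central_cell_captures_all(self, rng):
        # one central B cell containing the whole A cloud
        mB = build_tessellation(LocalizationSet(np.array(
            [[500.0, 500], [500, 5000], [5000, 500], [-4000, 500], [500, -4000]]
        )))
        pts = 450 + rng.random((50, 2)) * 100
        mA = build_tessellation(LocalizationSet(pts))
        p = pair_densities(mA, mB)
        np.testing.assert_array_equal(p.partner_A, 0)

    def test_partner_matches_brute_force(self, rng):
        a = rng.random((200, 2)) * 500
        b = rng.random((200, 2)) * 500
        mA = build_tessellation(LocalizationSet(a))
        mB = build_tessellation(LocalizationSet(b))
        p = pair_densities(mA, mB)
        np.testing.assert_array_equal(p.partner_A, cdist(a, b).argmin(axis=1))
        np.testing.assert_array_equal(p.partner_B, cdist(b, a).argmin(axis=1))

    def test_dim_mismatch(self, rng):
        mA = build_tessellation(LocalizationSet(rng.random((10, 2))))
        mB = build_tessellation(LocalizationSet(rng.random((10, 3))))
        with pytest.raises(ConfigError):
            pair_densities(mA, mB)


class TestClassify:
    def test_all_below_threshold_is_background(self):
        p = make_pairs([0.1, 0.5, 0.9], [0.2, 0.3, 0.4])
        res = classify(p, T=1.0, edge_correction=False)
        assert set(res.labels_A) == {"bg"}
        assert set(res.labels_B) == {"bg"}

    def test_threshold_is_inclusive(self):
        p = make_pairs([1.0, 0.999], [1.0, 1.0])
        res = classify(p, T=1.0, edge_correction=False)
        assert res.labels_A[0] == "AB"
        assert res.labels_A[1] == "bg"

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigError):
            classify(make_pairs([1.0], [1.0]), T=-0.5, edge_correction=False)

    def test_eight_point_manual_oracle(self):
        # hand-evaluated three-class + five-class rules, T = 1:
        # A: (own, partner): (2, 3)->AB (1, 0.5)->Ab (0.2, 2)->bg (0, 0)->bg
        # B: (partner, own): (2, 2)->BA (0.1, 1)->Ba (3, 0.9)->bg (1, 1)->BA
        p = PairDescriptorTable(
            x_A=np.array([2.0, 1.0, 0.2, 0.0]),
            y_A=np.array([3.0, 0.5, 2.0, 0.0]),
            partner_A=np.zeros(4, int),
            x_B=np.array([2.0, 0.1, 3.0, 1.0]),
            y_B=np.array([2.0, 1.0, 0.9, 1.0]),
            partner_B=np.zeros(4, int),
        )
        res = classify(p, T=1.0, edge_correction=False)
        assert list(res.labels_A) == ["AB", "Ab", "bg", "bg"]
        assert list(res.labels_B) == ["BA", "Ba", "bg", "BA"]
        counts = res.class_counts()
        assert sum(counts.values()) == 8

    def test_labels_partition_both_channels(self, small_sim):
        A, B = small_sim(seed=5)
        mA = build_tessellation(LocalizationSet(A.coords))
        mB = build_tessellation(LocalizationSet(B.coords))
        p = pair_densities(mA, mB)
        res = classify(p, edge_correction=True, model_A=mA, model_B=mB)
        assert sum(res.class_counts().values()) == A.n + B.n

    def test_channel_swap_maps_classes(self, small_sim):
        A, B = small_sim(seed=6)
        mA = build_tessellation(LocalizationSet(A.coords))
        mB = build_tessellation(LocalizationSet(B.coords))
        p = pair_densities(mA, mB)
        res = classify(p, edge_correction=True, model_A=mA, model_B=mB)
        swapped = classify(p.swapped(), edge_correction=True,
                           model_A=mB, model_B=mA)
        mapping = {"AB": "BA", "Ab": "Ba", "bg": "bg"}
        assert [mapping[c] for c in res.labels_A] == list(swapped.labels_B)


def strip_delaunay(n_rect=4, width=1.0, height=4.0):
    """Column of rectangles; Delaunay splits each into two equal triangles."""
    ys = np.arange(n_rect + 1) * height
    pts = np.array([(x, y) for y in ys for x in (0.0, width)])
    return Delaunay(pts)


class TestTriangleSet:
    def test_iqr_outlier_removed(self):
        # frozen oracle: seven simplices of measure 2 plus one oversized
        # one -> q25 = q75 = 2, IQR = 0, cutoff 2, only the big one removed
        pts = np.array([[0.0, 0], [1, 0], [0, 4], [1, 4], [0, 8], [1, 8],
                        [0, 12], [1, 12], [0, 16], [1, 16]])
        tri = SimpleNamespace(
            points=pts,
            simplices=np.array(
                [[0, 1, 2], [1, 2, 3], [2, 3, 4], [3, 4, 5], [4, 5, 6],
                 [5, 6, 7], [6, 7, 8]]
                + [[0, 1, 9]]  # area (1 * 16)/2 = 8 > cutoff
            ),
        )
        ts = build_triangle_set(tri, np.ones(10, bool))
        assert ts.q25 == 2 and ts.q75 == 2
        np.testing.assert_array_equal(ts.kept, [True] * 7 + [False])

    def test_all_equal_none_removed(self):
        tri = strip_delaunay()
        ts = build_triangle_set(tri, np.ones(tri.points.shape[0], bool))
        assert np.all(ts.kept)

    def test_empty_class_empty_set(self):
        tri = strip_delaunay()
        ts = build_triangle_set(tri, np.zeros(tri.points.shape[0], bool))
        assert ts.n_kept == 0
        assert not ts.contains(np.array([[0.5, 2.0]]))[0]

    def test_contains_matches_exhaustive_scan(self, rng):
        pts = rng.random((80, 2)) * 100
        tri = Delaunay(pts)
        mask = rng.random(80) < 0.6
        ts = build_triangle_set(tri, mask)
        queries = rng.random((500, 2)) * 120 - 10
        got = ts.contains(queries)
        # exhaustive barycentric scan over kept simplices
        kept = ts.simplex_indices[ts.kept]
        expected = np.zeros(500, bool)
        for s in kept:
            T = tri.transform[s]
            b = (queries - T[2]) @ T[:2].T
            bary = np.column_stack([b, 1 - b.sum(axis=1)])
            expected |= bary.min(axis=1) >= -1e-9
        np.testing.assert_array_equal(got, expected)


class TestEdgeCorrect:
    def test_empty_triangle_set_demotes_all(self, rng):
        pre_A = np.array(["AB", "AB", "Ab", "bg"])
        pre_B = np.array(["BA", "Ba", "bg", "bg"])
        tri = strip_delaunay()
        empty = build_triangle_set(tri, np.zeros(tri.points.shape[0], bool))
        full = build_triangle_set(tri, np.ones(tri.points.shape[0], bool))
        coords = np.full((4, 2), 0.5)
        labels_A, labels_B = edge_correct(pre_A, pre_B, full, empty,
                                          coords, coords)
        assert list(labels_A) == ["Ab", "Ab", "Ab", "bg"]
        assert list(labels_B) == ["BA", "Ba", "bg", "bg"]

    def test_point_on_kept_edge_is_retained(self):
        tri = strip_delaunay()
        ts = build_triangle_set(tri, np.ones(tri.points.shape[0], bool))
        # (0.5, 2.0) lies exactly on the shared diagonal edge y = 4x
        on_edge = np.array([[0.5, 2.0], [0.0, 4.0]])
        assert ts.contains(on_edge).all()

    def test_correction_only_demotes_and_conserves(self, small_sim):
        A, B = small_sim(d=50.0, seed=9)
        mA = build_tessellation(LocalizationSet(A.coords))
        mB = build_tessellation(LocalizationSet(B.coords))
        p = pair_densities(mA, mB)
        pre = classify(p, edge_correction=False)
        post = classify(p, edge_correction=True, model_A=mA, model_B=mB)
        ab_pre = pre.labels_A == "AB"
        ab_post = post.labels_A == "AB"
        assert np.all(ab_post <= ab_pre)  # corr(C^AB) subset of C^AB
        assert ab_post.sum() < ab_pre.sum()  # partial overlap loses some
        # AB + Ab total conserved (= C^A)
        assert (ab_pre | (pre.labels_A == "Ab")).sum() == (
            ab_post | (post.labels_A == "Ab")
        ).sum()

    def test_row_order_invariance(self, small_sim):
        A, B = small_sim(seed=11)
        perm = np.random.default_rng(1).permutation(A.n)
        mA1 = build_tessellation(LocalizationSet(A.coords))
        mA2 = build_tessellation(LocalizationSet(A.coords[perm]))
        mB = build_tessellation(LocalizationSet(B.coords))
        r1 = classify(pair_densities(mA1, mB), edge_correction=True,
                      model_A=mA1, model_B=mB)
        r2 = classify(pair_densities(mA2, mB), edge_correction=True,
                      model_A=mA2, model_B=mB)
        assert list(r1.labels_A[perm]) == list(r2.labels_A)
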