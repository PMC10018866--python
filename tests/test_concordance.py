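import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nomehic import bsreads, concordance
from nomehic.concordance import (
    ConcordanceError,
    binarize_and_phi,
    concordance_from_groups,
    fisher_z_compare,
    local_control_pairs,
    pair_fractions,
    pearson_r,
    run_long_range_concordance,
    shuffle_null,
    tetrachoric_r,
)


class TestPearson:
    def test_collinear_ascending(self):
        assert pearson_r([(0, 0.1), (0.5, 0.5), (1, 0.9)]) == pytest.approx(1.0)

    def test_collinear_descending(self):
        assert pearson_r([(0, 1), (0.5, 0.5), (1, 0)]) == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.random((20_000, 2))
        assert abs(pearson_r(pts)) < 0.02

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ConcordanceError):
            pearson_r([(0, 1), (1, 0)])
        with pytest.raises(ConcordanceError):
            pearson_r([(0.5, 0.1), (0.5, 0.5), (0.5, 0.9)])


class TestPhi:
    def test_known_table(self):
        # 40 concordant-high, 40 concordant-low, 10+10 discordant -> phi 0.6
        pts = (
            [(1.0, 1.0)] * 40 + [(1.0, 0.0)] * 10 + [(0.0, 1.0)] * 10 + [(0.0, 0.0)] * 40
        )
        phi, table = binarize_and_phi(pts)
        assert table.tolist() == [[40, 10], [10, 40]]
        assert phi == pytest.approx((40 * 40 - 10 * 10) / math.sqrt(50**4))

    def test_half_binarizes_to_one(self):
        _, table = binarize_and_phi([(0.5, 0.5), (0.0, 0.0), (1.0, 0.0)])
        assert table[0, 0] == 1  # the (0.5, 0.5) point lands in the 1/1 cell

    def test_phi_equals_pearson_on_binary(self):
        rng = np.random.default_rng(1)
        pts = rng.random((500, 2))
        phi, _ = binarize_and_phi(pts)
        binary = (pts >= 0.5).astype(float)
        assert phi == pytest.approx(pearson_r(binary), abs=1e-12)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ConcordanceError):
            binarize_and_phi([(0.9, 0.1), (0.8, 0.9), (0.7, 0.2)])


class TestTetrachoric:
    def test_independence_gives_zero(self):
        assert tetrachoric_r(np.array([[25, 25], [25, 25]])) == pytest.approx(
            0.0, abs=0.01
        )

    def test_cosine_fallback(self):
        est = tetrachoric_r(np.array([[40, 10], [10, 40]]), method="cosine")
        assert est == pytest.approx(math.cos(math.pi / 5))

    def test_ml_recovers_latent_correlation(self):
        rng = np.random.default_rng(5)
        rho = 0.5
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=50_000)
        x, y = xy[:, 0] > 0, xy[:, 1] > 0
        t = np.array(
            [[(x & y).sum(), (x & ~y).sum()], [(~x & y).sum(), (~x & ~y).sum()]]
        )
        assert tetrachoric_r(t) == pytest.approx(rho, abs=0.03)

    def test_zero_cell_continuity_correction(self):
        est = tetrachoric_r(np.array([[10, 0], [3, 12]]))
        assert -1 < est < 1

    def test_empty_margin_rejected(self):
        with pytest.raises(ConcordanceError):
            tetrachoric_r(np.array([[0, 0], [5, 5]]))


class TestShuffleNull:
    def test_two_point_group_exhaustive(self):
        groups = {"a": [(1.0, 0.0), (0.0, 1.0)]}
        reps = shuffle_null(groups, n_shuffles=50, seed=3)
        for rep in reps:
            as_set = {tuple(p) for p in rep}
            assert as_set in ({(1.0, 0.0), (0.0, 1.0)}, {(1.0, 1.0), (0.0, 0.0)})
            assert rep[:, 0].mean() == 0.5 and rep[:, 1].mean() == 0.5

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        groups = {g: [tuple(p) for p in rng.random((7, 2))] for g in "abc"}
        r1 = shuffle_null(groups, n_shuffles=10, seed=42)
        r2 = shuffle_null(groups, n_shuffles=10, seed=42)
        assert all(np.array_equal(a, b) for a, b in zip(r1, r2))

    def test_mean_preservation_exact_every_replicate(self):
        rng = np.random.default_rng(10)
        groups = {
            f"g{i}": [tuple(p) for p in rng.random((rng.integers(1, 15), 2))]
            for i in range(8)
        }
        reps = shuffle_null(groups, n_shuffles=25, seed=0)
        sizes = {g: len(v) for g, v in groups.items()}
        for rep in reps:
            offset = 0
            for g in sorted(groups):
                chunk = rep[offset : offset + sizes[g]]
                orig = np.asarray(groups[g])
                # per-anchor means are exact invariants (permutation only)
                assert np.isclose(chunk[:, 0].mean(), orig[:, 0].mean(), atol=0)
                assert np.isclose(chunk[:, 1].mean(), orig[:, 1].mean(), atol=0)
                offset += sizes[g]

    def test_destroys_planted_correlation(self):
        rng = np.random.default_rng(11)
        z = rng.standard_normal(2_000)
        pts = np.column_stack([z + 0.5 * rng.standard_normal(2_000),
                               z + 0.5 * rng.standard_normal(2_000)])
        groups = {"all": [tuple(p) for p in pts]}
        assert pearson_r(pts) > 0.7
        reps = shuffle_null(groups, n_shuffles=20, seed=1)
        rs = [pearson_r(rep) for rep in reps]
        assert abs(np.mean(rs)) < 0.05


class TestFisherZ:
    def test_formula_example(self):
        z, p = fisher_z_compare(0.5, 103, 0.0, 103)
        assert z == pytest.approx(3.8842, abs=1e-3)
        assert p == pytest.approx(1.027e-4, rel=1e-2)

    def test_equal_correlations(self):
        z, p = fisher_z_compare(0.4, 50, 0.4, 80)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        z1, p1 = fisher_z_compare(0.6, 40, 0.2, 60)
        z2, p2 = fisher_z_compare(0.2, 60, 0.6, 40)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_unit_correlation_rejected(self):
        with pytest.raises(ConcordanceError):
            fisher_z_compare(1.0, 10, 0.0, 10)

    def test_matches_independent_reimplementation(self):
        """Textbook formula recomputed with math-module primitives."""
        rng = np.random.default_rng(12)
        for _ in range(1_000):
            r1, r2 = rng.uniform(-0.99, 0.99, 2)
            n1, n2 = rng.integers(4, 10_000, 2)
            z, p = fisher_z_compare(r1, int(n1), r2, int(n2))
            zt1 = 0.5 * math.log((1 + r1) / (1 - r1))
            zt2 = 0.5 * math.log((1 + r2) / (1 - r2))
            z_ref = (zt1 - zt2) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
            p_ref = math.erfc(abs(z_ref) / math.sqrt(2))
            assert z == pytest.approx(z_ref, rel=1e-12)
            assert p == pytest.approx(p_ref, rel=1e-9)


class TestPairFractions:
    def test_min_sites_gate(self, small_pairs, small_dataset):
        pairs, _ = small_pairs
        grouped = bsreads.assign_pairs_to_anchor_pairs(pairs, small_dataset.anchors)
        pts = pair_fractions(grouped, min_sites=3)
        labels = frozenset({"GCH"})
        n_qualifying = sum(
            1
            for plist in grouped.values()
            for p in plist
            if p.end1.summarize(labels)[1] >= 3 and p.end2.summarize(labels)[1] >= 3
        )
        assert sum(len(v) for v in pts.values()) == n_qualifying

    def test_wcg_mode(self, small_pairs, small_dataset):
        pairs, _ = small_pairs
        grouped = bsreads.assign_pairs_to_anchor_pairs(pairs, small_dataset.anchors)
        pts = pair_fractions(grouped, context="WCG", min_sites=1)
        for plist in pts.values():
            for x, y in plist:
                assert 0 <= x <= 1 and 0 <= y <= 1


class TestLocalControl:
    def _mk(self, s1, s2):
        e1 = bsreads.AlignedEnd("chr1", s1, s1 + 100, 60, "OT")
        e2 = bsreads.AlignedEnd("chr1", s2, s2 + 100, 60, "OT")
        cls, sep = bsreads.classify_pair(e1, e2)
        return bsreads.LinkedReadPair(f"m{s1}_{s2}", e1, e2, cls, sep)

    @pytest.fixture()
    def anchors(self):
        return bsreads.AnchorPairSet.from_records(
            [("chr1", 0, 2_000, "chr1", 50_000, 52_000)]
        )

    def test_distance_gate(self, anchors):
        near = self._mk(100, 900)  # span 900 <= 1000
        far = self._mk(100, 1_500)  # span 1500 > 1000
        out = local_control_pairs([near, far], anchors)
        assert sum(len(v) for v in out.values()) == 1

    def test_sample_cap(self, anchors):
        pairs = [self._mk(i, i + 200) for i in range(0, 250 * 4, 4)]
        pairs = [p for p in pairs if p.end2.end <= 2_000]
        # pad to 250 inside the anchor
        pairs = (pairs * (250 // len(pairs) + 1))[:250]
        out = local_control_pairs(pairs, anchors, sample_cap=100, seed=0)
        assert sum(len(v) for v in out.values()) == 100


class TestEndToEnd:
    def test_planted_correlation_detected(self, small_pairs, small_dataset):
        lr, local = run_long_range_concordance(
            small_pairs[0], small_dataset.anchors, seed=2
        )
        assert lr.r_observed > lr.r_shuffled_mean + 0.1
        assert lr.p_fisher < 1e-4
        assert len(lr.r_shuffled_per_rep) == lr.n_shuffles == 100
        assert all(-1 <= r <= 1 for r in lr.r_shuffled_per_rep)
        # local control exists and shows the strong within-molecule signal
        assert local is not None and local.r_observed > 0.3

    def test_insufficient_data_raises(self):
        with pytest.raises(ConcordanceError):
            concordance_from_groups({})


@settings(deadline=None, max_examples=30)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_monotone_in_planted_correlation_is_seed_stable(seed):
    """Sanity: shuffling never raises |r| above the observed planted value."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(300)
    pts = np.column_stack(
        [z + rng.standard_normal(300), z + rng.standard_normal(300)]
    )
    groups = {"g": [tuple(p) for p in pts]}
    obs = pearson_r(pts)
    reps = shuffle_null(groups, n_shuffles=5, seed=0)
    assert np.mean([pearson_r(r) for r in reps]) < obs
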