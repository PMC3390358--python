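"""Tests of r2/D', distance records, capture curves, and LD blocks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synassoc as sa
from synassoc import lddist
from synassoc.disease import CausalSet
from synassoc.panel import HaplotypePanel, RecombinationMap


def _panel_from_haps(h, bp=None, cm=None):
    h = np.asarray(h, dtype=np.int8)
    bp = np.asarray(bp) if bp is not None else np.arange(1, h.shape[1] + 1) * 100
    cm = np.asarray(cm, float) if cm is not None else bp / 1e4
    return HaplotypePanel.from_matrix(h, bp, cm)


class TestR2:
    def test_variant_with_itself_is_one(self):
        p = _panel_from_haps([[0, 0], [1, 1], [0, 0], [1, 1]])
        assert lddist.r2(p, 0, 0) == pytest.approx(1.0)

    def test_perfect_coupling_counts(self):
        # haplotype counts AB=2, Ab=0, aB=0, ab=2 -> D = 0.25, r2 = 1
        p = _panel_from_haps([[1, 1], [1, 1], [0, 0], [0, 0]])
        assert lddist.r2(p, 0, 1) == pytest.approx(1.0)

    def test_exact_equilibrium_is_zero(self):
        # counts AB=1, Ab=1, aB=1, ab=1
        p = _panel_from_haps([[1, 1], [1, 0], [0, 1], [0, 0]])
        assert lddist.r2(p, 0, 1) == pytest.approx(0.0)

    def test_monomorphic_is_signaled(self):
        p = _panel_from_haps([[0, 1], [0, 0], [0, 1], [0, 0]])
        with pytest.raises(ValueError):
            lddist.r2(p, 0, 1)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equals_squared_correlation_and_invariances(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.integers(0, 2, (30, 2), dtype=np.int8)
        if len(set(h[:, 0])) < 2 or len(set(h[:, 1])) < 2:
            return
        p = _panel_from_haps(h)
        expected = np.corrcoef(h[:, 0], h[:, 1])[0, 1] ** 2
        assert lddist.r2(p, 0, 1) == pytest.approx(expected, abs=1e-12)
        # symmetry and allele-relabel invariance
        assert lddist.r2(p, 1, 0) == pytest.approx(lddist.r2(p, 0, 1), abs=1e-12)
        p2 = _panel_from_haps(np.stack([1 - h[:, 0], h[:, 1]], axis=1))
        assert lddist.r2(p2, 0, 1) == pytest.approx(expected, abs=1e-12)

    def test_r2_table_matches_pairwise(self, toy_panel):
        panel, _ = toy_panel
        poly = np.flatnonzero(panel.variants["maf"].to_numpy() > 0)[:8]
        table = lddist.r2_table(panel, poly, poly)
        for i, a in enumerate(poly):
            for j, b in enumerate(poly):
                assert table[i, j] == pytest.approx(lddist.r2(panel, a, b), abs=1e-12)


class TestDistanceRecords:
    def _fixture(self):
        # marker column 0; causal columns 1,2,3 engineered with r2 ~ (0.2, 0.9, 0.5)
        rng = np.random.default_rng(42)
        n = 400
        m = rng.integers(0, 2, n)

        def correlated(x, swap_frac):
            y = x.copy()
            flip = rng.choice(n, int(swap_frac * n), replace=False)
            y[flip] = 1 - y[flip]
            return y

        h = np.stack([m, correlated(m, 0.45), correlated(m, 0.02), correlated(m, 0.2)], axis=1)
        cm = np.array([0.50, 0.60, 0.58, 0.51])
        bp = np.array([100, 200, 300, 400])
        order = np.argsort(bp)
        panel = _panel_from_haps(h[:, order], bp[order], cm[order])
        return panel

    def test_distance_to_highest_r2_causal(self):
        panel = self._fixture()
        causal = CausalSet(np.array([1, 2, 3]), np.ones(3, np.int8),
                           panel.variants["maf"].to_numpy()[[1, 2, 3]])
        scan = pd.DataFrame(
            {"marker": [0], "cm": [0.50], "bp": [100], "significant": [True]}
        )
        rec = lddist.distance_records(scan, causal, panel, RecombinationMap([1, 500], [0, 0.005]))
        assert rec["causal"].iloc[0] == 2  # the r2~0.9 column
        assert rec["dist_highest"].iloc[0] == pytest.approx(0.08)
        assert rec["dist_closest"].iloc[0] == pytest.approx(0.01)
        assert rec["dist_closest"].iloc[0] <= rec["dist_highest"].iloc[0]

    def test_perfect_ld_same_position_distance_zero(self):
        m = np.random.default_rng(1).integers(0, 2, 100)
        h = np.stack([m, m], axis=1)
        panel = _panel_from_haps(h, bp=[100, 200], cm=[0.3, 0.3])
        causal = CausalSet(np.array([1]), np.ones(1, np.int8), np.array([m.mean()]))
        scan = pd.DataFrame({"marker": [0], "cm": [0.3], "bp": [100], "significant": [True]})
        rec = lddist.distance_records(scan, causal, panel, RecombinationMap([1, 500], [0, 0.005]))
        assert rec["dist_highest"].iloc[0] == 0.0

    def test_r2_tie_broken_by_proximity(self):
        m = np.random.default_rng(2).integers(0, 2, 100)
        h = np.stack([m, m, m], axis=1)  # both causal in perfect LD
        panel = _panel_from_haps(h, bp=[100, 200, 300], cm=[0.30, 0.40, 0.32])
        causal = CausalSet(np.array([1, 2]), np.ones(2, np.int8), np.full(2, m.mean()))
        scan = pd.DataFrame({"marker": [0], "cm": [0.30], "bp": [100], "significant": [True]})
        rec = lddist.distance_records(scan, causal, panel, RecombinationMap([1, 500], [0, 0.005]))
        assert rec["causal"].iloc[0] == 2  # nearer in cM

    def test_closest_never_exceeds_highest_r2_distance(self, mini_result):
        a = mini_result.associations
        a = a[a["dist_highest"].notna()]
        assert (a["dist_closest"] <= a["dist_highest"] + 1e-12).all()


class TestCaptureCurve:
    def test_exhaustive_window_reaches_one(self):
        d = [np.array([0.5, 3.0]), np.array([0.01])]
        w = np.array([5.0])
        assert lddist.capture_curve(d, w)[0] == 1.0

    def test_curve_non_decreasing(self):
        rng = np.random.default_rng(0)
        d = [rng.exponential(0.2, rng.integers(1, 5)) for _ in range(30)]
        curve = lddist.capture_curve(d, lddist.default_windows())
        assert (np.diff(curve) >= 0).all()

    def test_hand_counted_fractions(self):
        d = [np.array([0.05, 0.5]), np.array([0.2]), np.array([0.8, 0.9])]
        w = np.array([0.1, 0.3, 1.0])
        assert lddist.capture_curve(d, w).tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            lddist.capture_curve([], np.array([1.0]))


class TestBlocks:
    def test_tight_pair_forms_block(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, 400)
        h = np.stack([a, a], axis=1)  # D' = 1 with tight CI at n=400
        panel = _panel_from_haps(h, bp=[1_000, 2_000], cm=[0.01, 0.012])
        rmap = RecombinationMap([1, 10_000], [0.0, 0.1])
        blocks = lddist.ld_blocks(panel, np.array([0, 1]), rmap)
        assert len(blocks) == 1
        assert blocks[0].members.tolist() == [0, 1]
        # flanked span: 0.002 + 2 * 0.0005
        assert blocks[0].end_cm - blocks[0].start_cm == pytest.approx(0.003)

    def test_equilibrium_markers_form_no_blocks(self):
        rng = np.random.default_rng(8)
        h = rng.integers(0, 2, (400, 6), dtype=np.int8)  # independent columns
        panel = _panel_from_haps(h, bp=np.arange(1, 7) * 1000)
        rmap = RecombinationMap([1, 10_000], [0.0, 0.1])
        assert lddist.ld_blocks(panel, np.arange(6), rmap) == []

    def test_flanked_span_at_least_one_millicentimorgan(self, growth_region):
        for b in growth_region.blocks:
            assert b.end_cm - b.start_cm >= 0.001 - 1e-12

    def test_mean_block_span_order_of_magnitude(self, growth_region):
        # CEU-like synthetic data: mean flanked span of order 0.005-0.01 cM
        spans = np.array([b.end_cm - b.start_cm for b in growth_region.blocks])
        assert spans.size > 10
        assert 0.002 < spans.mean() < 0.02

    def test_dprime_ci_certain_when_coupling_is_complete(self):
        dp, lo, hi = lddist.dprime_ci([200.0], [0.0], [0.0], [200.0])
        assert dp[0] == pytest.approx(1.0)
        assert lo[0] > 0.9 and hi[0] == 1.0

    def test_block_capture_hand_count(self):
        # 5 associations, 2 blocks, 2 causal: captured = 2 of 5
        rng = np.random.default_rng(3)
        h = rng.integers(0, 2, (40, 8), dtype=np.int8)
        panel = _panel_from_haps(h, bp=np.arange(1, 9) * 100, cm=np.arange(8) * 0.01)
        blocks = [
            lddist.LDBlock(100, 200, -0.0005, 0.0105, members=np.array([0, 1])),
            lddist.LDBlock(500, 600, 0.0395, 0.0505, members=np.array([4, 5])),
        ]
        causal = CausalSet(np.array([1, 6]), np.ones(2, np.int8), np.array([0.2, 0.2]))
        scan = pd.DataFrame(
            {
                "marker": [0, 1, 3, 5, 7],  # 3 and 7 in no block; 5's block has no causal
                "significant": [True] * 5,
            }
        )
        frac = lddist.block_capture(scan, blocks, causal, panel)
        assert frac == pytest.approx(2 / 5)

    def test_association_outside_blocks_not_captured(self):
        panel = _panel_from_haps(np.random.default_rng(0).integers(0, 2, (10, 2)))
        causal = CausalSet(np.array([1]), np.ones(1, np.int8), np.array([0.3]))
        scan = pd.DataFrame({"marker": [0], "significant": [True]})
        assert lddist.block_capture(scan, [], causal, panel) == 0.0
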