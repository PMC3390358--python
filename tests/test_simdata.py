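"""Tests of the coalescent panel generator, the Li–Stephens mosaic
resampler, and array-marker ascertainment."""

import numpy as np
import pytest
from scipy import stats

import synassoc as sa
from synassoc import simdata
from synassoc.lddist import r2_table
from synassoc.panel import RecombinationMap
from synassoc.simdata import MosaicParams


class TestSimulatePanel:
    def test_zero_mutation_rate_gives_no_variants(self):
        preset = simdata.DemographyPreset("mute", mutation_rate=0.0)
        panel, _ = sa.simulate_panel(preset, 10_000, 0.0, 10, seed=1)
        assert panel.n_var == 0

    def test_deterministic_given_seed(self):
        a, _ = sa.simulate_panel(sa.CONSTANT, 20_000, 0.02, 20, seed=5)
        b, _ = sa.simulate_panel(sa.CONSTANT, 20_000, 0.02, 20, seed=5)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.variants.equals(b.variants)

    def test_segregating_sites_match_watterson_expectation(self):
        # closed-form coalescent oracle: E[S] = theta*a1, Var[S] = theta*a1 + theta^2*b1
        n_hap, L = 100, 100_000
        preset = sa.CONSTANT
        theta = 4 * preset.ancestral_size * preset.mutation_rate * L
        i = np.arange(1, n_hap)
        a1, b1 = (1 / i).sum(), (1 / i**2).sum()
        mean = theta * a1
        sd = np.sqrt(theta * a1 + theta**2 * b1)
        panel, _ = sa.simulate_panel(preset, L, 0.0, n_hap, seed=42)
        assert abs(panel.n_var - mean) < 3 * sd

    @pytest.mark.parametrize("seed", range(5))
    def test_growth_enriches_rare_variants(self, seed):
        kw = dict(locus_length=60_000, flank_cm=0.0, n_hap=100)
        grow, _ = sa.simulate_panel(sa.BOTTLENECK_GROWTH, seed=seed, **kw)
        const, _ = sa.simulate_panel(sa.CONSTANT, seed=seed, **kw)
        frac = lambda p: (p.variants["maf"] < 0.04).mean()
        assert frac(grow) > frac(const)

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            sa.simulate_panel(sa.CONSTANT, 0, 0.0, 10, seed=1)
        with pytest.raises(ValueError):
            sa.simulate_panel(sa.CONSTANT, 1000, 0.0, 2, seed=1)

    def test_locus_bounds_inside_panel_span(self, toy_panel):
        panel, _ = toy_panel
        lo, hi = panel.meta["locus_bounds"]
        assert hi - lo + 1 == 20_000
        bp = panel.variants["bp"]
        assert bp.min() >= 1 and ((bp >= lo) & (bp <= hi)).any()


class TestMosaic:
    def test_identical_panel_gives_identical_outputs(self):
        h = np.tile(np.array([0, 1, 1, 0, 1], dtype=np.int8), (6, 1))
        panel = sa.HaplotypePanel.from_matrix(h, np.arange(1, 6) * 100, np.linspace(0, 0.1, 5))
        rmap = RecombinationMap([1, 500], [0.0, 0.1])
        out = sa.resample_mosaic(panel, 10, rmap, MosaicParams(copy_error=0.0), seed=3)
        assert np.array_equal(out.haplotypes, np.tile(h[0], (10, 1)))

    def test_zero_switch_rate_copies_whole_haplotypes(self, toy_panel):
        panel, rmap = toy_panel
        params = MosaicParams(switch_intensity=1e-12, copy_error=0.0)
        out = sa.resample_mosaic(panel, 30, rmap, params, seed=4)
        rows = {r.tobytes() for r in panel.haplotypes}
        assert all(r.tobytes() in rows for r in out.haplotypes)

    def test_frequencies_within_binomial_envelope(self, toy_panel):
        # exact binomial(n_out, panel frequency) 99.9% interval per column
        panel, rmap = toy_panel
        n_out = 400
        out = sa.resample_mosaic(panel, n_out, rmap, MosaicParams(copy_error=0.0), seed=8)
        f = panel.alt_freq()
        counts = out.haplotypes.sum(axis=0)
        lo = stats.binom.ppf(0.0005, n_out, f)
        hi = stats.binom.ppf(0.9995, n_out, f)
        ok = (counts >= lo) & (counts <= hi)
        # allow a couple of boundary misses across ~200 correlated columns
        assert ok.mean() > 0.98

    def test_infinite_switch_rate_destroys_ld(self):
        panel, rmap = sa.simulate_panel(sa.CONSTANT, 50_000, 0.6, 40, seed=9)
        params = MosaicParams(switch_intensity=1e6, copy_error=0.0)
        out = sa.resample_mosaic(panel, 400, rmap, params, seed=10)
        common = np.flatnonzero(out.variants["maf"].to_numpy() >= 0.1)
        cm = out.variants["cm"].to_numpy()[common]
        r = r2_table(out, common, common)
        far = np.abs(cm[:, None] - cm[None, :]) >= 1.0
        assert far.any()
        assert np.nanmean(r[far]) < 0.02

    def test_ld_decay_preserved_for_common_variants(self):
        # binned mean pairwise r2 agreement between panel and expansion
        panel, rmap = sa.simulate_panel(sa.BOTTLENECK_GROWTH, 60_000, 0.15, 120, seed=12)
        out = sa.resample_mosaic(panel, 2_000, rmap, MosaicParams(copy_error=0.0), seed=13)
        common = np.flatnonzero(panel.variants["maf"].to_numpy() >= 0.05)
        cm = panel.variants["cm"].to_numpy()[common]
        rp = r2_table(panel, common, common)
        ro = r2_table(out, common, common)
        iu = np.triu_indices(len(common), k=1)
        d = np.abs(cm[iu[0]] - cm[iu[1]])
        bins = (d / 0.01).astype(int)
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() < 20:
                continue
            assert abs(np.nanmean(rp[iu][sel]) - np.nanmean(ro[iu][sel])) < 0.05

    def test_rejects_empty_panel(self):
        empty = sa.HaplotypePanel.from_matrix(np.empty((4, 0), dtype=np.int8), [], [])
        rmap = RecombinationMap([1, 2], [0.0, 0.0])
        with pytest.raises(ValueError):
            sa.resample_mosaic(empty, 10, rmap, seed=0)

    def test_copy_error_flips_alleles(self):
        h = np.zeros((4, 500), dtype=np.int8)
        panel = sa.HaplotypePanel.from_matrix(h, np.arange(1, 501), np.zeros(500))
        rmap = RecombinationMap([1, 500], [0.0, 0.0])
        out = sa.resample_mosaic(panel, 100, rmap, MosaicParams(copy_error=0.01), seed=5)
        rate = out.haplotypes.mean()
        assert 0.005 < rate < 0.02


class TestAscertainArray:
    def test_floor_half_yields_empty_set(self):
        # no column reaches a folded frequency of exactly 0.5
        rng = np.random.default_rng(1)
        h = np.zeros((20, 3), dtype=np.int8)
        for j, c in enumerate((2, 5, 9)):
            h[rng.choice(20, c, replace=False), j] = 1
        panel = sa.HaplotypePanel.from_matrix(h, [10, 20, 30], np.zeros(3))
        with pytest.warns(UserWarning):
            idx = sa.ascertain_array(panel, maf_floor=0.5, seed=1)
        assert idx.size == 0

    def test_no_thinning_when_spacing_below_min_gap(self, toy_panel):
        panel, _ = toy_panel
        idx = sa.ascertain_array(panel, maf_floor=0.0, target_spacing=1, seed=1, discovery_haps=0)
        assert np.array_equal(idx, np.arange(panel.n_var))

    def test_all_markers_pass_floor(self, toy_panel):
        panel, _ = toy_panel
        idx = sa.ascertain_array(panel, maf_floor=0.05, seed=7)
        assert (panel.variants["maf"].to_numpy()[idx] >= 0.05).all()

    def test_deterministic_and_spacing(self, toy_panel):
        panel, _ = toy_panel
        a = sa.ascertain_array(panel, 0.05, 2_000, seed=7)
        b = sa.ascertain_array(panel, 0.05, 2_000, seed=7)
        assert np.array_equal(a, b)
        bp = panel.variants["bp"].to_numpy()[a]
        spacing = np.diff(bp).mean()
        assert 1_000 < spacing < 6_000  # ~target up to empty-bin inflation

    def test_common_bias_relative_to_panel_sfs(self):
        panel, _ = sa.simulate_panel(sa.BOTTLENECK_GROWTH, 60_000, 0.05, 220, seed=21)
        idx = sa.ascertain_array(panel, 0.05, 2_000, seed=3)
        maf = panel.variants["maf"].to_numpy()
        eligible = maf >= 0.05
        frac_low_array = (maf[idx] < 0.1).mean()
        frac_low_eligible = (maf[eligible] < 0.1).mean()
        assert frac_low_array < frac_low_eligible
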