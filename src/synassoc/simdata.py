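"""Synthetic resequencing panels: coalescent simulation, mosaic expansion,
and array-marker ascertainment.

The study design emulated here is a fully resequenced 100-kb "disease
locus" with dense rare variation, embedded in flanking sequence so that
genotyping-array markers are available out to a fixed genetic distance on
each side. Two demographic presets are provided:

``constant``
    A constant effective population size of 10,000 — variation typical of
    a population without a strong recent expansion.
``bottleneck_growth``
    A bottleneck to Ne = 1,000 at 2,000 generations ago followed by
    exponential growth to Ne = 1,000,000 at present — the explosive recent
    growth that inflates the proportion of rare variants in European-
    ancestry samples.

Small reference panels are expanded to GWAS-scale sample sizes with a
Li–Stephens-style mosaic resampler: each new haplotype copies segments of
existing panel haplotypes, switching templates at a rate proportional to
genetic distance, so that allele frequencies and LD decay of the source
panel are approximately preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import msprime
import numpy as np

from .panel import HaplotypePanel, RecombinationMap

__all__ = [
    "DemographyPreset",
    "MosaicParams",
    "CONSTANT",
    "BOTTLENECK_GROWTH",
    "get_preset",
    "simulate_panel",
    "simulate_cohort",
    "resample_mosaic",
    "ascertain_array",
]


@dataclass(frozen=True)
class DemographyPreset:
    """Single-population demographic history plus per-bp rates.

    Sizes are diploid effective sizes; times are generations before
    present. With ``bottleneck_size`` set, the population is of size
    ``ancestral_size`` before ``bottleneck_time``, drops to
    ``bottleneck_size`` at that time, and grows exponentially to
    ``present_size`` at sampling.
    """

    label: str
    ancestral_size: float = 10_000.0
    bottleneck_size: Optional[float] = None
    bottleneck_time: Optional[float] = None
    present_size: Optional[float] = None
    mutation_rate: float = 1.25e-8  # per bp per generation
    mean_recomb_cm_per_mb: float = 1.2

    def __post_init__(self):
        for v in (self.ancestral_size, self.bottleneck_size, self.bottleneck_time, self.present_size):
            if v is not None and v <= 0:
                raise ValueError("demography sizes and times must be positive")

    def add_to(self, demography: msprime.Demography, name: str) -> None:
        """Append this history as one population of an msprime demography."""
        if self.bottleneck_size is None:
            demography.add_population(name=name, initial_size=self.ancestral_size)
        else:
            rate = np.log(self.present_size / self.bottleneck_size) / self.bottleneck_time
            demography.add_population(name=name, initial_size=self.present_size, growth_rate=rate)
            demography.add_population_parameters_change(
                time=self.bottleneck_time, population=name,
                initial_size=self.ancestral_size, growth_rate=0.0,
            )


CONSTANT = DemographyPreset("constant")
BOTTLENECK_GROWTH = DemographyPreset(
    "bottleneck_growth", bottleneck_size=1_000.0, bottleneck_time=2_000.0, present_size=1_000_000.0
)

_PRESETS = {p.label: p for p in (CONSTANT, BOTTLENECK_GROWTH)}


def get_preset(label: str) -> DemographyPreset:
    try:
        return _PRESETS[label]
    except KeyError:
        raise ValueError(f"unknown demography preset {label!r}; choose from {sorted(_PRESETS)}")


@dataclass(frozen=True)
class MosaicParams:
    """Parameters of the Li–Stephens mosaic resampler.

    ``switch_intensity`` is the expected number of template switches per
    cM; ``None`` selects the Li–Stephens default 4·Ne·c/k, with k the
    source-panel haplotype count and Ne taken from the demography used to
    simulate the panel. ``copy_error`` is the per-site allele flip
    probability (the copying "mutation" rate), near zero by default.
    """

    switch_intensity: Optional[float] = None
    copy_error: float = 1e-4

    def __post_init__(self):
        if self.switch_intensity is not None and self.switch_intensity <= 0:
            raise ValueError("switch intensity must be > 0")
        if not 0.0 <= self.copy_error <= 0.01:
            raise ValueError("copy error must be in [0, 0.01]")

    def resolved_intensity(self, n_panel_hap: int, ne: float = 10_000.0) -> float:
        if self.switch_intensity is not None:
            return self.switch_intensity
        # 4*Ne*c/k with c = 0.01 Morgan per cM
        return 4.0 * ne * 0.01 / n_panel_hap


# ---------------------------------------------------------------------------
# genetic-map synthesis


def _draw_rates(rng: np.random.Generator, n: int, mean_rate: float) -> np.ndarray:
    """Segment recombination rates (cM/Mb), lognormal around the mean.

    sigma = 0.6 gives roughly the spread of broad-scale human map rates.
    """
    sigma = 0.6
    return mean_rate * np.exp(rng.normal(-sigma**2 / 2.0, sigma, n))


def synth_genetic_map(
    locus_length: int,
    flank_cm: float,
    rng: np.random.Generator,
    mean_rate: float = 1.2,
    segment_bp: int = 100_000,
):
    """Build a piecewise genetic map covering locus + flanks.

    Returns ``(RecombinationMap, (locus_start_bp, locus_end_bp), total_bp)``.
    The flanks each span exactly ``flank_cm`` centimorgans; their physical
    extent follows from the drawn segment rates.
    """
    if locus_length <= 0:
        raise ValueError("locus_length must be positive")
    if flank_cm < 0:
        raise ValueError("flank must be non-negative")

    def flank_segments() -> tuple[list[int], list[float]]:
        lengths, cms = [], []
        acc = 0.0
        while acc < flank_cm - 1e-12:
            rate = _draw_rates(rng, 1, mean_rate)[0]
            seg_cm = rate * segment_bp / 1e6
            if acc + seg_cm > flank_cm:
                seg_len = int(round((flank_cm - acc) / rate * 1e6))
                seg_len = max(seg_len, 1)
                seg_cm = flank_cm - acc
            else:
                seg_len = segment_bp
            lengths.append(seg_len)
            cms.append(seg_cm)
            acc += seg_cm
        return lengths, cms

    left_len, left_cm = flank_segments()
    n_locus_seg = max(1, locus_length // segment_bp)
    locus_rates = _draw_rates(rng, n_locus_seg, mean_rate)
    locus_len = [locus_length // n_locus_seg] * n_locus_seg
    locus_len[-1] += locus_length - sum(locus_len)
    locus_cm = [r * L / 1e6 for r, L in zip(locus_rates, locus_len)]
    right_len, right_cm = flank_segments()

    seg_len = left_len + locus_len + right_len
    seg_cm = left_cm + locus_cm + right_cm
    bp = np.concatenate(([1], 1 + np.cumsum(seg_len)))
    cm = np.concatenate(([0.0], np.cumsum(seg_cm)))
    rmap = RecombinationMap(bp, cm)
    locus_start = 1 + int(sum(left_len))
    locus_end = locus_start + locus_length - 1
    return rmap, (locus_start, locus_end), int(bp[-1])


def _msprime_rate_map(rmap: RecombinationMap, total_bp: int) -> msprime.RateMap:
    # physical anchors are 1-based inclusive; msprime wants 0-based edges
    pos = np.concatenate(([0.0], rmap.positions_bp[1:] - 1, [float(total_bp)]))
    pos = np.unique(pos)
    rates_morgan_per_bp = np.diff(rmap.genetic_position(pos + 1)) / 100.0 / np.diff(pos)
    return msprime.RateMap(position=pos, rate=rates_morgan_per_bp)


# ---------------------------------------------------------------------------
# coalescent simulation


def _panel_from_ts(ts, rmap, cols_keep_pop, label, meta):
    if ts.num_sites == 0:
        empty = np.empty((cols_keep_pop.shape[0], 0), dtype=np.int8)
        return HaplotypePanel.from_matrix(empty, [], [], population_label=label, meta=meta)
    G = ts.genotype_matrix().T  # (n_hap_total, n_sites)
    bp = np.floor(ts.sites_position).astype(np.int64) + 1
    h = np.ascontiguousarray(G[cols_keep_pop], dtype=np.int8)
    # keep biallelic 0/1 sites segregating in this sample
    ok = (h.max(axis=0) == 1) & (h.min(axis=0) == 0)
    # discrete genome can (rarely) stack two sites at one bp; keep the first
    dup = np.zeros(len(bp), dtype=bool)
    dup[1:] = np.diff(bp) == 0
    ok &= ~dup
    h = h[:, ok]
    bp = bp[ok]
    return HaplotypePanel.from_matrix(
        h, bp, rmap.genetic_position(bp), population_label=label, meta=meta
    )


def simulate_cohort(
    demography: DemographyPreset,
    locus_length: int,
    flank_cm: float,
    n_hap: int,
    seed: int,
    n_outgroup_hap: int = 0,
    outgroup_preset: Optional[DemographyPreset] = None,
    split_time: float = 1_000.0,
):
    """Simulate a focal panel, its map, and optionally an outgroup panel.

    The outgroup is a sister population that split ``split_time``
    generations ago; the ancestral lineage follows the focal preset's
    trajectory, so the split time acts as the age threshold of the
    mutation-age classification (a focal variant older than the split can
    be carried by the outgroup, a younger one cannot, barring the
    outgroup's own drift). By default the sister follows the focal preset
    since the split. The outgroup panel shares the focal panel's variant
    columns (sites segregating in the focal sample), which is what the
    age-of-mutation classification consumes.

    Returns ``(panel, rmap)`` or ``(panel, rmap, outgroup_panel)``.
    """
    if n_hap < 4:
        raise ValueError("n_hap must be >= 4")
    if n_hap % 2 or n_outgroup_hap % 2:
        raise ValueError("haplotype counts must be even (diploid samples)")

    ss = np.random.SeedSequence(seed)
    map_rng = np.random.default_rng(ss.spawn(1)[0])
    anc_seed, mut_seed = (int(s) for s in ss.generate_state(2, dtype=np.uint32) % (2**31 - 1) + 1)

    rmap, locus_bounds, total_bp = synth_genetic_map(
        locus_length, flank_cm, map_rng, demography.mean_recomb_cm_per_mb
    )
    meta = {"locus_bounds": locus_bounds, "demography": demography.label, "seed": seed}

    dem = msprime.Demography()
    demography.add_to(dem, "focal")
    samples = {"focal": n_hap // 2}
    if n_outgroup_hap:
        og = outgroup_preset or demography
        og.add_to(dem, "outgroup")
        # the ancestral lineage follows the focal trajectory (sizes in
        # msprime are referenced to time 0, so this is a direct mirror)
        demography.add_to(dem, "anc")
        dem.add_population_split(time=split_time, derived=["focal", "outgroup"], ancestral="anc")
        samples["outgroup"] = n_outgroup_hap // 2
        dem.sort_events()

    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=total_bp,
        recombination_rate=_msprime_rate_map(rmap, total_bp),
        random_seed=anc_seed,
        ploidy=2,
    )
    if demography.mutation_rate > 0:
        ts = msprime.sim_mutations(
            ts, rate=demography.mutation_rate, random_seed=mut_seed,
            model=msprime.BinaryMutationModel(),
        )

    focal_cols = np.arange(n_hap)
    panel = _panel_from_ts(ts, rmap, focal_cols, demography.label, meta)
    if not n_outgroup_hap:
        return panel, rmap

    # outgroup matrix restricted to the focal panel's variant columns
    if ts.num_sites == 0:
        out_h = np.empty((n_outgroup_hap, 0), dtype=np.int8)
        out_panel = HaplotypePanel.from_matrix(out_h, [], [], population_label="outgroup")
        return panel, rmap, out_panel
    G = ts.genotype_matrix().T
    bp_all = np.floor(ts.sites_position).astype(np.int64) + 1
    keep = np.isin(bp_all, panel.variants["bp"].to_numpy())
    first = np.zeros(len(bp_all), dtype=bool)
    seen = set()
    for i, b in enumerate(bp_all):
        if keep[i] and b not in seen:
            first[i] = True
            seen.add(b)
    out_h = np.ascontiguousarray(G[n_hap : n_hap + n_outgroup_hap][:, first], dtype=np.int8)
    out_panel = HaplotypePanel.from_matrix(
        out_h, bp_all[first], rmap.genetic_position(bp_all[first]), population_label="outgroup"
    )
    return panel, rmap, out_panel


def simulate_panel(
    demography: DemographyPreset,
    locus_length: int,
    flank_cm: float,
    n_hap: int,
    seed: int,
):
    """Simulate one resequenced panel (disease locus + flanks) and its map.

    The panel's ``meta['locus_bounds']`` records the physical bounds of the
    central disease locus. Deterministic given ``seed``.
    """
    return simulate_cohort(demography, locus_length, flank_cm, n_hap, seed)


# ---------------------------------------------------------------------------
# mosaic expansion


def resample_mosaic(
    panel: HaplotypePanel,
    n_out: int,
    rmap: RecombinationMap,
    params: MosaicParams = MosaicParams(),
    seed: int = 0,
    ne: float = 10_000.0,
    chunk: int = 2_048,
) -> HaplotypePanel:
    """Expand a panel to ``n_out`` haplotypes with a Li–Stephens mosaic.

    Each output haplotype starts from a uniformly chosen template and, in
    the gap between adjacent variants separated by d cM, switches to a new
    uniformly chosen template with probability 1 − exp(−λ·d). Each copied
    allele is flipped with probability ε (``params.copy_error``).
    """
    if panel.n_var == 0 or panel.n_hap == 0:
        raise ValueError("cannot resample an empty panel")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")

    lam = params.resolved_intensity(panel.n_hap, ne)
    cm = panel.variants["cm"].to_numpy()
    p_switch = 1.0 - np.exp(-lam * np.diff(cm))
    rng = np.random.default_rng(seed)
    k, m = panel.n_hap, panel.n_var
    out = np.empty((n_out, m), dtype=np.int8)

    for lo in range(0, n_out, chunk):
        hi = min(lo + chunk, n_out)
        c = hi - lo
        switches = rng.random((c, m - 1)) < p_switch if m > 1 else np.zeros((c, 0), bool)
        slot = np.zeros((c, m), dtype=np.int64)
        np.cumsum(switches, axis=1, out=slot[:, 1:])
        n_slots = int(slot[:, -1].max()) + 1 if m else 1
        templates = rng.integers(0, k, size=(c, n_slots))
        tmpl_per_site = templates[np.arange(c)[:, None], slot]
        block = panel.haplotypes[tmpl_per_site, np.arange(m)[None, :]]
        if params.copy_error > 0:
            flips = rng.random((c, m)) < params.copy_error
            block = block ^ flips
        out[lo:hi] = block

    return HaplotypePanel.from_matrix(
        out,
        panel.variants["bp"].to_numpy(),
        cm,
        ids=panel.variants["id"],
        population_label=panel.population_label,
        meta=dict(panel.meta),
    )


# ---------------------------------------------------------------------------
# array-marker ascertainment


def ascertain_array(
    panel: HaplotypePanel,
    maf_floor: float = 0.05,
    target_spacing: int = 2_000,
    seed: int = 0,
    discovery_haps: int = 24,
) -> np.ndarray:
    """Select common-biased "genotyping array" marker columns.

    Commercial genome-wide arrays carry SNPs that were (i) discovered in
    small resequencing panels and (ii) preferentially chosen as
    informative tags, which flattens the array MAF spectrum relative to
    the underlying site-frequency spectrum. This is emulated with the
    classic double-hit ascertainment model: a variant is eligible if its
    panel MAF is >= ``maf_floor`` and its minor allele is seen at least
    twice in a random "discovery" subsample of ``discovery_haps``
    haplotypes; one eligible variant per ``target_spacing``-bp bin is then
    drawn with probability proportional to its discovery-sample
    heterozygosity 2f(1-f). Set ``discovery_haps=0`` to disable the
    discovery step (pure frequency floor).

    Returns sorted column indices; empty (with a warning) if nothing
    passes the floor.
    """
    if not 0.0 <= maf_floor <= 0.5:
        raise ValueError("maf_floor must be in [0, 0.5]")
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    rng = np.random.default_rng(seed)

    maf = panel.variants["maf"].to_numpy()
    pass_floor = maf >= maf_floor
    if discovery_haps and panel.n_hap > discovery_haps:
        disc_rows = rng.choice(panel.n_hap, size=discovery_haps, replace=False)
        ones = panel.haplotypes[disc_rows].sum(axis=0)
        minor = np.minimum(ones, discovery_haps - ones)
        f_disc = ones / discovery_haps
        discovered = minor >= 2
    else:
        f_disc = panel.alt_freq()
        discovered = np.ones(panel.n_var, dtype=bool)
    eligible = np.flatnonzero(pass_floor & discovered)
    if eligible.size == 0:
        warnings.warn("no variant passes the MAF floor; empty marker set", stacklevel=2)
        return np.empty(0, dtype=np.int64)

    het = 2.0 * f_disc[eligible] * (1.0 - f_disc[eligible])
    bp = panel.variants["bp"].to_numpy()[eligible]
    bins = (bp - bp[0]) // target_spacing
    chosen = []
    start = 0
    for b in np.unique(bins):
        stop = start + int(np.sum(bins == b))
        grp = eligible[start:stop]
        w = het[start:stop]
        w = w / w.sum() if w.sum() > 0 else None
        chosen.append(rng.choice(grp, p=w))
        start = stop
    return np.sort(np.asarray(chosen, dtype=np.int64))
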