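"""Linkage disequilibrium, genetic-map distances, capture curves, and
Gabriel-style LD blocks.

Because panels are phased by construction, r-squared and D' are computed
directly from haplotype counts. Association-distance records measure,
for each significant marker, the genetic distance to the causal variant
with which it is in highest r2 (ties broken by genetic proximity, then
physical position) and to the closest causal variant. Capture curves
give, per resequencing window size, the fraction of association tests in
which at least one association falls within that distance of its
highest-r2 causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .disease import CausalSet
from .panel import HaplotypePanel, RecombinationMap

__all__ = [
    "r2",
    "r2_table",
    "genetic_position",
    "distance_records",
    "capture_curve",
    "default_windows",
    "dprime_ci",
    "ld_blocks",
    "block_capture",
    "LDBlock",
]


def genetic_position(bp, rmap: RecombinationMap):
    """Genetic position (cM) by linear interpolation on the map."""
    return rmap.genetic_position(bp)


# ---------------------------------------------------------------------------
# r2 and D'


def r2(panel: HaplotypePanel, a: int, b: int) -> float:
    """Haplotype-based r2 between two variant columns.

    r2 = (p_ab - p_a p_b)^2 / (p_a(1-p_a) p_b(1-p_b)); raises for
    monomorphic input.
    """
    ha = panel.haplotypes[:, a].astype(float)
    hb = panel.haplotypes[:, b].astype(float)
    pa, pb = ha.mean(), hb.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("r2 undefined for a monomorphic variant")
    d = (ha * hb).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def r2_table(panel: HaplotypePanel, rows: Sequence[int], cols: Sequence[int]) -> np.ndarray:
    """r2 between every row variant and every column variant (vectorized).

    Monomorphic pairs yield NaN.
    """
    hr = panel.haplotypes[:, rows].astype(np.float64)
    hc = panel.haplotypes[:, cols].astype(np.float64)
    n = panel.n_hap
    pr = hr.mean(axis=0)
    pc = hc.mean(axis=0)
    pj = hr.T @ hc / n
    d = pj - np.outer(pr, pc)
    denom = np.outer(pr * (1 - pr), pc * (1 - pc))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = d * d / denom
    out[denom <= 0] = np.nan
    return out


def _hap_counts(panel: HaplotypePanel, a: int, b: int) -> np.ndarray:
    ha = panel.haplotypes[:, a]
    hb = panel.haplotypes[:, b]
    idx = 2 * ha.astype(np.int64) + hb
    return np.bincount(idx, minlength=4).astype(float)  # [n00, n01, n10, n11]


def dprime_ci(
    n00: np.ndarray,
    n01: np.ndarray,
    n10: np.ndarray,
    n11: np.ndarray,
    grid: int = 1000,
    tail: float = 0.05,
):
    """|D'| point estimate and likelihood-grid confidence bounds.

    Vectorized over pairs. The bounds follow the standard approach used
    for Gabriel-type block calling: evaluate the multinomial likelihood of
    the haplotype counts over a |D'| grid (allele frequencies held at
    their MLEs), normalize, and report the 5th/95th cumulative
    percentiles. Returns ``(dprime, low, high)``.
    """
    n00, n01, n10, n11 = (np.asarray(x, dtype=float) for x in (n00, n01, n10, n11))
    n = n00 + n01 + n10 + n11
    pa = (n10 + n11) / n  # allele 1 at first site
    pb = (n01 + n11) / n
    pab = n11 / n
    d = pab - pa * pb
    sign = np.where(d >= 0, 1.0, -1.0)
    dmax = np.where(
        d >= 0,
        np.minimum(pa * (1 - pb), (1 - pa) * pb),
        np.minimum(pa * pb, (1 - pa) * (1 - pb)),
    )
    dmax = np.maximum(dmax, 1e-12)
    dp = np.abs(d) / dmax

    g = np.linspace(0.0, 1.0, grid + 1)  # |D'| grid
    dd = sign[:, None] * g[None, :] * dmax[:, None]  # (P, G)
    p11 = np.clip(pa[:, None] * pb[:, None] + dd, 1e-12, 1.0)
    p10 = np.clip(pa[:, None] * (1 - pb[:, None]) - dd, 1e-12, 1.0)
    p01 = np.clip((1 - pa[:, None]) * pb[:, None] - dd, 1e-12, 1.0)
    p00 = np.clip((1 - pa[:, None]) * (1 - pb[:, None]) + dd, 1e-12, 1.0)
    ll = (
        n00[:, None] * np.log(p00)
        + n01[:, None] * np.log(p01)
        + n10[:, None] * np.log(p10)
        + n11[:, None] * np.log(p11)
    )
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll)
    cum = np.cumsum(post, axis=1)
    cum /= cum[:, -1:]
    low = g[np.argmax(cum > tail, axis=1)]
    high = g[np.argmax(cum >= 1.0 - tail, axis=1)]
    return dp, low, high


# ---------------------------------------------------------------------------
# association distances and capture


def distance_records(
    scan: pd.DataFrame,
    causal: CausalSet,
    panel: HaplotypePanel,
    rmap: RecombinationMap,
) -> pd.DataFrame:
    """Per significant association: distance to its highest-r2 causal.

    Returns one row per significant marker with columns ``marker``,
    ``causal`` (panel column of the argmax-r2 causal variant), ``r2``,
    ``dist_highest`` and ``dist_closest`` (cM, non-negative). Argmax ties
    are broken by smaller genetic distance, then smaller bp.
    """
    if len(causal) == 0:
        raise ValueError("empty causal set")
    sig = scan[scan["significant"]] if "significant" in scan else scan
    if sig.empty:
        return pd.DataFrame(
            columns=["marker", "causal", "r2", "dist_highest", "dist_closest"]
        )
    markers = sig["marker"].to_numpy()
    cm_m = sig["cm"].to_numpy()
    cm_c = panel.variants["cm"].to_numpy()[causal.indices]
    bp_c = panel.variants["bp"].to_numpy()[causal.indices]
    r2m = r2_table(panel, markers, causal.indices)  # (n_sig, n_causal)
    r2m = np.nan_to_num(r2m, nan=-1.0)
    dist = np.abs(cm_m[:, None] - cm_c[None, :])

    # argmax r2 with (distance, bp) tie-breaks: lexicographic key
    best = np.zeros(len(markers), dtype=np.int64)
    for i in range(len(markers)):
        top = np.flatnonzero(r2m[i] >= r2m[i].max() - 1e-12)
        if top.size > 1:
            key = np.lexsort((bp_c[top], dist[i, top]))
            top = top[key]
        best[i] = top[0]
    rows = np.arange(len(markers))
    return pd.DataFrame(
        {
            "marker": markers,
            "causal": causal.indices[best],
            "r2": r2m[rows, best],
            "dist_highest": dist[rows, best],
            "dist_closest": dist.min(axis=1),
        }
    )


def default_windows(stop: float = 10.0, step: float = 0.005) -> np.ndarray:
    """Resequencing window grid (cM), 0 to ``stop`` inclusive."""
    return np.round(np.arange(0.0, stop + step / 2, step), 10)


def capture_curve(per_test_distances: Iterable[np.ndarray], windows: np.ndarray) -> np.ndarray:
    """Fraction of tests with >=1 association within each window size.

    ``per_test_distances`` holds, per association test with at least one
    significant association, the distances of its associations to their
    highest-r2 causal variants. The curve is non-decreasing in the window.
    """
    mins = np.array([np.min(d) for d in per_test_distances if len(d)])
    if mins.size == 0:
        raise ValueError("no tests with significant associations")
    return (mins[:, None] <= np.asarray(windows)[None, :]).mean(axis=0)


# ---------------------------------------------------------------------------
# Gabriel-style LD blocks


@dataclass(frozen=True)
class LDBlock:
    """An LD block over array markers, flank-expanded in cM.

    Physical and genetic bounds include the flank (default 0.0005 cM per
    side) added to compensate for block-boundary uncertainty.
    """

    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    members: np.ndarray  # panel column indices of member markers

    def contains_cm(self, cm: float) -> bool:
        return self.start_cm <= cm <= self.end_cm


def ld_blocks(
    panel: HaplotypePanel,
    marker_idx: np.ndarray,
    rmap: RecombinationMap,
    flank_cm: float = 0.0005,
    max_span_bp: int = 200_000,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    informative_frac: float = 0.95,
) -> list[LDBlock]:
    """Estimate Gabriel-style haplotype blocks from array markers.

    Pairs are classed by the D' confidence interval: strong LD if the CI
    is [>=strong_low, >=strong_high], strong recombination if the upper
    bound < recomb_high. A candidate block requires a strong outermost
    pair and >= ``informative_frac`` of informative pairs strong;
    candidates are accepted greedily by physical span. Each accepted
    block is expanded by ``flank_cm`` per side.
    """
    marker_idx = np.sort(np.asarray(marker_idx, dtype=np.int64))
    nm = marker_idx.size
    if nm < 2:
        return []
    bp = panel.variants["bp"].to_numpy()[marker_idx]
    cm = panel.variants["cm"].to_numpy()[marker_idx]
    h = panel.haplotypes[:, marker_idx]  # int8, shared counts via einsum
    colsum = h.sum(axis=0, dtype=np.int64)
    n_hap = panel.n_hap

    # width of the banded pair matrices
    wmax = 1
    for i in range(nm):
        j = np.searchsorted(bp, bp[i] + max_span_bp, side="right") - 1
        wmax = max(wmax, j - i)
    wmax = min(wmax, nm - 1)

    strong = np.zeros((nm, wmax + 1), dtype=bool)  # strong[i, d] ~ pair (i, i+d)
    inform = np.zeros((nm, wmax + 1), dtype=bool)
    # batched CI computation over diagonals
    for d in range(1, wmax + 1):
        i = np.arange(nm - d)
        ok = bp[i + d] - bp[i] <= max_span_bp
        i = i[ok]
        if i.size == 0:
            continue
        n11 = np.einsum("ij,ij->j", h[:, i], h[:, i + d], dtype=np.int64).astype(float)
        n10 = colsum[i] - n11
        n01 = colsum[i + d] - n11
        n00 = n_hap - n11 - n10 - n01
        poly = (colsum[i] % n_hap != 0) & (colsum[i + d] % n_hap != 0)
        _, low, high = dprime_ci(n00, n01, n10, n11)
        s = poly & (low >= strong_low) & (high >= strong_high)
        r = poly & (high < recomb_high)
        strong[i, d] = s
        inform[i, d] = s | r

    scum = np.cumsum(strong, axis=1)  # row-wise prefix over distance d
    icum = np.cumsum(inform, axis=1)

    candidates = []  # (span_bp, i, j)
    for i in range(nm - 1):
        jmax = min(nm - 1, i + wmax)
        width = jmax - i
        if width < 1:
            continue
        # counts of pairs within [i, j]: sum over a of prefix up to j - a
        ar = np.arange(i, jmax)  # rows a = i .. jmax-1
        jr = np.arange(1, width + 1)  # j = i + jr
        depth = jr[None, :] - (ar[:, None] - i)  # j - a
        depth = np.clip(depth, 0, wmax)
        valid_rows = depth > 0
        s_counts = np.where(valid_rows, scum[ar[:, None], depth], 0).sum(axis=0)
        i_counts = np.where(valid_rows, icum[ar[:, None], depth], 0).sum(axis=0)
        outer_strong = strong[i, np.clip(jr, 0, wmax)]
        span_ok = bp[i + jr] - bp[i] <= max_span_bp
        good = (
            outer_strong
            & span_ok
            & (i_counts > 0)
            & (s_counts >= informative_frac * i_counts)
        )
        for jr_g in np.flatnonzero(good):
            j = i + jr[jr_g]
            candidates.append((int(bp[j] - bp[i]), i, j))

    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(nm, dtype=bool)
    blocks: list[LDBlock] = []
    for _, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        lo_cm = cm[i] - flank_cm
        hi_cm = cm[j] + flank_cm
        blocks.append(
            LDBlock(
                start_bp=int(round(rmap.physical_position(lo_cm))),
                end_bp=int(round(rmap.physical_position(hi_cm))),
                start_cm=float(lo_cm),
                end_cm=float(hi_cm),
                members=marker_idx[i : j + 1],
            )
        )
    blocks.sort(key=lambda b: b.start_bp)
    return blocks


def block_capture(
    scan: pd.DataFrame,
    blocks: Sequence[LDBlock],
    causal: CausalSet,
    panel: HaplotypePanel,
) -> float:
    """Fraction of significant associations whose LD block holds a causal.

    An association inside a (flank-expanded) block is captured iff any
    causal variant's genetic position lies within that block's expanded
    interval; associations belonging to no block count as not captured.
    """
    sig = scan[scan["significant"]] if "significant" in scan else scan
    if sig.empty:
        raise ValueError("no significant associations")
    cm_c = panel.variants["cm"].to_numpy()[causal.indices] if len(causal) else np.empty(0)
    member_of = {}
    for bi, blk in enumerate(blocks):
        for mk in blk.members:
            member_of[int(mk)] = bi
    captured = 0
    for mk in sig["marker"].to_numpy():
        bi = member_of.get(int(mk))
        if bi is None:
            continue
        blk = blocks[bi]
        if len(cm_c) and np.any((cm_c >= blk.start_cm) & (cm_c <= blk.end_cm)):
            captured += 1
    return captured / len(sig)


def blocks_to_bed(blocks: Sequence[LDBlock], chrom: str = "1") -> pd.DataFrame:
    """Blocks as BED (0-based half-open physical coordinates)."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [b.start_bp - 1 for b in blocks],
            "end": [b.end_bp for b in blocks],
            "name": [f"block{i}" for i in range(len(blocks))],
        }
    )
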