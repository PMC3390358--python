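"""Pooled signature statistics contrasting synthetic vs. natural
associations, and the age-of-mutation partition of rare variants.

"Synthetic" associations are significant common-marker signals driven by
rare causal variants; "natural" associations have common causal variants.
The signatures pooled over all tests of a scenario are: the distribution
of association-to-causal genetic distances, capture fractions at named
window sizes, the LD-block capture rate, and the MAF distribution of
associated markers (median, fraction below 0.1, and standard deviation,
the latter being a proposed flag for underlying rare causal variants).
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .panel import HaplotypePanel

__all__ = [
    "maf_summary",
    "top_association",
    "top_assoc_maf",
    "classify_age",
    "compare_scenarios",
]


def maf_summary(mafs: Sequence[float]) -> dict:
    """Median, fraction < 0.1, and sample SD of pooled association MAFs.

    SD uses the n-1 denominator (0 for a single association). Raises on
    empty input.
    """
    m = np.asarray(mafs, dtype=float)
    if m.size == 0:
        raise ValueError("no associations to summarize")
    return {
        "n": int(m.size),
        "median_maf": float(np.median(m)),
        "frac_below_0.1": float((m < 0.1).mean()),
        "sd_maf": float(m.std(ddof=1)) if m.size > 1 else 0.0,
    }


def top_association(scan: pd.DataFrame) -> pd.Series:
    """The most significant association of one test.

    Ties on p are broken by larger |beta|, then smaller bp.
    """
    sig = scan[scan["significant"]] if "significant" in scan else scan
    if sig.empty:
        raise ValueError("test has no significant association")
    order = sig.assign(_absb=-sig["beta"].abs()).sort_values(["p", "_absb", "bp"])
    return order.iloc[0].drop(labels="_absb")


def top_assoc_maf(per_test_scans: Sequence[pd.DataFrame]) -> np.ndarray:
    """MAF of the most significant association, one value per test."""
    return np.array([top_association(s)["maf"] for s in per_test_scans], dtype=float)


def classify_age(
    panel: HaplotypePanel,
    candidates: Sequence[int],
    out_panels: Sequence[HaplotypePanel],
    freq_window: tuple = (0.005, 0.02),
) -> pd.Series:
    """Partition rare variants into relatively more-recent vs. older.

    A candidate's minor allele (in the focal panel) absent from *every*
    out-population panel marks the mutation as relatively ``more_recent``;
    presence in any out-panel marks it ``older``. Candidates must lie in
    the narrowed frequency window (default 0.005-0.02), which keeps the
    two age classes roughly balanced. Out-panels must share the focal
    panel's variant columns (same bp order).
    """
    if len(out_panels) == 0:
        raise ValueError("at least one out-population panel is required")
    candidates = np.asarray(candidates, dtype=np.int64)
    maf = panel.variants["maf"].to_numpy()[candidates]
    lo, hi = freq_window
    bad = (maf < lo) | (maf > hi)
    if bad.any():
        j = candidates[bad][0]
        raise ValueError(
            f"candidate column {j} (MAF {panel.variants['maf'].iloc[j]:.4f}) "
            f"outside the narrowed window [{lo}, {hi}]"
        )
    minor = panel.minor_allele()[candidates]  # allele value 0/1

    focal_bp = panel.variants["bp"].to_numpy()[candidates]
    labels = np.full(candidates.size, "more_recent", dtype=object)
    for out in out_panels:
        out_bp = out.variants["bp"].to_numpy()
        pos = np.searchsorted(out_bp, focal_bp)
        present_col = (pos < out_bp.size) & (out_bp[np.minimum(pos, out_bp.size - 1)] == focal_bp)
        for k in range(candidates.size):
            if labels[k] == "older":
                continue
            if not present_col[k]:
                continue  # site not observed segregating info; column must exist
            col = out.haplotypes[:, pos[k]]
            if np.any(col == minor[k]):
                labels[k] = "older"
    return pd.Series(labels, index=candidates, name="age_class")


def _boot_median_diff(a_by_test, b_by_test, rng, n_boot=1000):
    """Bootstrap CI of median(a) - median(b), resampling tests."""
    a_by_test = [np.asarray(x) for x in a_by_test if len(x)]
    b_by_test = [np.asarray(x) for x in b_by_test if len(x)]
    diffs = np.empty(n_boot)
    na, nb = len(a_by_test), len(b_by_test)
    for i in range(n_boot):
        ai = rng.integers(0, na, na)
        bi = rng.integers(0, nb, nb)
        diffs[i] = np.median(np.concatenate([a_by_test[k] for k in ai])) - np.median(
            np.concatenate([b_by_test[k] for k in bi])
        )
    return float(np.quantile(diffs, 0.025)), float(np.quantile(diffs, 0.975))


def compare_scenarios(
    per_test_values: Dict[str, Sequence[np.ndarray]],
    pairs: Sequence[tuple],
    seed: int = 0,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Ordered contrasts of pooled medians between scenarios.

    ``per_test_values`` maps scenario label -> list of per-test value
    arrays (e.g. association distances or MAFs); ``pairs`` lists
    (scenario_a, scenario_b) contrasts. For each pair the difference of
    pooled medians is reported with a bootstrap CI that resamples tests
    (respecting the replicate structure), plus the observed ordering.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        va = np.concatenate([np.asarray(x) for x in per_test_values[a] if len(x)] or [[]])
        vb = np.concatenate([np.asarray(x) for x in per_test_values[b] if len(x)] or [[]])
        if va.size == 0 or vb.size == 0:
            raise ValueError(f"no pooled values for contrast ({a}, {b})")
        diff = float(np.median(va) - np.median(vb))
        lo, hi = _boot_median_diff(per_test_values[a], per_test_values[b], rng, n_boot)
        rows.append(
            {
                "scenario_a": a,
                "scenario_b": b,
                "median_a": float(np.median(va)),
                "median_b": float(np.median(vb)),
                "median_diff": diff,
                "ci_low": lo,
                "ci_high": hi,
                "a_greater": diff > 0,
            }
        )
    return pd.DataFrame(rows)
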