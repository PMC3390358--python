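"""Core containers: recombination maps and phased haplotype panels.

A :class:`HaplotypePanel` holds a binary phased haplotype matrix together
with per-variant physical (bp) and genetic (cM) coordinates, mirroring the
layout of resequencing data for a disease locus plus its flanking region.
A :class:`RecombinationMap` is a piecewise-linear mapping from physical to
genetic position, in the style of a HapMap-format genetic map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["RecombinationMap", "HaplotypePanel"]


class RecombinationMap:
    """Piecewise-linear physical (bp) -> genetic (cM) map.

    Parameters
    ----------
    positions_bp
        Anchor physical positions, 1-based, strictly increasing.
    positions_cm
        Cumulative genetic positions (cM) at the anchors, non-decreasing.

    Interpolation between anchors is linear; queries beyond either end are
    extrapolated at the terminal interval's rate.
    """

    def __init__(self, positions_bp: Sequence[int], positions_cm: Sequence[float]):
        bp = np.asarray(positions_bp, dtype=float)
        cm = np.asarray(positions_cm, dtype=float)
        if bp.ndim != 1 or bp.shape != cm.shape or bp.size < 2:
            raise ValueError("map needs >=2 anchors of equal length")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("physical anchor positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("genetic anchor positions must be non-decreasing")
        self.positions_bp = bp
        self.positions_cm = cm

    @property
    def n_anchors(self) -> int:
        return self.positions_bp.size

    def _terminal_rates(self) -> tuple[float, float]:
        bp, cm = self.positions_bp, self.positions_cm
        left = (cm[1] - cm[0]) / (bp[1] - bp[0])
        right = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
        return left, right

    def genetic_position(self, bp):
        """Interpolated genetic position (cM) at physical position(s) ``bp``."""
        q = np.asarray(bp, dtype=float)
        out = np.interp(q, self.positions_bp, self.positions_cm)
        lrate, rrate = self._terminal_rates()
        lo = q < self.positions_bp[0]
        hi = q > self.positions_bp[-1]
        if np.any(lo):
            out = np.where(lo, self.positions_cm[0] - (self.positions_bp[0] - q) * lrate, out)
        if np.any(hi):
            out = np.where(hi, self.positions_cm[-1] + (q - self.positions_bp[-1]) * rrate, out)
        return float(out) if np.isscalar(bp) else out

    def physical_position(self, cm):
        """Inverse lookup: physical position at genetic position(s) ``cm``.

        Within flat (zero-rate) intervals the left edge is returned.
        """
        q = np.asarray(cm, dtype=float)
        out = np.interp(q, self.positions_cm, self.positions_bp)
        lrate, rrate = self._terminal_rates()
        lo = q < self.positions_cm[0]
        hi = q > self.positions_cm[-1]
        if np.any(lo) and lrate > 0:
            out = np.where(lo, self.positions_bp[0] - (self.positions_cm[0] - q) / lrate, out)
        if np.any(hi) and rrate > 0:
            out = np.where(hi, self.positions_bp[-1] + (q - self.positions_cm[-1]) / rrate, out)
        return float(out) if np.isscalar(cm) else out

    def rates_cm_per_mb(self) -> np.ndarray:
        """Per-interval recombination rates in cM/Mb."""
        return np.diff(self.positions_cm) / np.diff(self.positions_bp) * 1e6

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RecombinationMap({self.n_anchors} anchors, "
            f"{self.positions_bp[0]:.0f}-{self.positions_bp[-1]:.0f} bp, "
            f"{self.positions_cm[-1] - self.positions_cm[0]:.3f} cM)"
        )


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotype matrix with variant annotations.

    ``haplotypes`` has one row per haplotype and one column per variant
    (0 = reference allele, 1 = alternate allele). Rows pair consecutively
    into diploid individuals, so ``n_hap`` must be even. ``variants`` has
    columns ``id``, ``bp`` (1-based physical position), ``cm`` (genetic
    position) and ``maf`` (panel minor-allele frequency); columns are sorted
    by physical position.
    """

    haplotypes: np.ndarray
    variants: pd.DataFrame
    population_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_matrix(cls, haplotypes, bp, cm, ids=None, population_label="", meta=None):
        """Build a panel from a matrix and coordinates, computing MAF."""
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        bp = np.asarray(bp, dtype=np.int64)
        if ids is None:
            ids = [f"var{i:06d}" for i in range(len(bp))]
        variants = pd.DataFrame(
            {
                "id": list(ids),
                "bp": bp,
                "cm": np.asarray(cm, dtype=float),
                "maf": _maf(haplotypes),
            }
        )
        return cls(haplotypes, variants, population_label, meta or {})

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        h = self.haplotypes
        if h.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if h.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even (consecutive rows pair)")
        if h.size and not np.isin(h, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        v = self.variants
        if len(v) != h.shape[1]:
            raise ValueError("variant table length must match matrix columns")
        if len(v) and np.any(np.diff(v["bp"].to_numpy()) < 0):
            raise ValueError("variants must be sorted by physical position")
        if len(v) and not np.allclose(v["maf"].to_numpy(), _maf(h)):
            raise ValueError("stored MAF disagrees with the matrix")

    # -- basic views ----------------------------------------------------

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_var(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_ind(self) -> int:
        return self.n_hap // 2

    def alt_freq(self) -> np.ndarray:
        """Alternate (1) allele frequency per variant."""
        return self.haplotypes.mean(axis=0) if self.n_var else np.empty(0)

    def minor_allele(self) -> np.ndarray:
        """Which allele (0 or 1) is the minor one at each variant (ties -> 1)."""
        return (self.alt_freq() <= 0.5).astype(np.int8)

    def dosages(self, cols=None) -> np.ndarray:
        """Per-individual alternate-allele dosage (0/1/2) matrix."""
        h = self.haplotypes if cols is None else self.haplotypes[:, cols]
        return (h[0::2] + h[1::2]).astype(np.int8)

    def subset(self, cols) -> "HaplotypePanel":
        """Panel restricted to the given variant columns (kept sorted)."""
        cols = np.asarray(cols)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        cols = np.sort(cols)
        return HaplotypePanel(
            self.haplotypes[:, cols],
            self.variants.iloc[cols].reset_index(drop=True),
            self.population_label,
            dict(self.meta),
        )

    def __repr__(self) -> str:  # pragma: no cover
        lbl = f" [{self.population_label}]" if self.population_label else ""
        return f"HaplotypePanel({self.n_hap} haplotypes x {self.n_var} variants{lbl})"


def _maf(h: np.ndarray) -> np.ndarray:
    if h.shape[1] == 0:
        return np.empty(0)
    f = h.mean(axis=0)
    return np.minimum(f, 1.0 - f)
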