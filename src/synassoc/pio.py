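"""Reading and writing panels: phased VCF v4.2 + HapMap-format genetic maps.

The map format is whitespace-delimited with a header line::

    position COMBINED_rate(cM/Mb) Genetic_Map(cM)

Haplotypes are written as phased diploid GT fields (``0|1``); consecutive
panel rows pair into one sample column. Round-trips are exact: the matrix
and physical positions are integers, and map coordinates are printed with
17 significant digits so floats survive the text round-trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import HaplotypePanel, RecombinationMap

__all__ = ["read_panel", "write_panel", "read_map", "write_map", "read_vcf", "write_vcf"]

_MAP_HEADER = "position COMBINED_rate(cM/Mb) Genetic_Map(cM)"


def write_map(rmap: RecombinationMap, path) -> None:
    """Write a genetic map in 3-column HapMap format."""
    bp = rmap.positions_bp
    cm = rmap.positions_cm
    rates = np.append(rmap.rates_cm_per_mb(), 0.0)
    with open(path, "w") as fh:
        fh.write(_MAP_HEADER + "\n")
        for b, r, c in zip(bp, rates, cm):
            fh.write(f"{int(b)} {r:.17g} {c:.17g}\n")


def read_map(path) -> RecombinationMap:
    """Read a 3-column HapMap-format genetic map; validates ordering."""
    df = pd.read_csv(
        path, sep=r"\s+", skiprows=1, header=None,
        names=["bp", "rate", "cm"], float_precision="round_trip",
    )
    if len(df) < 2:
        raise ValueError(f"{path}: genetic map needs >=2 anchors")
    bp = df["bp"].to_numpy()
    cm = df["cm"].to_numpy()
    if np.any(np.diff(bp) <= 0):
        raise ValueError(f"{path}: map positions not strictly increasing")
    if np.any(np.diff(cm) < 0):
        raise ValueError(f"{path}: cumulative cM decreases (unsorted map)")
    return RecombinationMap(bp, cm)


def write_vcf(panel: HaplotypePanel, path, contig: str = "1") -> None:
    """Write the panel as an uncompressed phased VCF v4.2."""
    n_samp = panel.n_ind
    names = "\t".join(f"S{i:05d}" for i in range(n_samp))
    h = panel.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for j, (vid, bp) in enumerate(zip(panel.variants["id"], panel.variants["bp"])):
            gts = "\t".join(f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(n_samp))
            fh.write(f"{contig}\t{int(bp)}\t{vid}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, rmap: RecombinationMap | None = None, population_label: str = "") -> HaplotypePanel:
    """Read a phased VCF into a panel.

    Raises on the first unphased or missing genotype, naming the record.
    Genetic positions are interpolated from ``rmap`` when given, else 0.
    """
    vcf = VCF(str(path))
    cols, bps, ids = [], [], []
    for rec in vcf:
        gts = np.asarray(rec.genotype.array())
        if np.any(gts[:, :2] < 0):
            raise ValueError(f"missing genotype at {rec.CHROM}:{rec.POS}")
        if np.any(gts[:, 2] == 0):
            raise ValueError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
        cols.append(gts[:, :2].reshape(-1))
        bps.append(rec.POS)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    vcf.close()
    if not cols:
        raise ValueError(f"{path}: no variant records")
    h = np.asarray(cols, dtype=np.int8).T
    bps = np.asarray(bps, dtype=np.int64)
    cm = rmap.genetic_position(bps) if rmap is not None else np.zeros(len(bps))
    return HaplotypePanel.from_matrix(h, bps, cm, ids=ids, population_label=population_label)


def write_panel(panel: HaplotypePanel, rmap: RecombinationMap, vcf_path, map_path) -> None:
    """Write a panel + map pair (phased VCF and HapMap-format map)."""
    write_vcf(panel, vcf_path)
    write_map(rmap, map_path)


def read_panel(vcf_path, map_path, population_label: str = ""):
    """Read a panel + map pair; returns ``(HaplotypePanel, RecombinationMap)``."""
    rmap = read_map(map_path)
    panel = read_vcf(vcf_path, rmap, population_label)
    return panel, rmap
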