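"""Replication driver binding all stages into the full experimental design.

For each demography preset and each independent "disease locus" draw:
simulate a resequenced panel plus array markers, expand it to GWAS scale
with the mosaic resampler, then for every causal scenario draw ``n_sets``
causal-variant sets and ``n_replicates`` stochastic case/control
assignments per set, scan the region, and pool the signature statistics.
Everything is reproducible from the master seed; each test's seed path is
recorded in the per-test output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import assoc, disease, lddist, signatures, simdata
from .disease import DiseaseScenario, STANDARD_SCENARIOS
from .panel import HaplotypePanel, RecombinationMap

__all__ = ["ExperimentConfig", "ExperimentResult", "RegionData", "prepare_region", "run_experiment"]

log = logging.getLogger("synassoc")

NAMED_WINDOWS = (0.01, 0.1, 1.0)  # cM, reported in summaries


@dataclass
class ExperimentConfig:
    """All knobs of one experiment; defaults follow the full study design."""

    demographies: Tuple[str, ...] = ("bottleneck_growth", "constant")
    n_loci: int = 5
    locus_length: int = 100_000
    flank_cm: float = 3.0
    n_hap_panel: int = 220
    n_expanded: int = 10_000  # diploid individuals after mosaic expansion
    scenarios: Tuple[DiseaseScenario, ...] = STANDARD_SCENARIOS
    n_sets: int = 50
    n_replicates: int = 10
    n_cases: int = 1_000
    n_controls: int = 1_000
    alpha: float = 0.05
    maf_floor: float = 0.05
    array_spacing: int = 2_000
    copy_error: float = 1e-4
    compute_blocks: bool = True
    max_retries: int = 10
    seed: int = 0

    def scale(self, factor: float) -> "ExperimentConfig":
        """Proportionally reduced desk-scale profile.

        Scales the number of causal sets and the population/cohort sizes;
        replicates per set are kept so the set/replicate structure
        survives. Schemas never change, only counts.
        """
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return dataclasses.replace(
            self,
            n_sets=max(1, round(self.n_sets * factor)),
            n_expanded=max(self.n_cases + self.n_controls, round(self.n_expanded * factor))
            if factor < 1
            else round(self.n_expanded * factor),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "scenarios" in d:
            d["scenarios"] = tuple(
                DiseaseScenario(
                    label=s["label"],
                    n_causal=s["n_causal"],
                    freq_window=tuple(s["freq_window"]),
                    grr=s["grr"],
                    baseline_risk=s.get("baseline_risk", 0.15),
                    combination=s.get("combination", "per_copy"),
                )
                if s.get("n_causal", 0) > 0
                else disease.null_scenario(s.get("label", "null"))
                for s in d["scenarios"]
            )
        if "demographies" in d:
            d["demographies"] = tuple(d["demographies"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _seed(*key) -> int:
    """Stable child seed from a master seed and an index tuple (< 2^31)."""
    return int(np.random.SeedSequence(tuple(int(k) for k in key)).generate_state(1)[0] % (2**31 - 1))


@dataclass
class RegionData:
    """One simulated locus, its array, and the expanded analysis panel."""

    demography: str
    locus: int
    base_panel: HaplotypePanel
    rmap: RecombinationMap
    expanded: HaplotypePanel  # analysis columns only (array + locus variants)
    marker_cols: np.ndarray  # array-marker columns of `expanded`
    locus_bounds: Tuple[int, int]
    dosages: np.ndarray  # (n_ind, n_cols) alternate-allele dosages of `expanded`
    blocks: list = field(default_factory=list)
    outgroup: Optional[HaplotypePanel] = None


def prepare_region(
    config: ExperimentConfig,
    demography_label: str,
    locus: int,
    with_outgroup: bool = False,
) -> RegionData:
    """Simulate and expand one locus-by-demography region."""
    preset = simdata.get_preset(demography_label)
    preset = dataclasses.replace(preset, label=preset.label)
    di = list(config.demographies).index(demography_label) if demography_label in config.demographies else 0
    sim_seed = _seed(config.seed, 1, di, locus)

    if with_outgroup:
        base, rmap, outgroup = simdata.simulate_cohort(
            preset, config.locus_length, config.flank_cm, config.n_hap_panel, sim_seed,
            n_outgroup_hap=config.n_hap_panel,
        )
    else:
        base, rmap = simdata.simulate_panel(
            preset, config.locus_length, config.flank_cm, config.n_hap_panel, sim_seed
        )
        outgroup = None
    locus_bounds = base.meta["locus_bounds"]
    log.info(
        "region %s/L%d: %d panel haplotypes x %d variants",
        demography_label, locus, base.n_hap, base.n_var,
    )

    array_idx = simdata.ascertain_array(
        base, config.maf_floor, config.array_spacing, seed=_seed(config.seed, 2, di, locus)
    )
    bp = base.variants["bp"].to_numpy()
    in_locus = np.flatnonzero((bp >= locus_bounds[0]) & (bp <= locus_bounds[1]))
    analysis_cols = np.union1d(array_idx, in_locus)
    sub = base.subset(analysis_cols)
    if outgroup is not None:
        outgroup = outgroup.subset(analysis_cols)
    marker_cols = np.searchsorted(analysis_cols, array_idx)

    params = simdata.MosaicParams(copy_error=config.copy_error)
    expanded = simdata.resample_mosaic(
        sub, 2 * config.n_expanded, rmap, params,
        seed=_seed(config.seed, 3, di, locus), ne=preset.ancestral_size,
    )
    # markers can drift below the polymorphism floor during expansion, but
    # stay in the tested set (as on a real array)
    dosages = expanded.dosages()

    blocks = []
    if config.compute_blocks:
        blocks = lddist.ld_blocks(expanded, marker_cols, rmap)
        log.info("region %s/L%d: %d LD blocks", demography_label, locus, len(blocks))
    return RegionData(
        demography_label, locus, base, rmap, expanded, marker_cols,
        locus_bounds, dosages, blocks, outgroup,
    )


@dataclass
class ExperimentResult:
    """Pooled outputs of :func:`run_experiment`."""

    associations: pd.DataFrame  # one row per significant association
    tests: pd.DataFrame  # one row per association test
    summaries: pd.DataFrame  # signature summary per scenario x region
    config: ExperimentConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.associations.to_csv(out / "associations.tsv", sep="\t", index=False)
        self.tests.to_csv(out / "tests.tsv", sep="\t", index=False)
        self.summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)


def run_scenario_tests(
    region: RegionData,
    scenario: DiseaseScenario,
    config: ExperimentConfig,
    scenario_index: int,
) -> Tuple[list, list]:
    """All (set x replicate) tests of one scenario on one region.

    Returns (association rows, test rows). Stage errors are recorded per
    test; the scenario aborts only if more than half its tests fail.
    """
    di = list(config.demographies).index(region.demography) if region.demography in config.demographies else 0
    assoc_rows, test_rows = [], []
    n_failed = 0
    n_total = config.n_sets * config.n_replicates

    for set_i in range(config.n_sets):
        causal = None
        err = None
        if not scenario.is_null:
            try:
                causal = disease.select_causal(
                    region.expanded, scenario, region.locus_bounds,
                    seed=_seed(config.seed, 4, di, region.locus, scenario_index, set_i),
                )
                risks = disease.assign_risk(
                    disease.risk_dosages(region.expanded, causal), scenario
                )
            except (ValueError, RuntimeError) as e:
                err = str(e)
        for rep in range(config.n_replicates):
            seed_path = f"{config.seed}/{region.demography}.L{region.locus}/{scenario.label}/set{set_i}/rep{rep}"
            row = {
                "demography": region.demography,
                "locus": region.locus,
                "scenario": scenario.label,
                "set": set_i,
                "rep": rep,
                "seed_path": seed_path,
            }
            if err is not None:
                n_failed += 1
                test_rows.append({**row, "error": err, "n_sig": np.nan, "any_sig": False})
                continue
            try:
                rep_seed = _seed(config.seed, 5, di, region.locus, scenario_index, set_i, rep)
                if scenario.is_null:
                    phen = disease.null_assignment(
                        config.n_expanded, config.n_cases, config.n_controls, rep_seed
                    )
                else:
                    phen = disease.sample_case_control(
                        risks, config.n_cases, config.n_controls, rep_seed, config.max_retries
                    )
                scan = assoc.region_scan(
                    region.expanded, region.marker_cols, phen, causal,
                    region.locus_bounds, config.flank_cm, region.rmap,
                    config.alpha, dosages_full=region.dosages,
                )
            except (ValueError, RuntimeError) as e:
                n_failed += 1
                test_rows.append({**row, "error": str(e), "n_sig": np.nan, "any_sig": False})
                continue

            sig = scan[scan["significant"]]
            trow = {
                **row,
                "error": "",
                "n_sig": len(sig),
                "any_sig": len(sig) > 0,
                "m_tested": scan.attrs["m_tested"],
            }
            if len(sig):
                trow["top_maf"] = float(signatures.top_association(scan)["maf"])
                if not scenario.is_null:
                    rec = lddist.distance_records(scan, causal, region.expanded, region.rmap)
                    trow["min_dist_highest"] = float(rec["dist_highest"].min())
                    bc = np.nan
                    if region.blocks:
                        bc = lddist.block_capture(scan, region.blocks, causal, region.expanded)
                    trow["block_capture"] = bc
                    for (_, srow), (_, drow) in zip(sig.iterrows(), rec.iterrows()):
                        assoc_rows.append(
                            {
                                **row,
                                "marker": int(srow["marker"]),
                                "bp": int(srow["bp"]),
                                "cm": srow["cm"],
                                "maf": srow["maf"],
                                "beta": srow["beta"],
                                "p": srow["p"],
                                "r2_causal": drow["r2"],
                                "dist_highest": drow["dist_highest"],
                                "dist_closest": drow["dist_closest"],
                            }
                        )
                else:
                    for _, srow in sig.iterrows():
                        assoc_rows.append(
                            {
                                **row,
                                "marker": int(srow["marker"]),
                                "bp": int(srow["bp"]),
                                "cm": srow["cm"],
                                "maf": srow["maf"],
                                "beta": srow["beta"],
                                "p": srow["p"],
                                "r2_causal": np.nan,
                                "dist_highest": np.nan,
                                "dist_closest": np.nan,
                            }
                        )
            test_rows.append(trow)

    if n_failed > n_total / 2:
        raise RuntimeError(
            f"scenario {scenario.label} on {region.demography}/L{region.locus}: "
            f"{n_failed}/{n_total} tests failed"
        )
    if n_failed:
        log.warning(
            "scenario %s on %s/L%d: %d/%d tests failed",
            scenario.label, region.demography, region.locus, n_failed, n_total,
        )
    return assoc_rows, test_rows


def summarize(associations: pd.DataFrame, tests: pd.DataFrame) -> pd.DataFrame:
    """Signature summary per scenario x demography x locus."""
    rows = []
    for key, tgrp in tests.groupby(["demography", "locus", "scenario"], sort=False):
        dem, locus, scen = key
        agrp = associations[
            (associations["demography"] == dem)
            & (associations["locus"] == locus)
            & (associations["scenario"] == scen)
        ]
        row = {
            "demography": dem,
            "locus": locus,
            "scenario": scen,
            "n_tests": len(tgrp),
            "frac_tests_any_sig": float(tgrp["any_sig"].mean()),
            "n_assoc": len(agrp),
        }
        if len(agrp):
            ms = signatures.maf_summary(agrp["maf"].to_numpy())
            row["median_maf"] = ms["median_maf"]
            row["frac_maf_below_0.1"] = ms["frac_below_0.1"]
            row["sd_maf"] = ms["sd_maf"]
            if agrp["dist_highest"].notna().any():
                d = agrp["dist_highest"].dropna().to_numpy()
                row["median_dist"] = float(np.median(d))
                row["iqr_dist"] = float(np.subtract(*np.percentile(d, [75, 25])))
                mins = tgrp["min_dist_highest"].dropna().to_numpy()
                for w in NAMED_WINDOWS:
                    row[f"capture_{w}cM"] = float((mins <= w).mean()) if mins.size else np.nan
            if "top_maf" in tgrp.columns:
                row["median_top_maf"] = float(tgrp["top_maf"].dropna().median())
            if "block_capture" in tgrp.columns:
                bc = tgrp["block_capture"].dropna()
                row["block_capture"] = float(bc.mean()) if len(bc) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def null_scan_fraction(region: RegionData, config: ExperimentConfig, n_scans: int) -> float:
    """Fraction of random-label scans with any Bonferroni-significant marker.

    Case/control labels are assigned uniformly at random, independent of
    all genotypes, giving the family-wise error rate of the region-wide
    scan; with a valid Bonferroni correction this is bounded by alpha.
    """
    hits = 0
    for i in range(n_scans):
        phen = disease.null_assignment(
            config.n_expanded, config.n_cases, config.n_controls,
            _seed(config.seed, 6, region.locus, i),
        )
        scan = assoc.region_scan(
            region.expanded, region.marker_cols, phen, None,
            region.locus_bounds, config.flank_cm, region.rmap,
            config.alpha, dosages_full=region.dosages,
        )
        hits += bool(scan["significant"].any())
    return hits / n_scans


def age_partition_tests(
    region: RegionData,
    config: ExperimentConfig,
    grr: float = 3.0,
    n_causal: int = 5,
    n_sets: int = 10,
    n_replicates: int = 3,
    freq_window: Tuple[float, float] = disease.RARE_NARROW_WINDOW,
):
    """Association tests with causal sets drawn within one mutation-age class.

    Rare variants in the narrowed frequency window are partitioned into
    relatively ``more_recent`` (minor allele absent from the out-population
    panel) vs. ``older`` classes; for each class, ``n_sets`` causal sets of
    ``n_causal`` variants are drawn from that class only and tested as
    usual. Returns ``{class: [per-test distance arrays]}`` for tests with
    at least one significant association.

    Requires the region to have been prepared with an outgroup panel.
    """
    from . import signatures as _sig

    if region.outgroup is None:
        raise ValueError("region has no out-population panel")
    exp = region.expanded
    bp = exp.variants["bp"].to_numpy()
    maf = exp.variants["maf"].to_numpy()
    minor_count = np.rint(maf * exp.n_hap)
    lo, hi = freq_window
    cand = np.flatnonzero(
        (bp >= region.locus_bounds[0]) & (bp <= region.locus_bounds[1])
        & (maf >= lo) & (maf <= hi) & (minor_count >= 2)
    )
    labels = _sig.classify_age(exp, cand, [region.outgroup], freq_window)
    scenario = DiseaseScenario(f"rare{n_causal}_aged", n_causal, freq_window, grr)
    minor = exp.minor_allele()

    out: dict[str, list] = {}
    for ci, cls in enumerate(("more_recent", "older")):
        pool = cand[(labels == cls).to_numpy()]
        if pool.size < n_causal:
            raise ValueError(f"only {pool.size} candidates in age class {cls!r}")
        per_test = []
        for set_i in range(n_sets):
            rng = np.random.default_rng(_seed(config.seed, 7, region.locus, ci, set_i))
            idx = np.sort(rng.choice(pool, n_causal, replace=False))
            causal = disease.CausalSet(idx, minor[idx], maf[idx])
            risks = disease.assign_risk(disease.risk_dosages(exp, causal), scenario)
            for rep in range(n_replicates):
                try:
                    phen = disease.sample_case_control(
                        risks, config.n_cases, config.n_controls,
                        _seed(config.seed, 8, region.locus, ci, set_i, rep),
                        config.max_retries,
                    )
                    scan = assoc.region_scan(
                        exp, region.marker_cols, phen, causal,
                        region.locus_bounds, config.flank_cm, region.rmap,
                        config.alpha, dosages_full=region.dosages,
                    )
                except (ValueError, RuntimeError):
                    continue
                if scan["significant"].any():
                    rec = lddist.distance_records(scan, causal, exp, region.rmap)
                    per_test.append(rec["dist_highest"].to_numpy())
        out[cls] = per_test
    return out


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentResult:
    """Run the full design; optionally write per-test and summary TSVs."""
    all_assoc, all_tests = [], []
    for dem in config.demographies:
        for locus in range(config.n_loci):
            region = prepare_region(config, dem, locus)
            for si, scen in enumerate(config.scenarios):
                a, t = run_scenario_tests(region, scen, config, si)
                all_assoc.extend(a)
                all_tests.extend(t)
                log.info(
                    "%s/L%d %s: %d tests, %d with >=1 significant",
                    dem, locus, scen.label, len(t), int(sum(r.get("any_sig", False) for r in t)),
                )
            del region
    assoc_cols = [
        "demography", "locus", "scenario", "set", "rep", "seed_path",
        "marker", "bp", "cm", "maf", "beta", "p",
        "r2_causal", "dist_highest", "dist_closest",
    ]
    associations = pd.DataFrame(all_assoc, columns=assoc_cols if not all_assoc else None)
    tests = pd.DataFrame(all_tests)
    summaries = summarize(associations, tests) if len(tests) else pd.DataFrame()
    result = ExperimentResult(associations, tests, summaries, config)
    if out_dir is not None:
        result.write(out_dir)
    return result
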