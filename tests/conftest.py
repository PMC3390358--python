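"""Shared fixtures: toy panels and desk-scale experiment runs.

The expensive session fixtures run the pipeline once at reduced scale
(fewer causal sets/replicates and smaller cohorts than the full design)
and are shared across the statistical and directional tests.
"""

import numpy as np
import pytest

import synassoc as sa
from synassoc.disease import STANDARD_SCENARIOS
from synassoc.pipeline import (
    ExperimentConfig,
    age_partition_tests,
    null_scan_fraction,
    prepare_region,
    run_experiment,
)


@pytest.fixture(scope="session")
def toy_panel():
    """Small constant-size panel + map for unit tests (20 haps, ~20 kb)."""
    panel, rmap = sa.simulate_panel(sa.CONSTANT, 20_000, 0.05, 20, seed=101)
    return panel, rmap


@pytest.fixture(scope="session")
def mini_cfg():
    """Reduced profile preserving every statistic's definition."""
    return ExperimentConfig(
        demographies=("bottleneck_growth", "constant"),
        n_loci=1,
        flank_cm=0.5,
        n_hap_panel=220,
        n_expanded=4_000,
        n_cases=500,
        n_controls=500,
        n_sets=8,
        n_replicates=3,
        scenarios=STANDARD_SCENARIOS,
        compute_blocks=True,
        seed=2026,
    )


@pytest.fixture(scope="session")
def mini_result(mini_cfg):
    """One full (desk-scale) experiment across all six scenarios."""
    return run_experiment(mini_cfg)


@pytest.fixture(scope="session")
def growth_region(mini_cfg):
    """The CEU-like region of the mini profile, with LD blocks."""
    return prepare_region(mini_cfg, "bottleneck_growth", 0)


@pytest.fixture(scope="session")
def null_fwer():
    """FWER of the region-wide scan over 200 random-label scans.

    Uses the null-scan design: CEU-like locus with 3 cM flanks, 2,000
    diploids after expansion, 1000 cases + 1000 controls labelled
    uniformly at random.
    """
    cfg = ExperimentConfig(
        demographies=("bottleneck_growth",),
        n_loci=1,
        n_expanded=2_000,
        n_cases=1_000,
        n_controls=1_000,
        compute_blocks=False,
        seed=31,
    )
    region = prepare_region(cfg, "bottleneck_growth", 0)
    return null_scan_fraction(region, cfg, n_scans=200)


@pytest.fixture(scope="session")
def desk_cfg():
    """Desk-scale profile of the main scenario runs (full cohort design)."""
    scens = tuple(
        s for s in STANDARD_SCENARIOS
        if s.label in ("common2_grr1.5", "rare5_grr3", "rare9_grr3")
    )
    return ExperimentConfig(
        demographies=("bottleneck_growth", "constant"),
        n_loci=2,
        n_expanded=10_000,
        n_cases=1_000,
        n_controls=1_000,
        n_sets=13,
        n_replicates=4,
        scenarios=scens,
        compute_blocks=False,
        seed=1729,
    )


@pytest.fixture(scope="session")
def desk_result(desk_cfg):
    """Scenario runs at the full 1000+1000 cohort design, fewer sets."""
    return run_experiment(desk_cfg)


@pytest.fixture(scope="session")
def age_partition():
    """Distance pools for more-recent vs. older rare causal variants."""
    cfg = ExperimentConfig(
        demographies=("bottleneck_growth",),
        n_loci=1,
        flank_cm=2.0,
        n_expanded=10_000,
        n_cases=1_000,
        n_controls=1_000,
        compute_blocks=False,
        seed=99,
    )
    region = prepare_region(cfg, "bottleneck_growth", 0, with_outgroup=True)
    return age_partition_tests(region, cfg, n_sets=25, n_replicates=4)


def pooled(values_by_test):
    return np.concatenate([np.asarray(v) for v in values_by_test if len(v)])
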