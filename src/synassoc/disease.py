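"""Disease model: causal-variant selection, genotypic relative risk, and
case/control sampling.

Each scenario fixes a number of causal variants, a risk-allele frequency
window (computed in the *expanded* sample), a genotypic relative risk
(GRR) per risk-allele copy, and a baseline risk. Individual risk is
p_i = min(1, pi0 * grr**a_i) with a_i the individual's total risk-allele
count over the causal set (a per-carrier alternative is available).
Disease status is Bernoulli(p_i); fixed numbers of cases and controls are
then drawn without replacement from the affected and unaffected pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .panel import HaplotypePanel

__all__ = [
    "DiseaseScenario",
    "CausalSet",
    "PhenotypeAssignment",
    "select_causal",
    "risk_dosages",
    "assign_risk",
    "sample_case_control",
    "null_assignment",
    "COMMON_WINDOW",
    "RARE_WINDOW",
    "RARE_NARROW_WINDOW",
]

# risk-allele frequency windows in the expanded sample
COMMON_WINDOW = (0.1, 0.3)
RARE_WINDOW = (0.005, 0.04)
# narrowed window used for the age-of-mutation partition
RARE_NARROW_WINDOW = (0.005, 0.02)


@dataclass(frozen=True)
class DiseaseScenario:
    """A causal-architecture scenario for one set of association tests."""

    label: str
    n_causal: int
    freq_window: Tuple[float, float]
    grr: float
    baseline_risk: float = 0.15
    combination: str = "per_copy"  # or "carrier"

    def __post_init__(self):
        lo, hi = self.freq_window
        if not 0.0 < lo < hi < 0.5:
            raise ValueError("frequency window must satisfy 0 < low < high < 0.5")
        if self.grr < 1.0:
            raise ValueError("GRR must be >= 1")
        if not 0.0 < self.baseline_risk < 1.0:
            raise ValueError("baseline risk must be in (0, 1)")
        if self.combination not in ("per_copy", "carrier"):
            raise ValueError("combination must be 'per_copy' or 'carrier'")
        if self.n_causal < 0:
            raise ValueError("n_causal must be non-negative")

    @property
    def is_null(self) -> bool:
        return self.n_causal == 0

    def window_mean(self) -> float:
        """Mean risk-allele frequency under uniform draws from the window."""
        return 0.5 * (self.freq_window[0] + self.freq_window[1])


def null_scenario(label: str = "null") -> DiseaseScenario:
    return DiseaseScenario(label, 0, (0.005, 0.04), 1.0)


# scenarios of the standard experimental design
STANDARD_SCENARIOS = (
    DiseaseScenario("common2_grr1.5", 2, COMMON_WINDOW, 1.5),
    DiseaseScenario("common2_grr3", 2, COMMON_WINDOW, 3.0),
    DiseaseScenario("common5_grr1.5", 5, COMMON_WINDOW, 1.5),
    DiseaseScenario("rare5_grr3", 5, RARE_WINDOW, 3.0),
    DiseaseScenario("rare9_grr3", 9, RARE_WINDOW, 3.0),
    null_scenario(),
)


@dataclass(frozen=True)
class CausalSet:
    """Indices of causal variants (into a panel) and their risk alleles.

    ``risk_allele`` holds, per causal variant, which allele (0/1 coding of
    the panel matrix) is the risk-increasing minor allele; ``freq`` its
    frequency in the panel the set was selected from.
    """

    indices: np.ndarray
    risk_allele: np.ndarray
    freq: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def select_causal(
    panel: HaplotypePanel,
    scenario: DiseaseScenario,
    locus_bounds: Tuple[int, int],
    seed: int,
) -> CausalSet:
    """Draw the scenario's causal variants uniformly from eligible sites.

    Eligibility: physical position within ``locus_bounds`` (inclusive),
    minor-allele frequency inside the scenario window as computed on
    ``panel`` (intended to be the expanded sample), and not a singleton
    (minor-allele count >= 2).
    """
    if scenario.is_null:
        return CausalSet(np.empty(0, np.int64), np.empty(0, np.int8), np.empty(0))
    bp = panel.variants["bp"].to_numpy()
    maf = panel.variants["maf"].to_numpy()
    minor_count = np.rint(maf * panel.n_hap)
    lo, hi = scenario.freq_window
    eligible = np.flatnonzero(
        (bp >= locus_bounds[0])
        & (bp <= locus_bounds[1])
        & (maf >= lo)
        & (maf <= hi)
        & (minor_count >= 2)
    )
    if eligible.size < scenario.n_causal:
        raise ValueError(
            f"only {eligible.size} eligible causal variants in window "
            f"{scenario.freq_window} within locus {locus_bounds}; "
            f"{scenario.n_causal} requested"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(eligible, size=scenario.n_causal, replace=False))
    risk_allele = panel.minor_allele()[idx]
    return CausalSet(idx, risk_allele, maf[idx])


def risk_dosages(panel: HaplotypePanel, causal: CausalSet) -> np.ndarray:
    """Per-individual risk-allele counts (n_ind x n_causal matrix)."""
    dos = panel.dosages(causal.indices).astype(np.int16)
    flip = causal.risk_allele == 0
    dos[:, flip] = 2 - dos[:, flip]
    return dos


def assign_risk(genotypes: np.ndarray, scenario: DiseaseScenario) -> np.ndarray:
    """Individual disease probability from risk-allele genotypes.

    ``genotypes`` is an (n_ind, n_causal) matrix of risk-allele counts in
    {0, 1, 2}. Per-copy combination: p = min(1, pi0 * grr**a) with a the
    row sum; carrier combination: p = pi0 * grr for a >= 1, else pi0.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2:
        raise ValueError("genotypes must be a 2-D (individuals x causal) matrix")
    if g.size and (g.min() < 0 or g.max() > 2):
        raise ValueError("genotypes must be in {0, 1, 2}")
    a = g.sum(axis=1)
    if scenario.combination == "carrier":
        p = np.where(a > 0, scenario.baseline_risk * scenario.grr, scenario.baseline_risk)
    else:
        p = scenario.baseline_risk * scenario.grr ** a
    return np.minimum(p, 1.0)


@dataclass(frozen=True)
class PhenotypeAssignment:
    """Disease statuses and the sampled case/control cohort."""

    status: np.ndarray  # bool per population individual
    case_idx: np.ndarray
    control_idx: np.ndarray
    risks: Optional[np.ndarray] = None

    @property
    def individuals(self) -> np.ndarray:
        """Population indices of the cohort (cases first, then controls)."""
        return np.concatenate([self.case_idx, self.control_idx])

    @property
    def y(self) -> np.ndarray:
        """Phenotype vector aligned with :attr:`individuals` (case = 1)."""
        return np.concatenate(
            [np.ones(len(self.case_idx), np.int8), np.zeros(len(self.control_idx), np.int8)]
        )

    def __post_init__(self):
        if not self.status[self.case_idx].all():
            raise ValueError("cases must be affected")
        if self.status[self.control_idx].any():
            raise ValueError("controls must be unaffected")


def sample_case_control(
    risks: np.ndarray,
    n_cases: int,
    n_controls: int,
    seed: int,
    max_retries: int = 10,
) -> PhenotypeAssignment:
    """Draw statuses Bernoulli(p_i) and sample the case/control cohort.

    Affected/unaffected pools are redrawn up to ``max_retries`` times if
    either is smaller than requested (possible in rare-causal scenarios).
    """
    risks = np.asarray(risks, dtype=float)
    n = risks.size
    if n < n_cases + n_controls:
        raise ValueError("population smaller than requested cohort")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries + 1):
        status = rng.random(n) < risks
        affected = np.flatnonzero(status)
        unaffected = np.flatnonzero(~status)
        if affected.size >= n_cases and unaffected.size >= n_controls:
            cases = np.sort(rng.choice(affected, n_cases, replace=False))
            controls = np.sort(rng.choice(unaffected, n_controls, replace=False))
            return PhenotypeAssignment(status, cases, controls, risks)
    raise RuntimeError(
        f"case/control pools insufficient after {max_retries} retries: "
        f"{affected.size} affected (need {n_cases}), "
        f"{unaffected.size} unaffected (need {n_controls})"
    )


def null_assignment(n: int, n_cases: int, n_controls: int, seed: int) -> PhenotypeAssignment:
    """Uniformly random case/control labels, independent of any genotype."""
    if n < n_cases + n_controls:
        raise ValueError("population smaller than requested cohort")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cases = np.sort(perm[:n_cases])
    controls = np.sort(perm[n_cases : n_cases + n_controls])
    status = np.zeros(n, dtype=bool)
    status[cases] = True
    return PhenotypeAssignment(status, cases, controls)
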