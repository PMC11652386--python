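"""Synthetic case-control genotype data with known ground truth.

Controls are drawn from Hardy-Weinberg proportions at a given alt-allele
frequency q: (p^2, 2pq, q^2) with p = 1 - q. Cases use the exposure-odds
construction: the control genotype frequencies are tilted by the
genotype-specific odds ratios (1, or_het, or_hom) and renormalised,

    f_case  proportional to  (p^2 * 1,  2pq * or_het,  q^2 * or_hom),

which is the genotype distribution among cases of a case-control design
whose het-vs-ref-hom and hom-vs-ref-hom odds ratios equal or_het and or_hom
— without having to specify a disease prevalence (the ORs are the estimand;
prevalence is unidentifiable from case-control data). Sample ORs estimated
from simulated cohorts therefore converge to (or_het, or_hom) as n grows.

Multiple SNPs are simulated independently (no linkage disequilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CohortPair, GenotypeCounts, SNPInfo, SubjectRecord

__all__ = [
    "SimulationConfig",
    "control_genotype_distribution",
    "case_genotype_distribution",
    "simulate_cohort_pair",
    "simulate_replicates",
    "materialize_subjects",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated SNP.

    ``or_het`` and ``or_hom`` are the het-vs-ref-hom and alt-hom-vs-ref-hom
    odds ratios (the two additive-model contrasts); both equal to 1 gives the
    null model where cases and controls share the HWE distribution.
    """

    snp: SNPInfo
    control_alt_freq: float
    or_het: float = 1.0
    or_hom: float = 1.0
    n_cases: int = 210
    n_controls: int = 210
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.control_alt_freq < 1:
            raise ValueError("control_alt_freq must be in (0,1)")
        if self.or_het <= 0 or self.or_hom <= 0:
            raise ValueError("odds ratios must be positive")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be >= 1")


def control_genotype_distribution(config: SimulationConfig) -> np.ndarray:
    """HWE genotype probabilities (ref-hom, het, alt-hom) in controls."""
    q = config.control_alt_freq
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


def case_genotype_distribution(config: SimulationConfig) -> np.ndarray:
    """Case genotype probabilities under the exposure-odds construction."""
    tilted = control_genotype_distribution(config) * np.array(
        [1.0, config.or_het, config.or_hom]
    )
    return tilted / tilted.sum()


def simulate_cohort_pair(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> CohortPair:
    """Draw one case/control cohort pair (bit-reproducible for a fixed seed)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    controls = rng.multinomial(config.n_controls, control_genotype_distribution(config))
    cases = rng.multinomial(config.n_cases, case_genotype_distribution(config))
    return CohortPair(
        snp=config.snp,
        cases=GenotypeCounts(*(int(x) for x in cases)),
        controls=GenotypeCounts(*(int(x) for x in controls)),
    )


def simulate_replicates(
    config: SimulationConfig, n_replicates: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised replicate draws for calibration studies.

    Returns ``(cases, controls)`` integer arrays of shape
    ``(n_replicates, 3)`` with columns (ref-hom, het, alt-hom).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    controls = rng.multinomial(
        config.n_controls, control_genotype_distribution(config), size=n_replicates
    )
    cases = rng.multinomial(
        config.n_cases, case_genotype_distribution(config), size=n_replicates
    )
    return cases, controls


def materialize_subjects(pair: CohortPair) -> list[SubjectRecord]:
    """Expand a cohort pair into per-subject records with deterministic IDs."""
    snp = pair.snp
    genotypes = (snp.ref_hom, snp.het, snp.alt_hom)
    records: list[SubjectRecord] = []
    for phenotype, counts, tag in (
        ("case", pair.cases, "CASE"),
        ("control", pair.controls, "CTRL"),
    ):
        i = 0
        for genotype, count in zip(genotypes, counts.as_tuple()):
            for _ in range(count):
                i += 1
                records.append(
                    SubjectRecord(
                        subject_id=f"{tag}{i:05d}",
                        phenotype=phenotype,
                        snp_id=snp.snp_id,
                        genotype=(genotype[0], genotype[1]),
                    )
                )
    return records
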