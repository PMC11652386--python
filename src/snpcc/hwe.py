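"""Hardy-Weinberg equilibrium testing per cohort.

The test is the classical 1-df chi-squared goodness of fit of the observed
genotype counts against the (p^2, 2pq, q^2) expectation, with the allele
frequency estimated from the same data (hence one degree of freedom, not two)
and no continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .io import GenotypeCounts

__all__ = ["HweResult", "allele_frequency", "expected_genotype_counts", "hwe_chi_square"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HweResult:
    """Outcome of the HWE goodness-of-fit test on one cohort."""

    allele_freq_ref: float
    expected: tuple[float, float, float]
    chi2: float
    p_value: float
    df: int = 1
    monomorphic: bool = False


def allele_frequency(counts: GenotypeCounts) -> tuple[float, float]:
    """Return (ref, alt) allele frequencies from genotype counts."""
    freq_ref = counts.ref_alleles / (2 * counts.n)
    return freq_ref, 1.0 - freq_ref


def expected_genotype_counts(counts: GenotypeCounts) -> tuple[float, float, float]:
    """HWE-expected (ref-hom, het, alt-hom) counts at the observed allele frequency."""
    p, q = allele_frequency(counts)
    n = counts.n
    return (p * p * n, 2 * p * q * n, q * q * n)


def hwe_chi_square(counts: GenotypeCounts) -> HweResult:
    """1-df chi-squared HWE goodness-of-fit test.

    A monomorphic cohort (only one allele observed) cannot deviate from HWE;
    it yields the degenerate result chi2 = 0, p = 1 with ``monomorphic=True``
    rather than raising, so batch analyses of simulated cohorts do not abort.
    """
    p, q = allele_frequency(counts)
    if p == 0.0 or q == 0.0:
        logger.warning("monomorphic cohort (ref allele frequency %.0f): HWE test degenerate", p)
        expected = expected_genotype_counts(counts)
        return HweResult(p, expected, chi2=0.0, p_value=1.0, monomorphic=True)
    expected = expected_genotype_counts(counts)
    chi2 = sum(
        (obs - exp) ** 2 / exp for obs, exp in zip(counts.as_tuple(), expected)
    )
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(p, expected, chi2=float(chi2), p_value=p_value)
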