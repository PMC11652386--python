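import numpy as np
import pytest
from hypothesis import settings

from snpcc import CohortPair, GenotypeCounts, SNPInfo, load_scz_counts

settings.register_profile("ci", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scz_pairs() -> dict[str, CohortPair]:
    """The bundled schizophrenia study keyed by rsID."""
    return {pair.snp.snp_id: pair for pair in load_scz_counts()}


@pytest.fixture()
def toy_snp() -> SNPInfo:
    return SNPInfo("rs0000001", "GENE1", "G", "A")


@pytest.fixture()
def toy_pair(toy_snp) -> CohortPair:
    return CohortPair(
        snp=toy_snp,
        cases=GenotypeCounts(10, 5, 3),
        controls=GenotypeCounts(7, 6, 2),
    )


def wald_log_or(a, b, c, d):
    """Independent vectorised Wald machinery used as an oracle in tests."""
    from scipy import stats

    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    lo = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2 * stats.norm.sf(np.abs(lo / se))
    return lo, se, p
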