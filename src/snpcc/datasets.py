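"""Bundled example data.

The package ships the genotype counts of a published candidate-gene
schizophrenia case-control study (210 cases, 210 controls, Bangladeshi
cohort) at three SNPs: NOTCH4 rs2071287 (G/A), NOTCH4 rs204993 (T/C) and
CYP2E1 rs2070673 (A/T), together with the study's displayed analysis results
for self-testing.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .io import CohortPair, read_counts_table

__all__ = ["load_scz_counts", "load_scz_expected", "scz_counts_path"]

_COUNTS = "scz_notch4_cyp2e1_counts.tsv"
_EXPECTED = "scz_notch4_cyp2e1_expected.json"


def scz_counts_path() -> Path:
    """Filesystem path of the bundled counts TSV."""
    return Path(str(resources.files("snpcc").joinpath("data", _COUNTS)))


def load_scz_counts() -> list[CohortPair]:
    """The bundled study as validated cohort pairs."""
    return read_counts_table(scz_counts_path())


def load_scz_expected() -> dict:
    """Displayed analysis values of the bundled study, for self-testing."""
    text = resources.files("snpcc").joinpath("data", _EXPECTED).read_text()
    return json.loads(text)
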