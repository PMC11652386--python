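"""Genetic inheritance models: recoding genotype counts into 2x2 contrasts.

A biallelic case-control SNP gives a 3x2 genotype-by-phenotype table. Each
inheritance model collapses (or restricts) it to a 2x2 contrast of an
"exposed" category against a baseline:

========== ============================= =============================
model       exposed                       baseline
========== ============================= =============================
additive1   het                           ref-hom
additive2   alt-hom                       ref-hom
dominant    het + alt-hom                 ref-hom
recessive   alt-hom                       ref-hom + het
overdominant het                          ref-hom + alt-hom
allelic     alt alleles (2n scale)        ref alleles (2n scale)
========== ============================= =============================

The two additive models *drop* the unused genotype class entirely (their
column totals shrink below the cohort size); they are restrictions, not
recodings. The baseline is always the reference-allele category, even when
the reference allele is the rarer one, so odds ratios keep the orientation
of the input data.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .io import CohortPair

__all__ = ["ModelKind", "TwoByTwoTable", "build_model_table", "build_all_models"]


class ModelKind(str, Enum):
    """The six contrasts, in canonical report order."""

    additive1 = "additive1"
    additive2 = "additive2"
    dominant = "dominant"
    recessive = "recessive"
    overdominant = "overdominant"
    allelic = "allelic"

    def describe(self, ref: str, alt: str) -> str:
        """Human-readable contrast label, e.g. ``"AG vs. GG"``."""
        ref_hom, het, alt_hom = ref * 2, ref + alt, alt * 2
        return {
            ModelKind.additive1: f"{het} vs. {ref_hom}",
            ModelKind.additive2: f"{alt_hom} vs. {ref_hom}",
            ModelKind.dominant: f"{het} + {alt_hom} vs. {ref_hom}",
            ModelKind.recessive: f"{alt_hom} vs. {ref_hom} + {het}",
            ModelKind.overdominant: f"{het} vs. {ref_hom} + {alt_hom}",
            ModelKind.allelic: f"{alt} vs. {ref}",
        }[self]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Labeled 2x2 contingency table: (a, b) cases, (c, d) controls.

    ``a``/``c`` are the exposed (variant-carrying) cells, ``b``/``d`` the
    baseline cells. Cells are floats so a continuity-corrected table can be
    represented; raw tables always carry integers.
    """

    model: ModelKind
    a: float
    b: float
    c: float
    d: float
    exposed_label: str
    baseline_label: str

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def has_zero_cell(self) -> bool:
        return 0 in self.cells()


def build_model_table(pair: CohortPair, model: ModelKind) -> TwoByTwoTable:
    """Construct the 2x2 table of one inheritance model from a cohort pair."""
    snp, cases, controls = pair.snp, pair.cases, pair.controls
    ref_hom, het, alt_hom = snp.ref_hom, snp.het, snp.alt_hom
    if model is ModelKind.additive1:
        cells = (cases.n_het, cases.n_ref_hom, controls.n_het, controls.n_ref_hom)
        labels = (het, ref_hom)
    elif model is ModelKind.additive2:
        cells = (cases.n_alt_hom, cases.n_ref_hom, controls.n_alt_hom, controls.n_ref_hom)
        labels = (alt_hom, ref_hom)
    elif model is ModelKind.dominant:
        cells = (
            cases.n_het + cases.n_alt_hom,
            cases.n_ref_hom,
            controls.n_het + controls.n_alt_hom,
            controls.n_ref_hom,
        )
        labels = (f"{het} + {alt_hom}", ref_hom)
    elif model is ModelKind.recessive:
        cells = (
            cases.n_alt_hom,
            cases.n_ref_hom + cases.n_het,
            controls.n_alt_hom,
            controls.n_ref_hom + controls.n_het,
        )
        labels = (alt_hom, f"{ref_hom} + {het}")
    elif model is ModelKind.overdominant:
        cells = (
            cases.n_het,
            cases.n_ref_hom + cases.n_alt_hom,
            controls.n_het,
            controls.n_ref_hom + controls.n_alt_hom,
        )
        labels = (het, f"{ref_hom} + {alt_hom}")
    elif model is ModelKind.allelic:
        cells = (
            cases.alt_alleles,
            cases.ref_alleles,
            controls.alt_alleles,
            controls.ref_alleles,
        )
        labels = (snp.alt_allele, snp.ref_allele)
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown model {model!r}")
    return TwoByTwoTable(model, *cells, exposed_label=labels[0], baseline_label=labels[1])


def build_all_models(pair: CohortPair) -> list[TwoByTwoTable]:
    """All six model tables in canonical order."""
    return [build_model_table(pair, model) for model in ModelKind]
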