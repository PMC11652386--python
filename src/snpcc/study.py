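"""End-to-end study driver in the model/results idiom.

:class:`SNPAssociationStudy` is the model object: it is built from genotype
count data (a counts TSV, a long-format subjects file, simulated cohorts or
in-memory :class:`~snpcc.io.CohortPair` objects) plus a :class:`StudyConfig`.
Its :meth:`~SNPAssociationStudy.fit` runs the full analysis sequence for every
SNP — HWE per cohort, the six genetic-model contrasts, odds-ratio estimation,
and the FPRP/BFDP noteworthiness screens — and returns a
:class:`StudyResults` carrying estimates, intervals, diagnostics, a
``summary()`` table and TSV/JSON writers.

The fit is a pure function of (input data, config): identical inputs produce
byte-identical reports. No multiple-testing adjustment is applied across the
model tests; the report footer states this.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .association import AssociationResult, odds_ratio_test
from .datasets import load_scz_counts, load_scz_expected
from .hwe import HweResult, hwe_chi_square
from .io import (
    CohortPair,
    CountsFormatError,
    SNPInfo,
    SubjectRecord,
    aggregate_subjects,
    read_counts_table,
    read_subjects,
)
from .models import ModelKind, build_all_models
from .noteworthiness import NoteworthinessConfig, NoteworthinessResult, evaluate

__all__ = [
    "StudyConfig",
    "SNPAssociationStudy",
    "SNPResults",
    "StudyResults",
    "SelfTestReport",
    "self_test",
]

logger = logging.getLogger(__name__)

#: Display rounding: OR/CI decimals, p decimals, HWE chi2 decimals, HWE/FPRP p decimals.
_ROUND_OR = 2
_ROUND_P = 4
_ROUND_CHI2 = 2
_ROUND_PROB = 3


@dataclass(frozen=True)
class StudyConfig:
    """Analysis settings: CI level, noteworthiness screen, HWE warning level."""

    confidence: float = 0.95
    noteworthiness: NoteworthinessConfig = field(default_factory=NoteworthinessConfig)
    hwe_warn_p: float = 0.05
    significance_level: float = 0.05  # p <= level flags significance

    def __post_init__(self) -> None:
        if not 0.5 < self.confidence < 1:
            raise ValueError("confidence must be in (0.5, 1)")


@dataclass(frozen=True)
class SNPResults:
    """Everything computed for one SNP."""

    pair: CohortPair
    hwe_cases: HweResult
    hwe_controls: HweResult
    associations: tuple[AssociationResult, ...]
    noteworthiness: tuple[NoteworthinessResult, ...]

    def association(self, model: ModelKind) -> AssociationResult:
        return next(r for r in self.associations if r.model is model)

    def noteworthy(self, model: ModelKind) -> NoteworthinessResult:
        return next(r for r in self.noteworthiness if r.model is model)


class SNPAssociationStudy:
    """Case-control single-SNP association model for one or more SNPs.

    Parameters
    ----------
    pairs
        Validated case/control genotype counts, one per SNP.
    config
        Analysis settings; defaults reproduce the conventional candidate-gene
        screen (95% CI, target OR 1.5, FPRP priors 0.25...1e-4).

    Examples
    --------
    >>> from snpcc import SNPAssociationStudy
    >>> study = SNPAssociationStudy.from_example()
    >>> results = study.fit()
    >>> results.association_frame().shape
    (18, 12)
    """

    def __init__(
        self,
        pairs: Sequence[CohortPair],
        config: StudyConfig | None = None,
        *,
        provenance: dict | None = None,
    ) -> None:
        if not pairs:
            raise CountsFormatError("study requires at least one SNP")
        self.pairs = list(pairs)
        self.config = config or StudyConfig()
        self._provenance = dict(provenance or {})

    # ---------------------------------------------------------------- builders
    @classmethod
    def from_counts_table(
        cls, path: str | Path, config: StudyConfig | None = None
    ) -> "SNPAssociationStudy":
        """Build from a genotype-counts TSV."""
        path = Path(path)
        pairs = read_counts_table(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        return cls(pairs, config, provenance={"input": str(path), "input_sha256": digest})

    @classmethod
    def from_subjects(
        cls,
        path_or_records: str | Path | Sequence[SubjectRecord],
        snps: Sequence[SNPInfo],
        config: StudyConfig | None = None,
    ) -> "SNPAssociationStudy":
        """Build from per-subject long-format genotype calls."""
        if isinstance(path_or_records, (str, Path)):
            records = read_subjects(path_or_records)
            provenance = {"input": str(path_or_records)}
        else:
            records = list(path_or_records)
            provenance = {"input": "<records>"}
        return cls(aggregate_subjects(records, snps), config, provenance=provenance)

    @classmethod
    def from_example(cls, config: StudyConfig | None = None) -> "SNPAssociationStudy":
        """Build from the bundled schizophrenia case-control dataset."""
        return cls(load_scz_counts(), config, provenance={"input": "<bundled scz dataset>"})

    # -------------------------------------------------------------------- fit
    def fit(self) -> "StudyResults":
        """Run HWE, association and noteworthiness for every SNP."""
        per_snp: dict[str, SNPResults] = {}
        for pair in self.pairs:
            snp_id = pair.snp.snp_id
            hwe_cases = hwe_chi_square(pair.cases)
            hwe_controls = hwe_chi_square(pair.controls)
            for label, result in (("cases", hwe_cases), ("controls", hwe_controls)):
                if result.p_value < self.config.hwe_warn_p:
                    logger.warning(
                        "%s: %s deviate from HWE (p = %.4g)", snp_id, label, result.p_value
                    )
            associations = tuple(
                odds_ratio_test(table, self.config.confidence)
                for table in build_all_models(pair)
            )
            noteworthiness = tuple(
                evaluate(assoc, self.config.noteworthiness) for assoc in associations
            )
            per_snp[snp_id] = SNPResults(
                pair, hwe_cases, hwe_controls, associations, noteworthiness
            )
            logger.info("%s: analysed (6 models)", snp_id)
        provenance = {
            "tool": "snpcc",
            "version": __version__,
            "n_snps": len(per_snp),
            **self._provenance,
            "config": {
                "confidence": self.config.confidence,
                "or_threshold": self.config.noteworthiness.or_threshold,
                "fprp_priors": list(self.config.noteworthiness.priors),
                "bfdp_priors": list(self.config.noteworthiness.bfdp_priors),
                "fprp_noteworthy_cutoff": self.config.noteworthiness.fprp_noteworthy_cutoff,
                "bfdp_noteworthy_cutoff": self.config.noteworthiness.bfdp_noteworthy_cutoff,
                "hwe_warn_p": self.config.hwe_warn_p,
                "significance_level": self.config.significance_level,
            },
        }
        return StudyResults(per_snp, self.config, provenance)


class StudyResults:
    """Fitted results of a :class:`SNPAssociationStudy`.

    Full-precision values live in the frames and in ``to_json``; ``summary()``
    and ``to_tsv`` apply the display rounding policy (OR/CI to 2 decimals,
    association p to 4, HWE chi2 to 2, probabilities to 3).
    """

    def __init__(
        self, snps: dict[str, SNPResults], config: StudyConfig, provenance: dict
    ) -> None:
        self.snps = snps
        self.config = config
        self.provenance = provenance

    # ------------------------------------------------------------------ frames
    def hwe_frame(self) -> pd.DataFrame:
        rows = []
        for snp_id, res in self.snps.items():
            for cohort, hwe in (("cases", res.hwe_cases), ("controls", res.hwe_controls)):
                rows.append(
                    {
                        "snp_id": snp_id,
                        "gene": res.pair.snp.gene,
                        "cohort": cohort,
                        "n": (res.pair.cases if cohort == "cases" else res.pair.controls).n,
                        "freq_ref": hwe.allele_freq_ref,
                        "chi2": hwe.chi2,
                        "p_value": hwe.p_value,
                        "monomorphic": hwe.monomorphic,
                    }
                )
        return pd.DataFrame(rows)

    def association_frame(self) -> pd.DataFrame:
        rows = []
        for snp_id, res in self.snps.items():
            for table, assoc in zip(
                (build_all_models(res.pair)), res.associations
            ):
                rows.append(
                    {
                        "snp_id": snp_id,
                        "model": assoc.model.value,
                        "contrast": assoc.model.describe(
                            res.pair.snp.ref_allele, res.pair.snp.alt_allele
                        ),
                        "a": table.a,
                        "b": table.b,
                        "c": table.c,
                        "d": table.d,
                        "or": assoc.or_estimate,
                        "ci_low": assoc.ci_low,
                        "ci_high": assoc.ci_high,
                        "p_value": assoc.p_value,
                        "significant": assoc.p_value <= self.config.significance_level,
                    }
                )
        return pd.DataFrame(rows)

    def noteworthiness_frame(self) -> pd.DataFrame:
        rows = []
        for snp_id, res in self.snps.items():
            for note in res.noteworthiness:
                row = {
                    "snp_id": snp_id,
                    "model": note.model.value,
                    "power": note.power,
                    "abf": note.abf,
                }
                for prior, value in note.fprp_by_prior.items():
                    row[f"fprp_{prior:g}"] = value
                for prior, flag in note.noteworthy_fprp.items():
                    row[f"fprp_noteworthy_{prior:g}"] = flag
                for prior, value in note.bfdp_by_prior.items():
                    row[f"bfdp_{prior:g}"] = value
                for prior, flag in note.noteworthy_bfdp.items():
                    row[f"bfdp_noteworthy_{prior:g}"] = flag
                rows.append(row)
        return pd.DataFrame(rows)

    # ----------------------------------------------------------------- display
    def summary(self) -> str:
        """Human-readable report mirroring the three study tables."""
        lines: list[str] = []
        lines.append("Case-control SNP association study")
        lines.append("=" * 70)
        lines.append(f"SNPs analysed: {len(self.snps)}; CI level: {self.config.confidence:.0%}")
        lines.append("")
        hwe = self.hwe_frame().copy()
        hwe["freq_ref"] = hwe["freq_ref"].round(4)
        hwe["chi2"] = hwe["chi2"].round(_ROUND_CHI2)
        hwe["p_value"] = hwe["p_value"].round(_ROUND_PROB)
        lines.append("Hardy-Weinberg equilibrium (1-df chi-squared, per cohort)")
        lines.append(hwe.drop(columns="monomorphic").to_string(index=False))
        lines.append("")
        assoc = self.association_frame().copy()
        for col in ("or", "ci_low", "ci_high"):
            assoc[col] = assoc[col].round(_ROUND_OR)
        assoc["p_value"] = assoc["p_value"].round(_ROUND_P)
        lines.append("Association (crude OR, Woolf CI, two-sided Wald z-test)")
        lines.append(assoc.to_string(index=False))
        lines.append("")
        note = self.noteworthiness_frame().copy()
        for col in note.columns:
            if col.startswith(("power", "fprp_0", "bfdp_0", "abf")):
                note[col] = note[col].round(_ROUND_PROB)
        keep = [c for c in note.columns if not c.startswith(("fprp_noteworthy", "bfdp_noteworthy"))]
        lines.append(
            f"Noteworthiness screen (target OR {self.config.noteworthiness.or_threshold}; "
            "power at exact observed p; FPRP per prior; Wakefield ABF / BFDP per prior)"
        )
        lines.append(note[keep].to_string(index=False))
        lines.append("")
        lines.append(
            "Note: no multiple-testing adjustment is applied across the model tests; "
            f"significance flags use p <= {self.config.significance_level}."
        )
        return "\n".join(lines)

    # --------------------------------------------------------------- serialise
    def to_dict(self) -> dict:
        """Full-precision nested representation (JSON-compatible)."""
        return {
            "provenance": self.provenance,
            "hwe": self.hwe_frame().to_dict(orient="records"),
            "association": self.association_frame().to_dict(orient="records"),
            "noteworthiness": self.noteworthiness_frame().to_dict(orient="records"),
        }

    def to_json(self, path: str | Path) -> None:
        """Write the full-precision report (lossless round-trip)."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_tsv(self, path: str | Path) -> None:
        """Write a display-rounded TSV report (one block per study table)."""
        hwe = self.hwe_frame().copy()
        hwe["chi2"] = hwe["chi2"].round(_ROUND_CHI2)
        hwe["p_value"] = hwe["p_value"].round(_ROUND_PROB)
        hwe["freq_ref"] = hwe["freq_ref"].round(4)
        assoc = self.association_frame().copy()
        for col in ("or", "ci_low", "ci_high"):
            assoc[col] = assoc[col].round(_ROUND_OR)
        assoc["p_value"] = assoc["p_value"].round(_ROUND_P)
        note = self.noteworthiness_frame().copy()
        for col in note.columns:
            if col.startswith(("power", "fprp_0", "bfdp_0", "abf")):
                note[col] = note[col].round(_ROUND_PROB)
        with open(path, "w") as fh:
            for name, frame in (("hwe", hwe), ("association", assoc), ("noteworthiness", note)):
                fh.write(f"# {name}\n")
                frame.to_csv(fh, sep="\t", index=False)
                fh.write("\n")
            fh.write(
                "# note: no multiple-testing adjustment applied across model tests\n"
            )


# -------------------------------------------------------------------- self-test
@dataclass
class SelfTestReport:
    """Per-cell comparison of the bundled dataset's fit against its published values."""

    rows: list[dict]

    @property
    def passed(self) -> bool:
        return all(row["status"] != "fail" for row in self.rows)

    @property
    def n_failed(self) -> int:
        return sum(row["status"] == "fail" for row in self.rows)

    def __str__(self) -> str:
        frame = pd.DataFrame(self.rows)
        tally = (
            f"{sum(r['status'] == 'pass' for r in self.rows)} pass, "
            f"{self.n_failed} fail, "
            f"{sum(r['status'] == 'info' for r in self.rows)} informational"
        )
        return frame.to_string(index=False) + "\n" + tally


def self_test(results: StudyResults | None = None) -> SelfTestReport:
    """Re-analyse the bundled dataset and diff against its published values.

    HWE, OR/CI/p and the published FPRP noteworthy pattern (0.5 screen) are
    pass/fail at the stated tolerances. BFDP cells are reported as
    informational only: the published BFDP columns follow an unstated
    spreadsheet convention that the standard Wakefield ABF does not reproduce.
    """
    expected = load_scz_expected()
    tol = expected["tolerances"]
    if results is None:
        config = StudyConfig(noteworthiness=NoteworthinessConfig.published_screen())
        results = SNPAssociationStudy.from_example(config).fit()
    rows: list[dict] = []

    def check(snp, section, cell, exp, act, tolerance):
        status = "pass" if abs(act - exp) <= tolerance else "fail"
        rows.append(
            {"snp": snp, "section": section, "cell": cell, "expected": exp,
             "actual": round(act, 6), "status": status}
        )

    for snp_id, spec in expected["snps"].items():
        res = results.snps[snp_id]
        for cohort, hwe_res in (("cases", res.hwe_cases), ("controls", res.hwe_controls)):
            exp_chi2, exp_p = spec["hwe"][cohort]
            check(snp_id, "hwe", f"{cohort} chi2", exp_chi2, hwe_res.chi2, tol["hwe_chi2"])
            check(snp_id, "hwe", f"{cohort} p", exp_p, hwe_res.p_value, tol["hwe_p"])
        for model_name, (exp_or, exp_lo, exp_hi, exp_p) in spec["association"].items():
            assoc = res.association(ModelKind(model_name))
            check(snp_id, "association", f"{model_name} OR", exp_or, assoc.or_estimate, tol["or"])
            check(snp_id, "association", f"{model_name} CI low", exp_lo, assoc.ci_low, tol["ci"])
            check(snp_id, "association", f"{model_name} CI high", exp_hi, assoc.ci_high, tol["ci"])
            check(snp_id, "association", f"{model_name} p", exp_p, assoc.p_value, tol["p"])
        for model_name, flags in spec["fprp_noteworthy"].items():
            note = res.noteworthy(ModelKind(model_name))
            actual_flags = [note.noteworthy_fprp[0.25], note.noteworthy_fprp[0.1]]
            rows.append(
                {"snp": snp_id, "section": "fprp flags", "cell": model_name,
                 "expected": flags, "actual": actual_flags,
                 "status": "pass" if flags == actual_flags else "fail"}
            )
    anchors = expected["noteworthiness_anchors"]
    for snp_id, models in anchors.items():
        res = results.snps[snp_id]
        for model_name, cells in models.items():
            note = res.noteworthy(ModelKind(model_name))
            if "power" in cells:
                check(snp_id, "noteworthiness", f"{model_name} power (3dp)",
                      cells["power"], round(note.power, 3), 0.0)
            for key, exp in cells.items():
                if key.startswith("fprp_prior_"):
                    prior = float(key.removeprefix("fprp_prior_"))
                    check(snp_id, "noteworthiness", f"{model_name} FPRP@{prior:g} (3dp)",
                          exp, round(note.fprp_by_prior[prior], 3), 0.0)
    # BFDP: informational only (convention-divergent in the published source)
    for snp_id, res in results.snps.items():
        for note in res.noteworthiness:
            rows.append(
                {"snp": snp_id, "section": "bfdp", "cell": note.model.value,
                 "expected": "convention-divergent",
                 "actual": {f"{p:g}": round(v, 3) for p, v in note.bfdp_by_prior.items()},
                 "status": "info"}
            )
    return SelfTestReport(rows)
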