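"""Reading, validation and aggregation of biallelic genotype data.

Two on-disk layouts are supported:

* a **counts table** (TSV): one row per SNP with the six genotype counts of a
  case cohort and a control cohort, plus allele orientation;
* a **subjects file** (CSV/TSV): one row per subject per SNP in long format,
  which :func:`aggregate_subjects` collapses into the same count tables.

All downstream statistics operate on :class:`CohortPair` objects produced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SNPInfo",
    "GenotypeCounts",
    "CohortPair",
    "SubjectRecord",
    "CountsFormatError",
    "GenotypeValidationError",
    "COUNTS_COLUMNS",
    "read_counts_table",
    "write_counts_table",
    "read_subjects",
    "aggregate_subjects",
]

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")

#: Mandatory column order of the counts TSV dialect.
COUNTS_COLUMNS = (
    "snp_id",
    "gene",
    "ref_allele",
    "alt_allele",
    "case_ref_hom",
    "case_het",
    "case_alt_hom",
    "ctrl_ref_hom",
    "ctrl_het",
    "ctrl_alt_hom",
)


class CountsFormatError(ValueError):
    """A genotype data file does not conform to the expected layout."""


class GenotypeValidationError(ValueError):
    """Genotype data are structurally well-formed but semantically invalid."""


@dataclass(frozen=True)
class SNPInfo:
    """Identity and allele orientation of one biallelic SNP.

    The reference allele is the baseline of every genetic-model contrast
    (the first-listed homozygote in report tables); it need not be the more
    frequent allele in either cohort.
    """

    snp_id: str
    gene: str
    ref_allele: str
    alt_allele: str
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise GenotypeValidationError("snp_id must be non-empty")
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in _VALID_ALLELES:
                raise GenotypeValidationError(
                    f"{self.snp_id}: allele {allele!r} is not one of A/C/G/T"
                )
        if self.ref_allele == self.alt_allele:
            raise GenotypeValidationError(
                f"{self.snp_id}: ref and alt alleles must differ"
            )

    @property
    def ref_hom(self) -> str:
        return self.ref_allele * 2

    @property
    def het(self) -> str:
        return self.ref_allele + self.alt_allele

    @property
    def alt_hom(self) -> str:
        return self.alt_allele * 2


@dataclass(frozen=True)
class GenotypeCounts:
    """The three genotype counts of one cohort at one biallelic SNP."""

    n_ref_hom: int
    n_het: int
    n_alt_hom: int

    def __post_init__(self) -> None:
        for name in ("n_ref_hom", "n_het", "n_alt_hom"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise GenotypeValidationError(f"{name}={value!r} is not an integer")
            if value < 0:
                raise GenotypeValidationError(f"{name}={value} is negative")
        if self.n == 0:
            raise GenotypeValidationError("cohort has zero subjects")

    @property
    def n(self) -> int:
        """Number of genotyped subjects."""
        return self.n_ref_hom + self.n_het + self.n_alt_hom

    @property
    def ref_alleles(self) -> int:
        return 2 * self.n_ref_hom + self.n_het

    @property
    def alt_alleles(self) -> int:
        return 2 * self.n_alt_hom + self.n_het

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_ref_hom, self.n_het, self.n_alt_hom)


@dataclass(frozen=True)
class CohortPair:
    """Case and control genotype counts for one SNP, sharing one orientation."""

    snp: SNPInfo
    cases: GenotypeCounts
    controls: GenotypeCounts


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's genotype call at one SNP (unphased; A/G ≡ G/A)."""

    subject_id: str
    phenotype: str  # "case" | "control"
    snp_id: str
    genotype: tuple[str, str] | None  # None = missing call

    def __post_init__(self) -> None:
        if self.phenotype not in ("case", "control"):
            raise GenotypeValidationError(
                f"subject {self.subject_id}: phenotype must be 'case' or 'control', "
                f"got {self.phenotype!r}"
            )
        if self.genotype is not None:
            a, b = self.genotype
            object.__setattr__(self, "genotype", tuple(sorted((a.upper(), b.upper()))))

    @classmethod
    def from_strings(
        cls, subject_id: str, phenotype: str, snp_id: str, genotype: str
    ) -> "SubjectRecord":
        """Build a record from a genotype string such as ``"A/G"`` ("" = missing)."""
        gt: tuple[str, str] | None
        if genotype in ("", ".", "./.", "NA"):
            gt = None
        else:
            parts = genotype.split("/")
            if len(parts) != 2 or not all(parts):
                raise GenotypeValidationError(
                    f"subject {subject_id}: malformed genotype {genotype!r}"
                )
            gt = (parts[0], parts[1])
        return cls(subject_id, phenotype, snp_id, gt)


def _validate_count_cell(value: object, snp_id: str, column: str) -> int:
    try:
        as_float = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise GenotypeValidationError(
            f"{snp_id}: count {column}={value!r} is not numeric"
        ) from None
    if as_float != int(as_float):
        raise GenotypeValidationError(
            f"{snp_id}: count {column}={value!r} is not an integer"
        )
    as_int = int(as_float)
    if as_int < 0:
        raise GenotypeValidationError(f"{snp_id}: count {column}={as_int} is negative")
    return as_int


def read_counts_table(path: str | Path) -> list[CohortPair]:
    """Parse a counts TSV into validated :class:`CohortPair` objects.

    Raises
    ------
    CountsFormatError
        If a mandatory column is missing or the file is empty.
    GenotypeValidationError
        On negative/non-integer counts, duplicate SNP ids, or empty cohorts.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise CountsFormatError(f"{path}: file is empty") from None
    missing = [c for c in COUNTS_COLUMNS if c not in frame.columns]
    if missing:
        raise CountsFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if frame.empty:
        raise CountsFormatError(f"{path}: no data rows")

    pairs: list[CohortPair] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        snp_id = str(row["snp_id"])
        if snp_id in seen:
            raise GenotypeValidationError(f"duplicate snp_id {snp_id!r}")
        seen.add(snp_id)
        snp = SNPInfo(
            snp_id=snp_id,
            gene=str(row["gene"]),
            ref_allele=str(row["ref_allele"]),
            alt_allele=str(row["alt_allele"]),
        )
        cells = {
            col: _validate_count_cell(row[col], snp_id, col)
            for col in COUNTS_COLUMNS[4:]
        }
        try:
            cases = GenotypeCounts(
                cells["case_ref_hom"], cells["case_het"], cells["case_alt_hom"]
            )
            controls = GenotypeCounts(
                cells["ctrl_ref_hom"], cells["ctrl_het"], cells["ctrl_alt_hom"]
            )
        except GenotypeValidationError as exc:
            raise GenotypeValidationError(f"{snp_id}: {exc}") from None
        pairs.append(CohortPair(snp=snp, cases=cases, controls=controls))
    return pairs


def write_counts_table(pairs: Sequence[CohortPair], path: str | Path) -> None:
    """Serialize cohort pairs back to the counts TSV dialect (lossless)."""
    rows = []
    for pair in pairs:
        rows.append(
            {
                "snp_id": pair.snp.snp_id,
                "gene": pair.snp.gene,
                "ref_allele": pair.snp.ref_allele,
                "alt_allele": pair.snp.alt_allele,
                "case_ref_hom": pair.cases.n_ref_hom,
                "case_het": pair.cases.n_het,
                "case_alt_hom": pair.cases.n_alt_hom,
                "ctrl_ref_hom": pair.controls.n_ref_hom,
                "ctrl_het": pair.controls.n_het,
                "ctrl_alt_hom": pair.controls.n_alt_hom,
            }
        )
    pd.DataFrame(rows, columns=list(COUNTS_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    """Read a long-format subjects file (TSV or CSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        raise CountsFormatError(f"{path}: file is empty") from None
    required = ("subject_id", "phenotype", "snp_id", "genotype")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise CountsFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return [
        SubjectRecord.from_strings(
            row["subject_id"], row["phenotype"], row["snp_id"], row["genotype"]
        )
        for _, row in frame.iterrows()
    ]


def aggregate_subjects(
    records: Iterable[SubjectRecord], snps: Sequence[SNPInfo]
) -> list[CohortPair]:
    """Tally per-subject genotype calls into per-SNP case/control count tables.

    Subjects with a missing call at a SNP are excluded from that SNP only;
    the number excluded is logged. A genotype whose alleles are not the SNP's
    declared ref/alt pair is a hard error naming the subject.
    """
    by_id = {snp.snp_id: snp for snp in snps}
    if len(by_id) != len(snps):
        raise GenotypeValidationError("duplicate snp_id in SNP list")
    # counts[snp_id][phenotype] = [ref_hom, het, alt_hom]
    tallies: dict[str, dict[str, list[int]]] = {
        snp_id: {"case": [0, 0, 0], "control": [0, 0, 0]} for snp_id in by_id
    }
    dropped: dict[str, int] = {snp_id: 0 for snp_id in by_id}
    for rec in records:
        snp = by_id.get(rec.snp_id)
        if snp is None:
            raise GenotypeValidationError(
                f"subject {rec.subject_id}: unknown snp_id {rec.snp_id!r}"
            )
        if rec.genotype is None:
            dropped[rec.snp_id] += 1
            continue
        allowed = {snp.ref_allele, snp.alt_allele}
        if not set(rec.genotype) <= allowed:
            raise GenotypeValidationError(
                f"subject {rec.subject_id}: genotype {'/'.join(rec.genotype)} does not "
                f"match declared alleles {snp.ref_allele}/{snp.alt_allele} of {snp.snp_id}"
            )
        n_alt = sum(allele == snp.alt_allele for allele in rec.genotype)
        tallies[rec.snp_id][rec.phenotype][n_alt] += 1
    for snp_id, n_drop in dropped.items():
        if n_drop:
            logger.info("%s: excluded %d subject(s) with missing genotype", snp_id, n_drop)
    pairs = []
    for snp_id, snp in by_id.items():
        try:
            cases = GenotypeCounts(*tallies[snp_id]["case"])
            controls = GenotypeCounts(*tallies[snp_id]["control"])
        except GenotypeValidationError as exc:
            raise GenotypeValidationError(f"{snp_id}: {exc}") from None
        pairs.append(CohortPair(snp=snp, cases=cases, controls=controls))
    return pairs
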