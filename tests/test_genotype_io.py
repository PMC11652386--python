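"""Parsing, validation, aggregation and round-tripping of genotype data."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from snpcc import (
    CountsFormatError,
    GenotypeCounts,
    GenotypeValidationError,
    SNPInfo,
    SubjectRecord,
    aggregate_subjects,
    read_counts_table,
    read_subjects,
    write_counts_table,
)
from snpcc.datasets import load_scz_counts


class TestBundledDataset:
    """The packaged study must reproduce its published genotype tallies."""

    EXPECTED = {
        "rs2071287": ((81, 96, 33), (83, 100, 27)),
        "rs204993": ((60, 102, 48), (89, 100, 21)),
        "rs2070673": ((46, 115, 49), (31, 94, 85)),
    }

    def test_counts_match_published(self, scz_pairs):
        assert set(scz_pairs) == set(self.EXPECTED)
        for snp_id, (cases, controls) in self.EXPECTED.items():
            pair = scz_pairs[snp_id]
            assert pair.cases.as_tuple() == cases
            assert pair.controls.as_tuple() == controls
            assert pair.cases.n == pair.controls.n == 210

    def test_allele_tallies_match_published(self, scz_pairs):
        # published per-cohort allele counts (ref, alt)
        expected = {
            "rs2071287": ((258, 162), (266, 154)),
            "rs204993": ((222, 198), (278, 142)),
            "rs2070673": ((207, 213), (156, 264)),
        }
        for snp_id, (case_alleles, ctrl_alleles) in expected.items():
            pair = scz_pairs[snp_id]
            assert (pair.cases.ref_alleles, pair.cases.alt_alleles) == case_alleles
            assert (pair.controls.ref_alleles, pair.controls.alt_alleles) == ctrl_alleles


counts_strategy = st.tuples(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
).filter(lambda t: sum(t) > 0)


@given(counts_strategy)
def test_allele_count_conservation(counts):
    gc = GenotypeCounts(*counts)
    assert gc.ref_alleles + gc.alt_alleles == 2 * gc.n


def test_derived_allele_counts():
    assert GenotypeCounts(10, 5, 3).alt_alleles == 2 * 3 + 5


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(snp_id="", gene="G1", ref_allele="A", alt_allele="G"),
        dict(snp_id="rs1", gene="G1", ref_allele="A", alt_allele="A"),
        dict(snp_id="rs1", gene="G1", ref_allele="A", alt_allele="Z"),
    ],
)
def test_snpinfo_rejects_invalid(kwargs):
    with pytest.raises(GenotypeValidationError):
        SNPInfo(**kwargs)


@pytest.mark.parametrize("bad", [(-1, 2, 3), (1.5, 2, 3), (0, 0, 0)])
def test_genotype_counts_rejects_invalid(bad):
    with pytest.raises(GenotypeValidationError):
        GenotypeCounts(*bad)


class TestCountsTable:
    def test_round_trip(self, tmp_path, scz_pairs):
        path = tmp_path / "counts.tsv"
        pairs = list(scz_pairs.values())
        write_counts_table(pairs, path)
        back = read_counts_table(path)
        assert [p.cases.as_tuple() for p in back] == [p.cases.as_tuple() for p in pairs]
        assert [p.controls.as_tuple() for p in back] == [
            p.controls.as_tuple() for p in pairs
        ]
        assert [p.snp.snp_id for p in back] == [p.snp.snp_id for p in pairs]

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("snp_id\tgene\nrs1\tG1\n")
        with pytest.raises(CountsFormatError, match="ref_allele"):
            read_counts_table(path)

    def test_negative_count_names_snp_and_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "snp_id\tgene\tref_allele\talt_allele\tcase_ref_hom\tcase_het\t"
            "case_alt_hom\tctrl_ref_hom\tctrl_het\tctrl_alt_hom\n"
            "rs1\tG1\tG\tA\t-1\t5\t3\t7\t6\t2\n"
        )
        with pytest.raises(GenotypeValidationError, match="rs1.*case_ref_hom"):
            read_counts_table(path)

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "snp_id\tgene\tref_allele\talt_allele\tcase_ref_hom\tcase_het\t"
            "case_alt_hom\tctrl_ref_hom\tctrl_het\tctrl_alt_hom\n"
            "rs1\tG1\tG\tA\t1.5\t5\t3\t7\t6\t2\n"
        )
        with pytest.raises(GenotypeValidationError, match="rs1"):
            read_counts_table(path)

    def test_duplicate_snp_id_rejected(self, tmp_path):
        header = (
            "snp_id\tgene\tref_allele\talt_allele\tcase_ref_hom\tcase_het\t"
            "case_alt_hom\tctrl_ref_hom\tctrl_het\tctrl_alt_hom\n"
        )
        row = "rs1\tG1\tG\tA\t1\t5\t3\t7\t6\t2\n"
        path = tmp_path / "bad.tsv"
        path.write_text(header + row + row)
        with pytest.raises(GenotypeValidationError, match="duplicate"):
            read_counts_table(path)

    def test_empty_cohort_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "snp_id\tgene\tref_allele\talt_allele\tcase_ref_hom\tcase_het\t"
            "case_alt_hom\tctrl_ref_hom\tctrl_het\tctrl_alt_hom\n"
            "rs1\tG1\tG\tA\t0\t0\t0\t7\t6\t2\n"
        )
        with pytest.raises(GenotypeValidationError, match="rs1"):
            read_counts_table(path)

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(CountsFormatError):
            read_counts_table(path)


class TestAggregateSubjects:
    def test_direct_tally(self, toy_snp):
        records = [
            SubjectRecord.from_strings("s1", "case", toy_snp.snp_id, "G/G"),
            SubjectRecord.from_strings("s2", "case", toy_snp.snp_id, "A/G"),
            SubjectRecord.from_strings("s3", "case", toy_snp.snp_id, "G/A"),
            SubjectRecord.from_strings("c1", "control", toy_snp.snp_id, "A/A"),
        ]
        (pair,) = aggregate_subjects(records, [toy_snp])
        assert pair.cases.as_tuple() == (1, 2, 0)
        assert pair.controls.as_tuple() == (0, 0, 1)

    def test_unphased_genotypes_equivalent(self, toy_snp):
        ag = SubjectRecord.from_strings("s", "case", toy_snp.snp_id, "A/G")
        ga = SubjectRecord.from_strings("s", "case", toy_snp.snp_id, "G/A")
        assert ag.genotype == ga.genotype

    def test_allele_mismatch_names_subject(self, toy_snp):
        records = [SubjectRecord.from_strings("s9", "case", toy_snp.snp_id, "T/C")]
        with pytest.raises(GenotypeValidationError, match="s9"):
            aggregate_subjects(records, [toy_snp])

    def test_unknown_snp_id_rejected(self, toy_snp):
        records = [SubjectRecord.from_strings("s1", "case", "rsUNKNOWN", "A/G")]
        with pytest.raises(GenotypeValidationError, match="rsUNKNOWN"):
            aggregate_subjects(records, [toy_snp])

    def test_missing_genotypes_dropped_per_snp(self, toy_snp):
        records = [
            SubjectRecord.from_strings("s1", "case", toy_snp.snp_id, "G/G"),
            SubjectRecord.from_strings("s2", "case", toy_snp.snp_id, ""),
            SubjectRecord.from_strings("c1", "control", toy_snp.snp_id, "A/A"),
        ]
        (pair,) = aggregate_subjects(records, [toy_snp])
        assert pair.cases.n == 1

    def test_materialized_subjects_round_trip(self, scz_pairs, tmp_path):
        """aggregate(materialize(pair)) is the identity on counts, via disk."""
        import pandas as pd

        from snpcc import materialize_subjects

        pair = scz_pairs["rs204993"]
        records = materialize_subjects(pair)
        path = tmp_path / "subjects.csv"
        pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "phenotype": r.phenotype,
                    "snp_id": r.snp_id,
                    "genotype": "/".join(r.genotype),
                }
                for r in records
            ]
        ).to_csv(path, index=False)
        (back,) = aggregate_subjects(read_subjects(path), [pair.snp])
        assert back.cases.as_tuple() == pair.cases.as_tuple()
        assert back.controls.as_tuple() == pair.controls.as_tuple()
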