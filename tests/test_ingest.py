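"""Report parsing, study filters, and protein-family sorting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glutenscan import (
    FilterSpec,
    ProteinFamily,
    ReportParseError,
    classify_protein_family,
    count_family_peptides,
    filter_peptides,
    parse_peptide_report,
)
from glutenscan.ingest import FAMILY_PRECEDENCE, UniquePeptideSet

from conftest import record

HEADER = "sequence\tprotein_accession\tprotein_description\ttaxon\tpep_expect\tenzyme\n"


def write_report(tmp_path, rows):
    p = tmp_path / "report.tsv"
    body = "".join(
        "\t".join(map(str, r)) + "\n" for r in rows
    )
    p.write_text(HEADER + body)
    return p


GOOD_ROW = ("QPQLPYQ", "P1", "alpha-gliadin", "Triticum aestivum", "0.001", "chymotrypsin")


class TestParse:
    def test_row_count_preserved(self, tmp_path):
        p = write_report(tmp_path, [GOOD_ROW] * 3)
        assert len(parse_peptide_report(p)) == 3

    def test_non_numeric_score_names_row(self, tmp_path):
        bad = GOOD_ROW[:4] + ("abc",) + GOOD_ROW[5:]
        p = write_report(tmp_path, [GOOD_ROW, bad])
        with pytest.raises(ReportParseError, match="row 2"):
            parse_peptide_report(p)

    def test_header_only_gives_empty(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text(HEADER)
        assert parse_peptide_report(p) == []

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("sequence\ttaxon\nQPQ\tTriticum aestivum\n")
        with pytest.raises(ReportParseError, match="missing column"):
            parse_peptide_report(p)


class TestFilter:
    def test_score_threshold_is_exclusive(self):
        records = [
            record("QPQLPYA", accession="X", pep_expect=0.05),
            record("QPQLPYC", accession="X", pep_expect=0.05),
        ]
        assert len(filter_peptides(records)) == 0

    def test_score_just_below_threshold_kept(self):
        records = [
            record("QPQLPYA", accession="X", pep_expect=0.049),
            record("QPQLPYC", accession="X", pep_expect=0.049),
        ]
        assert len(filter_peptides(records)) == 2

    def test_single_peptide_protein_contributes_nothing(self):
        records = [
            record("QPQLPYA", accession="X"),
            record("QPQLPYC", accession="X"),
            record("QQQQQQQ", accession="Y"),
        ]
        upset = filter_peptides(records)
        assert sorted(upset) == ["QPQLPYA", "QPQLPYC"]

    def test_taxon_substring_match_covers_hordeum_spp(self):
        records = [
            record("QPQLPYA", accession="X", taxon="Hordeum vulgare subsp. vulgare"),
            record("QPQLPYC", accession="X", taxon="hordeum chilense"),
            record("QPQLPYD", accession="X", taxon="Zea mays"),
        ]
        assert sorted(filter_peptides(records)) == ["QPQLPYA", "QPQLPYC"]

    def test_duplicate_rows_deduplicated(self):
        records = [
            record("QPQLPYA", accession="X"),
            record("QPQLPYA", accession="X"),
            record("QPQLPYC", accession="X"),
        ]
        upset = filter_peptides(records)
        assert sorted(upset) == ["QPQLPYA", "QPQLPYC"]
        assert len(upset.provenance["QPQLPYA"]) == 2

    def test_support_counted_after_score_and_taxon_filters(self):
        # accession X nominally has two peptides, but one fails the score
        # filter, so X ends up under-supported and contributes nothing
        records = [
            record("QPQLPYA", accession="X", pep_expect=0.001),
            record("QPQLPYC", accession="X", pep_expect=0.9),
        ]
        assert len(filter_peptides(records)) == 0

    def test_idempotent(self):
        records = [
            record("QPQLPYA", accession="X"),
            record("QPQLPYC", accession="X"),
            record("QQQQQQQ", accession="Y"),
        ]
        once = filter_peptides(records)
        surviving_rows = [r for seq in once for r in once.provenance[seq]]
        twice = filter_peptides(surviving_rows)
        assert twice.sequences == once.sequences

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(max_pep_expect=0.0)
        with pytest.raises(ValueError):
            FilterSpec(min_peptides_per_protein=0)


SEQS = st.text(alphabet="QPLF", min_size=5, max_size=9)


@st.composite
def report_rows(draw):
    n = draw(st.integers(1, 25))
    rows = []
    for _ in range(n):
        rows.append(
            record(
                draw(SEQS),
                accession=draw(st.sampled_from(["A", "B", "C"])),
                taxon=draw(st.sampled_from(
                    ["Triticum aestivum", "Hordeum vulgare", "Zea mays"]
                )),
                pep_expect=draw(st.floats(0, 0.1, allow_nan=False)),
            )
        )
    return rows


@settings(max_examples=60, deadline=None, derandomize=True)
@given(report_rows(), st.permutations(range(25)))
def test_filter_output_independent_of_row_order(rows, perm):
    shuffled = [rows[i % len(rows)] for i in perm[: len(rows)]]
    # a permutation with repeats only adds duplicate rows, which must not
    # change the unique-peptide outcome either
    base = filter_peptides(rows)
    other = filter_peptides(list(reversed(rows)))
    assert base.sequences == other.sequences
    assert filter_peptides(rows + shuffled).sequences == base.sequences


@settings(max_examples=60, deadline=None, derandomize=True)
@given(report_rows())
def test_relaxing_filters_is_monotone(rows):
    strict = filter_peptides(rows, FilterSpec(max_pep_expect=0.05))
    loose_score = filter_peptides(rows, FilterSpec(max_pep_expect=0.2))
    loose_support = filter_peptides(
        rows, FilterSpec(min_peptides_per_protein=1)
    )
    assert set(strict.sequences) <= set(loose_score.sequences)
    assert set(strict.sequences) <= set(loose_support.sequences)


class TestFamilies:
    @pytest.mark.parametrize(
        "description,family",
        [
            ("alpha-gliadin [Triticum aestivum]", ProteinFamily.ALPHA_GLIADIN),
            ("Alpha/beta-gliadin precursor", ProteinFamily.ALPHA_GLIADIN),
            ("high molecular weight glutenin subunit", ProteinFamily.HMW_GLUTENIN),
            ("Low-molecular-weight glutenin subunit", ProteinFamily.LMW_GLUTENIN),
            ("omega-gliadin", ProteinFamily.OMEGA_GLIADIN),
            ("gamma-gliadin B", ProteinFamily.GAMMA_GLIADIN),
            ("alpha-amylase/trypsin inhibitor CM3", ProteinFamily.ATI),
            ("avenin-like protein a", ProteinFamily.AVENIN),
            ("non-specific lipid transfer protein", ProteinFamily.LTP),
            ("serpin-Z1A", ProteinFamily.SERPIN),
            ("globulin 3", ProteinFamily.GLOBULIN),
            ("hypothetical protein", ProteinFamily.OTHER),
        ],
    )
    def test_keyword_classification(self, description, family):
        assert classify_protein_family(description) is family

    def test_counts_by_hand(self):
        records = [
            record("QPQLPYA", accession="X", description="alpha-gliadin"),
            record("QPQLPYC", accession="X", description="alpha-gliadin"),
            record("QQFFQQQ", accession="Z", description="serpin-Z"),
            record("QQFFQQC", accession="Z", description="serpin-Z"),
        ]
        counts = count_family_peptides(filter_peptides(records))
        assert counts[ProteinFamily.ALPHA_GLIADIN] == 2
        assert counts[ProteinFamily.SERPIN] == 2
        assert sum(counts.values()) == 4

    def test_shared_peptide_counted_once_at_higher_precedence(self):
        records = [
            record("QPQLPYA", accession="A", description="gamma-gliadin"),
            record("QPQLPYA", accession="B", description="alpha-gliadin"),
            record("QPQLPYC", accession="A", description="gamma-gliadin"),
            record("QPQLPYC", accession="B", description="alpha-gliadin"),
        ]
        counts = count_family_peptides(filter_peptides(records))
        assert counts[ProteinFamily.ALPHA_GLIADIN] == 2
        assert counts[ProteinFamily.GAMMA_GLIADIN] == 0

    def test_counts_conserve_set_size(self):
        records = [
            record("QPQLPYA", accession="X", description="omega-gliadin"),
            record("QPQLPYC", accession="X", description="unknown thing"),
        ]
        upset = filter_peptides(records)
        assert sum(count_family_peptides(upset).values()) == len(upset)

    def test_empty_set_all_zero(self):
        upset = UniquePeptideSet(sample_label="empty")
        counts = count_family_peptides(upset)
        assert set(counts.values()) == {0}

    def test_precedence_order_is_fixed(self):
        assert FAMILY_PRECEDENCE[0] is ProteinFamily.OMEGA_GLIADIN
        assert FAMILY_PRECEDENCE[-1] is ProteinFamily.OTHER
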