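"""Flat-file dialect: parsing, accessor API, round trips, invariants."""

import pytest

from ptmvar.errors import FlatfileFormatError, UnknownAccessionError
from ptmvar.flatfile import (
    COLUMNS,
    get_go_terms,
    get_mutations,
    get_ptms,
    get_sequence,
    parse_flatfile,
    write_flatfile,
)
from ptmvar.models import MOD_RESIDUE

from conftest import make_sequence


def write_lines(path, rows, header=COLUMNS):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def row(acc="P1", alt="", gene="G", species="synthetic", seq="", mods="",
        muts="", go=""):
    return (acc, alt, gene, species, seq, mods, muts, go)


SEQ = make_sequence(300, {257: "S", 259: "S", 263: "V", 256: "R"})


class TestParsing:
    def test_semicolon_separated_modifications(self, tmp_path):
        """Two phospho tokens yield two Modification objects at 259 and 257."""
        f = tmp_path / "p.tsv"
        write_lines(f, [row(seq=SEQ, mods="S 259-Phosphoserine; S 257-Phosphoserine")])
        rec = parse_flatfile(f)["P1"]
        assert sorted(m.position for m in rec.modifications) == [257, 259]
        assert all(m.mod_type == "Phosphoserine" for m in rec.modifications)

    def test_empty_annotation_cells_give_empty_lists(self, tmp_path):
        f = tmp_path / "p.tsv"
        write_lines(f, [row(seq=SEQ)])
        rec = parse_flatfile(f)["P1"]
        assert rec.modifications == [] and rec.mutations == [] and rec.go_terms == []

    def test_mutation_annotation_token(self, tmp_path):
        f = tmp_path / "p.tsv"
        write_lines(f, [row(seq=SEQ, muts="V263A:pathogenic; R256S")])
        muts = parse_flatfile(f)["P1"].mutations
        by_pos = {m.position: m for m in muts}
        assert by_pos[263].clinical_significance == "pathogenic"
        assert by_pos[256].clinical_significance == "unannotated"

    def test_missing_column_names_the_column(self, tmp_path):
        f = tmp_path / "p.tsv"
        write_lines(f, [], header=[c for c in COLUMNS if c != "sequence"])
        with pytest.raises(FlatfileFormatError, match="sequence"):
            parse_flatfile(f)

    def test_unknown_mod_type_becomes_other(self, tmp_path):
        f = tmp_path / "p.tsv"
        write_lines(f, [row(seq=SEQ, mods="S 259-Sumoylation")])
        (mod,) = parse_flatfile(f)["P1"].modifications
        assert mod.mod_type == "Other:Sumoylation"

    def test_duplicate_tokens_deduplicated(self, tmp_path):
        f = tmp_path / "p.tsv"
        write_lines(f, [row(seq=SEQ,
                            mods="S 259-Phosphoserine; S 259-Phosphoserine",
                            muts="V263A:pathogenic; V263A:pathogenic")])
        rec = parse_flatfile(f)["P1"]
        assert len(rec.modifications) == 1 and len(rec.mutations) == 1


class TestLenientVsStrict:
    @pytest.mark.parametrize(
        "mods,muts",
        [
            ("S 999-Phosphoserine", ""),        # position beyond sequence
            ("S 263-Phosphoserine", ""),        # residue disagrees with sequence
            ("K 259-Phosphoserine", ""),        # chemistry violation
            ("", "V263V"),                       # wt == mut
            ("", "A263G:pathogenic"),           # wt disagrees with sequence
            ("", "V263A:maybe-bad"),            # unknown annotation token
        ],
    )
    def test_invalid_tokens_dropped_lenient_abort_strict(self, tmp_path, mods, muts):
        f = tmp_path / "p.tsv"
        write_lines(f, [row(seq=SEQ, mods=mods, muts=muts)])
        records = parse_flatfile(f, strict=False)
        rec = records["P1"]
        assert rec.modifications == [] and rec.mutations == []
        dropped = (records.report.n_mod_tokens_dropped
                   + records.report.n_mut_tokens_dropped)
        assert dropped == 1
        with pytest.raises(FlatfileFormatError):
            parse_flatfile(f, strict=True)

    def test_bad_sequence_drops_record(self, tmp_path):
        f = tmp_path / "p.tsv"
        write_lines(f, [row(acc="BAD", seq="ACDB!"), row(acc="OK", seq=SEQ)])
        records = parse_flatfile(f)
        assert "OK" in records and "BAD" not in records
        assert records.report.n_records_dropped == 1


class TestAccessorAPI:
    def test_alias_and_primary_retrieval_agree(self, tmp_path):
        f = tmp_path / "p.tsv"
        write_lines(f, [row(alt="P1ALT; P1OLD", seq=SEQ, muts="V263A:pathogenic")])
        records = parse_flatfile(f)
        assert get_mutations(records, "P1ALT") == get_mutations(records, "P1")
        assert get_sequence(records, "P1OLD") == SEQ

    def test_counts_preserved_and_empty_fields(self, tmp_path):
        f = tmp_path / "p.tsv"
        write_lines(f, [row(seq=SEQ, muts="V263A; V263G; R256S")])
        records = parse_flatfile(f)
        assert len(get_mutations(records, "P1")) == 3
        assert get_ptms(records, "P1") == []
        assert get_go_terms(records, "P1") == []

    def test_unknown_accession_is_distinct_error(self, tmp_path):
        f = tmp_path / "p.tsv"
        write_lines(f, [row(seq=SEQ)])
        records = parse_flatfile(f)
        with pytest.raises(UnknownAccessionError):
            get_mutations(records, "NOSUCH")


class TestRoundTripAndOrder:
    def test_write_parse_identity(self, small_proteome, tmp_path):
        records, _ = small_proteome
        path = tmp_path / "out.tsv"
        write_flatfile(records, path)
        back = parse_flatfile(path)
        assert set(back) == set(records)
        for acc in records:
            a, b = records[acc], back[acc]
            assert a.sequence == b.sequence
            assert a.alt_accessions == b.alt_accessions
            assert a.go_terms == b.go_terms
            assert sorted(a.modifications, key=lambda m: (m.position, m.mod_type)) \
                == b.modifications
            assert sorted(a.mutations, key=lambda m: (m.position, m.mut_residue)) \
                == b.mutations
        assert (back.report.n_records_dropped, back.report.n_mod_tokens_dropped,
                back.report.n_mut_tokens_dropped) == (0, 0, 0)

    def test_line_order_does_not_matter(self, small_proteome, tmp_path):
        records, _ = small_proteome
        path = tmp_path / "a.tsv"
        write_flatfile(records, path)
        lines = path.read_text().splitlines()
        header, data = lines[0], lines[1:]
        shuffled = tmp_path / "b.tsv"
        shuffled.write_text("\n".join([header, *reversed(data)]) + "\n")
        a, b = parse_flatfile(path), parse_flatfile(shuffled)
        assert set(a) == set(b)
        assert all(a[k] == b[k] for k in a)

    def test_retained_annotations_satisfy_invariants(self, small_proteome, tmp_path):
        records, _ = small_proteome
        path = tmp_path / "out.tsv"
        write_flatfile(records, path)
        for rec in parse_flatfile(path).values():
            for m in rec.modifications:
                assert 1 <= m.position <= rec.length
                assert rec.sequence[m.position - 1] == m.residue
                forced = MOD_RESIDUE.get(m.mod_type)
                assert forced is None or m.residue == forced
            for m in rec.mutations:
                assert 1 <= m.position <= rec.length
                assert m.wt_residue != m.mut_residue
                assert rec.sequence[m.position - 1] == m.wt_residue
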