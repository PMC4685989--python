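"""Residue-unique counting, window semantics and the enrichment test."""

import numpy as np
import pytest

from ptmvar.enrichment import (
    collect_mutated_residues,
    has_ptm_within,
    pathogenic_protein_set,
    rank_mutations_by_nearby_ptms,
    test_enrichment as run_enrichment,
)
from ptmvar.errors import EmptyForegroundError
from ptmvar.flatfile import Proteome
from ptmvar.models import CORE_MOD_TYPES, Modification, Mutation, ProteinRecord
from ptmvar.simulate import SyntheticConfig, generate_proteome

from conftest import make_sequence
from oracles import collect_oracle, rank_oracle


class TestWindowSemantics:
    def test_phosphosite_within_eight_of_mutation(self, kinase_record):
        """S259 phosphorylation is 'nearby' for the V263 disease mutation."""
        assert has_ptm_within(kinase_record, 263, "Phosphoserine", 8)

    def test_boundary_inclusive_at_eight_exclusive_at_nine(self, kinase_record):
        # Phosphoserine at 108: |108-100| = 8 counts, |109-100| would not
        assert has_ptm_within(kinase_record, 100, "Phosphoserine", 8)
        assert not has_ptm_within(kinase_record, 101 - 9 + 8, "Phosphoserine", 7)
        assert not has_ptm_within(kinase_record, 117, "Phosphoserine", 8)

    def test_window_zero_means_on_site(self, kinase_record):
        assert has_ptm_within(kinase_record, 259, "Phosphoserine", 0)
        assert not has_ptm_within(kinase_record, 260, "Phosphoserine", 0)

    def test_other_mod_type_does_not_count(self, kinase_record):
        assert not has_ptm_within(kinase_record, 259, "Ubiquitination", 8)

    def test_out_of_range_position_raises(self, kinase_record):
        with pytest.raises(ValueError):
            has_ptm_within(kinase_record, 0, "Phosphoserine", 8)
        with pytest.raises(ValueError):
            has_ptm_within(kinase_record, 999, "Phosphoserine", 8)


class TestCollect:
    def test_or_collapse_of_multi_mutation_residue(self, tiny_proteome):
        residues = collect_mutated_residues(
            tiny_proteome, {"SYNRAF01"}, "dbsnp", windows=(0, 8))
        by_pos = {r.position: r for r in residues}
        # V263A (pathogenic) + V263G (unannotated) collapse to one residue
        assert len(residues) == 3
        assert by_pos[263].is_pathogenic
        assert not by_pos[256].is_pathogenic
        assert by_pos[263].nearby_ptm[("Phosphoserine", 8)]
        assert not by_pos[263].nearby_ptm[("Phosphoserine", 0)]

    def test_distinct_positions_counted_separately(self, tiny_proteome):
        residues = collect_mutated_residues(tiny_proteome,
                                            set(tiny_proteome), "dbsnp")
        assert len(residues) == 4  # 3 on the kinase + 1 on the plain protein

    def test_empty_subset_refused(self, tiny_proteome):
        with pytest.raises(EmptyForegroundError):
            collect_mutated_residues(tiny_proteome, set(), "dbsnp")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_quadratic_oracle(self, seed):
        cfg = SyntheticConfig(n_proteins=10, length_range=(40, 120), seed=seed)
        records, _ = generate_proteome(cfg)
        subset = set(records)
        windows = (0, 8)
        got = {
            (r.accession, r.position): (r.wt_residue, r.is_pathogenic, r.nearby_ptm)
            for r in collect_mutated_residues(records, subset, "dbsnp",
                                              CORE_MOD_TYPES, windows)
        }
        expected = collect_oracle(records, subset, "dbsnp", CORE_MOD_TYPES, windows)
        assert got == expected


class TestPathogenicSet:
    def test_planted_set_recovered(self, small_proteome):
        records, truth = small_proteome
        assert pathogenic_protein_set(records, "dbsnp") \
            == truth.pathogenic_accessions()

    def test_source_switch_reads_other_category(self, tiny_proteome):
        assert pathogenic_protein_set(tiny_proteome, "humsavar") == set()
        tiny_proteome["SYNPLAIN"].mutations.append(
            Mutation(10, "K", "R", "Disease", source="humsavar"))
        assert pathogenic_protein_set(tiny_proteome, "humsavar") == {"SYNPLAIN"}

    def test_no_pathogenic_means_empty_foreground_error(self):
        p = Proteome()
        p.add(ProteinRecord("SYNX", make_sequence(30, {5: "V"}),
                            mutations=[Mutation(5, "V", "A", "unannotated")]))
        assert pathogenic_protein_set(p, "dbsnp") == set()
        with pytest.raises(EmptyForegroundError):
            run_enrichment(p, "dbsnp")


class TestEnrichmentTest:
    def test_contingency_conservation_and_window_monotonicity(self, small_proteome):
        records, _ = small_proteome
        subset = pathogenic_protein_set(records, "dbsnp")
        residues = collect_mutated_residues(records, subset, "dbsnp")
        n_path = sum(r.is_pathogenic for r in residues)
        n_non = len(residues) - n_path
        res0 = {r.mod_type: r for r in run_enrichment(records, window=0)}
        res8 = {r.mod_type: r for r in run_enrichment(records, window=8)}
        for t in CORE_MOD_TYPES:
            for res in (res0, res8):
                assert res[t].table.a + res[t].table.b == n_path
                assert res[t].table.c + res[t].table.d == n_non
            assert res8[t].table.a >= res0[t].table.a
            assert res8[t].table.c >= res0[t].table.c
        # every analyzed residue is inside the bias-controlled set
        assert {r.accession for r in residues} <= subset

    def test_window_zero_with_no_onsite_overlap(self):
        p = Proteome()
        seq = make_sequence(60, {10: "S", 30: "V", 40: "V"})
        p.add(ProteinRecord(
            "SYNX", seq,
            modifications=[Modification("S", 10, "Phosphoserine")],
            mutations=[Mutation(30, "V", "A", "pathogenic"),
                       Mutation(40, "V", "L", "unannotated")],
        ))
        res = {r.mod_type: r for r in run_enrichment(p, window=0)}
        r = res["Phosphoserine"]
        assert r.table.a == 0 and r.p == 1.0

    def test_type_without_ptms_flagged_untestable(self):
        cfg = SyntheticConfig(
            n_proteins=30, length_range=(80, 160), seed=9,
            ptm_rate={"Phosphoserine": 0.2},  # only one type generated
        )
        records, _ = generate_proteome(cfg)
        res = {r.mod_type: r for r in run_enrichment(records, window=8)}
        assert res["Phosphoserine"].testable
        for t in CORE_MOD_TYPES:
            if t != "Phosphoserine":
                assert not res[t].testable
                assert np.isnan(res[t].p) and np.isnan(res[t].q)

    def test_all_zero_ptm_rates_all_untestable(self):
        cfg = SyntheticConfig(n_proteins=20, length_range=(60, 100), seed=3,
                              ptm_rate={})
        records, _ = generate_proteome(cfg)
        assert all(not r.testable for r in run_enrichment(records, window=8))

    def test_q_at_least_p_and_sorted_by_q(self, small_proteome):
        records, _ = small_proteome
        res = run_enrichment(records, window=8)
        testable = [r for r in res if r.testable]
        assert all(r.q >= r.p - 1e-15 for r in testable)
        assert all(x.q <= y.q for x, y in zip(testable, testable[1:]))


class TestRanking:
    def test_direct_count_and_tie_break(self):
        p = Proteome()
        seq = make_sequence(60, {12: "S", 19: "S", 20: "V", 21: "T", 28: "S",
                                 40: "V", 5: "V"})
        p.add(ProteinRecord(
            "SYNX", seq,
            modifications=[
                Modification("S", 12, "Phosphoserine"),   # offset -8
                Modification("S", 19, "Phosphoserine"),   # offset -1
                Modification("T", 21, "Phosphothreonine"),  # offset +1
                Modification("S", 28, "Phosphoserine"),   # offset +8
            ],
            mutations=[Mutation(20, "V", "A", "pathogenic"),
                       Mutation(40, "V", "L"), Mutation(5, "V", "I")],
        ))
        df = rank_mutations_by_nearby_ptms(p, window=8)
        assert df.iloc[0]["position"] == 20 and df.iloc[0]["n_nearby_ptms"] == 4
        # ties (both zero) break by (accession, position)
        assert list(df["position"]) == [20, 5, 40]

    def test_protein_with_dense_window_ranks_first(self):
        cfg = SyntheticConfig(n_proteins=8, length_range=(60, 100), seed=21)
        records, _ = generate_proteome(cfg)
        target = next(iter(records.values()))
        # plant 10 phosphosites around the first mutated residue
        target.mutations.append(Mutation(30, target.sequence[29], "W"
                                         if target.sequence[29] != "W" else "F",
                                         "pathogenic"))
        positions = [p for p in range(22, 39) if p != 30][:10]
        target.modifications = [
            Modification(target.sequence[p - 1], p, "Other:Planted")
            for p in positions
        ]
        df = rank_mutations_by_nearby_ptms(records, window=8)
        assert df.iloc[0]["accession"] == target.primary_accession
        assert df.iloc[0]["n_nearby_ptms"] >= 10

    @pytest.mark.parametrize("seed", [4, 5])
    def test_equals_quadratic_oracle(self, seed):
        cfg = SyntheticConfig(n_proteins=10, length_range=(40, 120), seed=seed)
        records, _ = generate_proteome(cfg)
        df = rank_mutations_by_nearby_ptms(records, window=8)
        expected = rank_oracle(records, window=8)
        assert len(df) == len(expected)
        for row in df.itertuples():
            wt, pathog, n_near = expected[(row.accession, row.position)]
            assert (row.wt_residue, row.is_pathogenic, row.n_nearby_ptms) \
                == (wt, pathog, n_near)
        counts = df["n_nearby_ptms"].to_numpy()
        assert np.all(np.diff(counts) <= 0)
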