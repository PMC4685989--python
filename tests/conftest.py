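import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ptmvar.flatfile import Proteome
from ptmvar.models import Modification, Mutation, ProteinRecord
from ptmvar.simulate import SyntheticConfig, generate_proteome


def make_sequence(length: int, residues: dict[int, str], fill: str = "A") -> str:
    """A fill-residue sequence with specific residues planted (1-based)."""
    seq = [fill] * length
    for pos, aa in residues.items():
        seq[pos - 1] = aa
    return "".join(seq)


@pytest.fixture
def kinase_record():
    """A hand-built record shaped like the RAF1 14-3-3 docking region.

    Phosphoserines at 257 and 259, a phosphothreonine at 258, and mutations
    clustered between 256 and 263; V263 carries both a pathogenic and an
    unannotated substitution.
    """
    seq = make_sequence(
        320, {256: "R", 257: "S", 258: "T", 259: "S", 260: "T", 263: "V",
              100: "G", 108: "S", 109: "S"},
    )
    return ProteinRecord(
        primary_accession="SYNRAF01",
        sequence=seq,
        alt_accessions=["SYNRAF01-ALT"],
        gene_name="RAF1LIKE",
        species="synthetic",
        modifications=[
            Modification("S", 257, "Phosphoserine"),
            Modification("T", 258, "Phosphothreonine"),
            Modification("S", 259, "Phosphoserine"),
            Modification("S", 108, "Phosphoserine"),
        ],
        mutations=[
            Mutation(256, "R", "S", "unannotated"),
            Mutation(263, "V", "A", "pathogenic"),
            Mutation(263, "V", "G", "unannotated"),
            Mutation(100, "G", "D", "non-pathogenic"),
        ],
        go_terms=["GO:0004672", "GO:0008284"],
    )


@pytest.fixture
def tiny_proteome(kinase_record):
    """Two proteins: the kinase-like record plus a PTM-free partner."""
    p = Proteome()
    p.add(kinase_record)
    p.add(
        ProteinRecord(
            primary_accession="SYNPLAIN",
            sequence=make_sequence(50, {10: "K", 20: "C"}),
            mutations=[Mutation(20, "C", "Y", "pathogenic")],
        )
    )
    return p


@pytest.fixture(scope="session")
def small_proteome():
    """A seeded 40-protein synthetic proteome (session-scoped, read-only)."""
    cfg = SyntheticConfig(n_proteins=40, length_range=(60, 160), seed=11)
    records, truth = generate_proteome(cfg)
    return records, truth
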