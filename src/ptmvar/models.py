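"""Core domain types.

The unit of the whole analysis is the *residue*, not the annotation: several
mutations may hit one residue and several modifications may sit in its
neighborhood, but enrichment is counted once per (protein, position). The
types below carry just enough structure for that counting rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

#: Residue chemistry forced by each modification type in the core vocabulary.
MOD_RESIDUE = {
    "Phosphoserine": "S",
    "Phosphothreonine": "T",
    "Phosphotyrosine": "Y",
    "Ubiquitination": "K",
    "N6-acetyllysine": "K",
    "N-Glycosylation": "N",
}

#: The modification types with enough annotations for per-type testing.
CORE_MOD_TYPES = tuple(MOD_RESIDUE)

#: Clinical-significance vocabularies by mutation source.
DBSNP_CATEGORIES = ("pathogenic", "non-pathogenic", "unannotated")
HUMSAVAR_CATEGORIES = ("Disease", "Polymorphism", "Unclassified")

#: Category token that marks a mutation as disease-causing, per source.
PATHOGENIC_CATEGORY = {"dbsnp": "pathogenic", "humsavar": "Disease"}


@dataclass(frozen=True, slots=True)
class Modification:
    """One post-translational modification instance on a protein.

    ``position`` is 1-based on the mature sequence, counting the initiator
    methionine as 1. ``mod_type`` is either one of :data:`CORE_MOD_TYPES` or
    an ``Other:<label>`` passthrough for types outside the core vocabulary.
    """

    residue: str
    position: int
    mod_type: str

    def is_core_type(self) -> bool:
        return self.mod_type in MOD_RESIDUE


@dataclass(frozen=True, slots=True)
class Mutation:
    """A missense substitution at a single residue.

    ``clinical_significance`` uses the dbSNP vocabulary
    (pathogenic / non-pathogenic / unannotated) for ``source='dbsnp'`` and the
    humsavar vocabulary (Disease / Polymorphism / Unclassified) for
    ``source='humsavar'``.
    """

    position: int
    wt_residue: str
    mut_residue: str
    clinical_significance: str = "unannotated"
    source: str = "dbsnp"
    variant_id: str = ""

    @property
    def is_pathogenic(self) -> bool:
        return self.clinical_significance == PATHOGENIC_CATEGORY.get(self.source)


@dataclass(slots=True)
class ProteinRecord:
    """One protein with its sequence and annotation lists."""

    primary_accession: str
    sequence: str
    alt_accessions: list[str] = field(default_factory=list)
    gene_name: str = ""
    species: str = ""
    modifications: list[Modification] = field(default_factory=list)
    mutations: list[Mutation] = field(default_factory=list)
    go_terms: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class HumsavarVariant:
    """One row of a humsavar-style variant index file (missense only)."""

    gene: str
    accession: str
    ftid: str
    position: int
    wt_residue: str
    mut_residue: str
    category: str
    dbsnp_id: str = ""
    disease_name: str = ""


@dataclass(slots=True)
class MutatedResidue:
    """The counting unit: a unique (protein, position) carrying mutations.

    ``is_pathogenic`` is the OR over every mutation recorded at the residue
    (one pathogenic annotation suffices); ``nearby_ptm`` maps
    ``(mod_type, window)`` to whether any modification of that type lies
    within ``window`` residues.
    """

    accession: str
    position: int
    wt_residue: str
    is_pathogenic: bool
    nearby_ptm: dict[tuple[str, int], bool] = field(default_factory=dict)


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """2x2 counts: rows foreground/background, columns feature/no-feature.

    a = foreground with feature, b = foreground without,
    c = background with feature, d = background without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"table entry {name}={v} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        num, den = self.a * self.d, self.b * self.c
        if den == 0:
            return float("inf") if num > 0 else float("nan")
        return num / den


@dataclass(slots=True)
class EnrichmentResult:
    """Per modification type and window: the table and its test."""

    mod_type: str
    window: int
    table: ContingencyTable
    odds_ratio: float
    p: float
    q: float
    n_foreground_proteins: int
    testable: bool = True


@dataclass(frozen=True, slots=True)
class AnnotationCounts:
    """Per-protein annotation tallies used in the study-bias analyses."""

    accession: str
    n_go: int
    n_mutations: int
    n_ptms: int
    length: int
    has_pathogenic: bool
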