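"""Parsing UniProt humsavar-style variant index files and cross-referencing.

The humsavar file ("Human polymorphisms and disease mutations") is
whitespace-aligned columnar text with a free-text preamble and footer. Each
data row carries a gene name, a UniProtKB accession, a variant FTId
(``VAR_NNNNNN``), a ``p.Xaa123Xaa`` substitution in three-letter code, a
category (``Disease`` / ``Polymorphism`` / ``Unclassified`` in the 2015-era
vocabulary), an optional dbSNP identifier and an optional disease name.

Only simple missense substitutions are parsed; deletions, frameshifts and
extensions are skipped with a logged count. Category matching downstream is
on the exact token ``Disease``; newer vocabularies (LB/B, LP/P) can be folded
in through the ``category_map`` argument.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio.Data.IUPACData import protein_letters_3to1

from .errors import HumsavarFormatError, UndefinedFractionError
from .flatfile import Proteome
from .models import HUMSAVAR_CATEGORIES, HumsavarVariant, Mutation

logger = logging.getLogger(__name__)

_THREE_TO_ONE = {k.capitalize(): v for k, v in protein_letters_3to1.items()}
_CHANGE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")
_FTID = re.compile(r"^VAR_\d{6}$")


class VariantList(list):
    """A list of :class:`HumsavarVariant` that remembers parser tallies."""

    def __init__(self, *args) -> None:
        super().__init__(*args)
        self.n_skipped_non_missense = 0
        self.n_skipped_bad_code = 0
        self.n_skipped_bad_category = 0


def parse_humsavar(path, category_map: dict[str, str] | None = None) -> VariantList:
    """Parse a humsavar-style file into a :class:`VariantList`.

    Lines before/after the data block and non-missense change tokens are
    skipped (tallied on the returned list). Raises
    :class:`HumsavarFormatError` when no data row at all is found.

    ``category_map`` optionally maps file category tokens onto the 2015-era
    vocabulary, e.g. ``{"LP/P": "Disease", "LB/B": "Polymorphism"}``.
    """
    category_map = category_map or {}
    variants = VariantList()
    n_candidate = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            tokens = line.split()
            if len(tokens) < 5 or not _FTID.match(tokens[2]):
                continue  # preamble, footer, blank or non-data line
            n_candidate += 1
            gene, accession, ftid, change = tokens[0], tokens[1], tokens[2], tokens[3]
            m = _CHANGE.match(change)
            if m is None:
                variants.n_skipped_non_missense += 1
                continue
            wt3, pos, mut3 = m.group(1), int(m.group(2)), m.group(3)
            wt = _THREE_TO_ONE.get(wt3)
            mut = _THREE_TO_ONE.get(mut3)
            if wt is None or mut is None or wt == mut:
                variants.n_skipped_bad_code += 1
                continue
            category = category_map.get(tokens[4], tokens[4])
            if category not in HUMSAVAR_CATEGORIES:
                variants.n_skipped_bad_category += 1
                continue
            dbsnp = tokens[5] if len(tokens) > 5 and tokens[5] != "-" else ""
            disease = " ".join(tokens[6:]) if len(tokens) > 6 else ""
            if disease == "-":
                disease = ""
            variants.append(
                HumsavarVariant(
                    gene=gene, accession=accession, ftid=ftid, position=pos,
                    wt_residue=wt, mut_residue=mut, category=category,
                    dbsnp_id=dbsnp, disease_name=disease,
                )
            )
    if n_candidate == 0:
        raise HumsavarFormatError(f"no humsavar data block found in {path}")
    skipped = (variants.n_skipped_non_missense + variants.n_skipped_bad_code
               + variants.n_skipped_bad_category)
    if skipped:
        logger.info(
            "parsed %d missense variants from %s; skipped %d non-missense, "
            "%d unmappable-code, %d unknown-category lines",
            len(variants), path, variants.n_skipped_non_missense,
            variants.n_skipped_bad_code, variants.n_skipped_bad_category,
        )
    return variants


@dataclass(slots=True)
class CrossrefReport:
    """Mapping tally: every input variant lands in exactly one bucket."""

    n_matched: int = 0
    n_residue_mismatch: int = 0
    n_accession_unmatched: int = 0
    mismatches: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return self.n_matched + self.n_residue_mismatch + self.n_accession_unmatched

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("bucket\tcount\n")
            fh.write(f"matched\t{self.n_matched}\n")
            fh.write(f"residue_mismatch\t{self.n_residue_mismatch}\n")
            fh.write(f"accession_unmatched\t{self.n_accession_unmatched}\n")


def crossref(variants: list[HumsavarVariant], records: Proteome) -> tuple[Proteome, CrossrefReport]:
    """Attach humsavar variants to matching protein records.

    A variant attaches when its accession resolves (primary or alternate) and
    its wild-type residue matches the sequence at its position; the attached
    :class:`Mutation` carries ``source='humsavar'`` and the variant's
    category. Mismatches are tallied, never fatal. Identical (position, wt,
    mut, category) attachments are de-duplicated per record.
    """
    report = CrossrefReport()
    seen: dict[str, set] = {}
    for v in variants:
        if v.accession not in records:
            report.n_accession_unmatched += 1
            continue
        rec = records.resolve(v.accession)
        if v.position > rec.length or rec.sequence[v.position - 1] != v.wt_residue:
            report.n_residue_mismatch += 1
            report.mismatches.append(v.ftid)
            continue
        key = (v.position, v.wt_residue, v.mut_residue, v.category)
        owned = seen.setdefault(rec.primary_accession, set())
        if key not in owned:
            owned.add(key)
            rec.mutations.append(
                Mutation(
                    position=v.position, wt_residue=v.wt_residue,
                    mut_residue=v.mut_residue, clinical_significance=v.category,
                    source="humsavar", variant_id=v.ftid,
                )
            )
        report.n_matched += 1
    logger.info(
        "crossref: %d matched, %d residue mismatches, %d accession unmatched",
        report.n_matched, report.n_residue_mismatch, report.n_accession_unmatched,
    )
    return records, report


def disease_fraction(
    variants: list[HumsavarVariant], restrict_to_disease_proteins: bool = False
) -> dict:
    """Fraction of variants labeled ``Disease``.

    With ``restrict_to_disease_proteins`` the variant list is first cut down
    to accessions carrying at least one Disease variant — the study-bias
    restriction under which annotation clustering inflates the fraction.
    Restriction can only remove non-disease variants, so the restricted
    fraction is never below the unrestricted one.
    """
    if not variants:
        raise UndefinedFractionError("disease fraction undefined on an empty variant list")
    pool = list(variants)
    if restrict_to_disease_proteins:
        disease_accs = {v.accession for v in pool if v.category == "Disease"}
        pool = [v for v in pool if v.accession in disease_accs]
    if not pool:
        return {"n_total": 0, "n_disease": 0, "fraction": 0.0}
    n_disease = sum(1 for v in pool if v.category == "Disease")
    return {"n_total": len(pool), "n_disease": n_disease,
            "fraction": n_disease / len(pool)}
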