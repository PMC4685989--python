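"""Reading and writing the tab-separated protein annotation flat file.

The dialect is ProteomeScout-like: one protein per line, annotations written
column-wise, multiple annotations of one type separated by ``"; "``. It is a
documented dialect of this package, not byte-compatible with any particular
ProteomeScout release (whose exact schema lives on an external wiki).

Columns (TSV, UTF-8, header row required)::

    accession        primary UniProtKB-style accession
    alt_accessions   "; "-separated alternate accessions (may be empty)
    gene             gene symbol
    species          species name
    sequence         one-letter amino-acid sequence (X permitted)
    modifications    tokens "R P-T", e.g. "S 259-Phosphoserine", "; "-joined
    mutations        tokens "XposY[:annotation]", e.g. "V263A:pathogenic"
    GO_terms         "GO:0008284; GO:0004672" style

Positions are 1-based counting the initiator methionine as position 1. In
lenient mode (default) tokens violating residue/position invariants are
dropped with a logged count; in strict mode they abort the parse.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .errors import FlatfileFormatError, UnknownAccessionError
from .models import (
    AA_SET,
    MOD_RESIDUE,
    Modification,
    Mutation,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

COLUMNS = (
    "accession",
    "alt_accessions",
    "gene",
    "species",
    "sequence",
    "modifications",
    "mutations",
    "GO_terms",
)

_SEP = "; "
_MOD_TOKEN = re.compile(r"^([A-Z]) (\d+)-(.+)$")
_MUT_TOKEN = re.compile(r"^([A-Z])(\d+)([A-Z])(?::(.+))?$")
_MUT_ANNOTATIONS = {"pathogenic", "non-pathogenic"}


@dataclass(slots=True)
class ParseReport:
    """Counts of what the parser kept and dropped."""

    n_records: int = 0
    n_records_dropped: int = 0
    n_mod_tokens_dropped: int = 0
    n_mut_tokens_dropped: int = 0
    n_go_tokens_dropped: int = 0


class Proteome(dict):
    """Accession-keyed map of :class:`ProteinRecord`.

    Keys are primary accessions; :meth:`resolve` additionally honors
    alternate accessions. Iteration order is insertion order.
    """

    def __init__(self) -> None:
        super().__init__()
        self._alias: dict[str, str] = {}
        self.report = ParseReport()

    def add(self, record: ProteinRecord) -> None:
        acc = record.primary_accession
        if not acc:
            raise ValueError("record has empty primary accession")
        if acc in self:
            raise ValueError(f"duplicate primary accession {acc!r}")
        self[acc] = record
        for alias in record.alt_accessions:
            if alias and alias not in self._alias and alias not in self:
                self._alias[alias] = acc

    def resolve(self, acc: str) -> ProteinRecord:
        direct = dict.get(self, acc)
        if direct is not None:
            return direct
        primary = self._alias.get(acc)
        if primary is not None:
            return self[primary]
        raise UnknownAccessionError(acc)

    def __contains__(self, acc) -> bool:  # membership honors aliases
        return super().__contains__(acc) or acc in self._alias


def _parse_modifications(cell: str, sequence: str, strict: bool, report: ParseReport) -> list[Modification]:
    mods: list[Modification] = []
    seen: set[tuple[int, str]] = set()
    for token in filter(None, (t.strip() for t in cell.split(";"))):
        m = _MOD_TOKEN.match(token)
        if m is None:
            if strict:
                raise FlatfileFormatError(f"malformed modification token {token!r}")
            report.n_mod_tokens_dropped += 1
            continue
        residue, pos, mod_type = m.group(1), int(m.group(2)), m.group(3).strip()
        forced = MOD_RESIDUE.get(mod_type)
        if forced is None and not mod_type.startswith("Other:"):
            mod_type = f"Other:{mod_type}"
        ok = (
            1 <= pos <= len(sequence)
            and sequence[pos - 1] == residue
            and (forced is None or residue == forced)
        )
        if not ok:
            if strict:
                raise FlatfileFormatError(
                    f"modification token {token!r} violates residue/position invariants"
                )
            report.n_mod_tokens_dropped += 1
            continue
        key = (pos, mod_type)
        if key in seen:  # identical position+type tokens are de-duplicated
            continue
        seen.add(key)
        mods.append(Modification(residue=residue, position=pos, mod_type=mod_type))
    return mods


def _parse_mutations(cell: str, sequence: str, strict: bool, report: ParseReport) -> list[Mutation]:
    muts: list[Mutation] = []
    seen: set[tuple[int, str, str, str]] = set()
    for token in filter(None, (t.strip() for t in cell.split(";"))):
        m = _MUT_TOKEN.match(token)
        annotation = m.group(4) if m else None
        if m is None or (annotation is not None and annotation not in _MUT_ANNOTATIONS):
            if strict:
                raise FlatfileFormatError(f"malformed mutation token {token!r}")
            report.n_mut_tokens_dropped += 1
            continue
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
        # wt==mut violates the substitution invariant; a wt that disagrees
        # with the sequence is an isoform/version mismatch.
        ok = wt != mut and 1 <= pos <= len(sequence) and sequence[pos - 1] == wt
        if not ok:
            if strict:
                raise FlatfileFormatError(
                    f"mutation token {token!r} violates residue/position invariants"
                )
            report.n_mut_tokens_dropped += 1
            continue
        category = annotation if annotation is not None else "unannotated"
        key = (pos, wt, mut, category)
        if key in seen:
            continue
        seen.add(key)
        muts.append(
            Mutation(position=pos, wt_residue=wt, mut_residue=mut,
                     clinical_significance=category, source="dbsnp")
        )
    return muts


_GO_TOKEN = re.compile(r"^GO:\d{7}$")


def parse_flatfile(path, strict: bool = False) -> Proteome:
    """Parse a flat file into an accession-keyed :class:`Proteome`.

    Parameters
    ----------
    path : str or PathLike
        The TSV flat file in the dialect documented in the module docstring.
    strict : bool
        When True, any malformed or invariant-violating token aborts parsing
        with :class:`FlatfileFormatError`; when False (default) such tokens —
        or whole records with invalid accession/sequence — are dropped and
        counted in ``Proteome.report``.
    """
    proteome = Proteome()
    report = proteome.report
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FlatfileFormatError("empty file: no header row")
        header = header_line.rstrip("\n").split("\t")
        index = {name: i for i, name in enumerate(header)}
        for col in COLUMNS:
            if col not in index:
                raise FlatfileFormatError(f"missing required column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            cells += [""] * (len(header) - len(cells))
            get = lambda col: cells[index[col]]  # noqa: E731
            acc = get("accession").strip()
            sequence = get("sequence").strip()
            record_ok = bool(acc) and acc not in proteome and bool(sequence) and set(sequence) <= (AA_SET | {"X"})
            if not record_ok:
                if strict:
                    raise FlatfileFormatError(
                        f"line {lineno}: invalid accession or sequence for {acc!r}"
                    )
                report.n_records_dropped += 1
                continue
            alt = [a.strip() for a in get("alt_accessions").split(";") if a.strip()]
            go_terms = []
            for token in (t.strip() for t in get("GO_terms").split(";")):
                if not token:
                    continue
                if _GO_TOKEN.match(token):
                    go_terms.append(token)
                elif strict:
                    raise FlatfileFormatError(f"malformed GO token {token!r}")
                else:
                    report.n_go_tokens_dropped += 1
            record = ProteinRecord(
                primary_accession=acc,
                sequence=sequence,
                alt_accessions=alt,
                gene_name=get("gene").strip(),
                species=get("species").strip(),
                modifications=_parse_modifications(get("modifications"), sequence, strict, report),
                mutations=_parse_mutations(get("mutations"), sequence, strict, report),
                go_terms=go_terms,
            )
            proteome.add(record)
            report.n_records += 1
    dropped = (report.n_records_dropped + report.n_mod_tokens_dropped
               + report.n_mut_tokens_dropped + report.n_go_tokens_dropped)
    if dropped:
        logger.info(
            "parsed %d records from %s; dropped %d records, %d modification / "
            "%d mutation / %d GO tokens",
            report.n_records, path, report.n_records_dropped,
            report.n_mod_tokens_dropped, report.n_mut_tokens_dropped,
            report.n_go_tokens_dropped,
        )
    return proteome


# ---------------------------------------------------------------------------
# Accessor API


def get_mutations(records: Proteome, acc: str) -> list[Mutation]:
    """All mutations of the record owning ``acc`` (primary or alternate)."""
    return list(records.resolve(acc).mutations)


def get_ptms(records: Proteome, acc: str) -> list[Modification]:
    """All modifications of the record owning ``acc``."""
    return list(records.resolve(acc).modifications)


def get_sequence(records: Proteome, acc: str) -> str:
    """The amino-acid sequence of the record owning ``acc``."""
    return records.resolve(acc).sequence


def get_go_terms(records: Proteome, acc: str) -> list[str]:
    """The GO identifiers of the record owning ``acc``."""
    return list(records.resolve(acc).go_terms)


# ---------------------------------------------------------------------------
# Writer


def _format_mutation(m: Mutation) -> str:
    token = f"{m.wt_residue}{m.position}{m.mut_residue}"
    if m.clinical_significance in _MUT_ANNOTATIONS:
        token += f":{m.clinical_significance}"
    return token


def write_flatfile(records: Proteome | dict, path) -> None:
    """Write records to ``path`` in the documented dialect.

    Records are written sorted by primary accession; within a record,
    annotation tokens are sorted by position so output is a pure function of
    record content. Only dbSNP-sourced mutations are rendered (humsavar
    attachments belong to the humsavar dialect).
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for acc in sorted(records):
            r = records[acc]
            mods = _SEP.join(
                f"{m.residue} {m.position}-{m.mod_type}"
                for m in sorted(r.modifications, key=lambda m: (m.position, m.mod_type))
            )
            muts = _SEP.join(
                _format_mutation(m)
                for m in sorted(
                    (m for m in r.mutations if m.source == "dbsnp"),
                    key=lambda m: (m.position, m.mut_residue),
                )
            )
            fh.write("\t".join([
                r.primary_accession,
                _SEP.join(r.alt_accessions),
                r.gene_name,
                r.species,
                r.sequence,
                mods,
                muts,
                _SEP.join(r.go_terms),
            ]) + "\n")
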