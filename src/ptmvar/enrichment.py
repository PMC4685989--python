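"""The core pipeline: residue-unique counting and windowed enrichment tests.

The analysis asks whether disease-causing missense mutations sit closer to
post-translational modification sites than mutations in general. Because
well-studied proteins accumulate annotations of every kind, the test is run
only inside the bias-controlled protein set — proteins carrying at least one
pathogenic (dbSNP) or Disease (humsavar) mutation — so foreground and
background share the same study-intensity distribution.

Counting is residue-unique: a residue hit by several mutations is one unit,
and it is pathogenic if any of its mutations is. "Within w amino acids"
means ``|ptm.position - position| <= w`` including 0, so the window-8 feature
set subsumes the window-0 (on-site) one; windows clip at the termini.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EmptyForegroundError
from .flatfile import Proteome
from .models import (
    CORE_MOD_TYPES,
    PATHOGENIC_CATEGORY,
    ContingencyTable,
    EnrichmentResult,
    MutatedResidue,
    ProteinRecord,
)
from .stats import bh_fdr, fisher_exact_one_sided

__all__ = [
    "pathogenic_protein_set",
    "has_ptm_within",
    "collect_mutated_residues",
    "test_enrichment",
    "rank_mutations_by_nearby_ptms",
]


def pathogenic_protein_set(records: Proteome, source: str = "dbsnp") -> set[str]:
    """Accessions of proteins with >= 1 pathogenic (or Disease) mutation.

    This set is the study-bias control: restricting both foreground and
    background to it removes the annotation-richness confound.
    """
    want = PATHOGENIC_CATEGORY[source]
    return {
        acc
        for acc, rec in records.items()
        if any(m.source == source and m.clinical_significance == want
               for m in rec.mutations)
    }


def has_ptm_within(record: ProteinRecord, position: int, mod_type: str,
                   window: int) -> bool:
    """True iff a modification of ``mod_type`` lies within ``window`` residues.

    ``window=0`` asks whether the queried residue itself is modified.
    Windows are clipped at the sequence termini (no padding).
    """
    if not 1 <= position <= record.length:
        raise ValueError(
            f"position {position} out of range 1..{record.length} "
            f"for {record.primary_accession}"
        )
    if window < 0:
        raise ValueError("window must be >= 0")
    return any(
        m.mod_type == mod_type and abs(m.position - position) <= window
        for m in record.modifications
    )


# ---------------------------------------------------------------------------
# Vectorized internals shared with the resampling control


def _residue_arrays(records: Proteome, protein_subset, source: str,
                    mod_types, windows):
    """Flatten the subset's mutated residues into numpy arrays.

    Returns (accessions, positions, wt, is_pathogenic, near) where ``near``
    maps (mod_type, window) -> bool array aligned with the residue axis,
    plus per-type PTM instance counts within the subset.
    """
    want = PATHOGENIC_CATEGORY[source]
    accs: list[str] = []
    positions: list[int] = []
    wts: list[str] = []
    pathog: list[bool] = []
    near = {(t, w): [] for t in mod_types for w in windows}
    n_instances = dict.fromkeys(mod_types, 0)
    for acc in sorted(protein_subset):
        rec = records.resolve(acc)
        by_pos: dict[int, bool] = {}
        for m in rec.mutations:
            if m.source != source:
                continue
            by_pos[m.position] = by_pos.get(m.position, False) or (
                m.clinical_significance == want
            )
        if not by_pos:
            continue
        pos = np.fromiter(sorted(by_pos), dtype=np.int64)
        ptm_pos = {
            t: np.fromiter(
                sorted(m.position for m in rec.modifications if m.mod_type == t),
                dtype=np.int64,
            )
            for t in mod_types
        }
        for t in mod_types:
            n_instances[t] += ptm_pos[t].size
        for (t, w), flags in near.items():
            arr = ptm_pos[t]
            if arr.size == 0:
                flags.append(np.zeros(pos.size, dtype=bool))
            else:
                lo = np.searchsorted(arr, pos - w, side="left")
                hi = np.searchsorted(arr, pos + w, side="right")
                flags.append(lo < hi)
        accs.extend([rec.primary_accession] * pos.size)
        positions.extend(pos.tolist())
        wts.extend(rec.sequence[p - 1] for p in pos.tolist())
        pathog.extend(by_pos[p] for p in pos.tolist())
    near_arr = {
        key: (np.concatenate(chunks) if chunks else np.zeros(0, dtype=bool))
        for key, chunks in near.items()
    }
    return (accs, np.asarray(positions, dtype=np.int64), wts,
            np.asarray(pathog, dtype=bool), near_arr, n_instances)


def collect_mutated_residues(records: Proteome, protein_subset, source: str,
                             mod_types=CORE_MOD_TYPES,
                             windows=(0, 8)) -> list[MutatedResidue]:
    """One :class:`MutatedResidue` per unique (protein, position).

    Pathogenicity is OR-collapsed over the residue's mutations; nearby-PTM
    flags are precomputed for every requested (mod_type, window) pair.
    """
    if not protein_subset:
        raise EmptyForegroundError("empty protein subset: nothing to count")
    accs, positions, wts, pathog, near, _ = _residue_arrays(
        records, protein_subset, source, tuple(mod_types), tuple(windows)
    )
    keys = list(near)
    flags = [near[k] for k in keys]
    return [
        MutatedResidue(
            accession=accs[i], position=int(positions[i]), wt_residue=wts[i],
            is_pathogenic=bool(pathog[i]),
            nearby_ptm={k: bool(f[i]) for k, f in zip(keys, flags)},
        )
        for i in range(len(accs))
    ]


def _results_from_masks(path_mask: np.ndarray, near: dict, n_instances: dict,
                        mod_types, window: int,
                        n_foreground_proteins: int) -> list[EnrichmentResult]:
    n_path = int(path_mask.sum())
    n_non = int(path_mask.size - n_path)
    results = []
    for t in mod_types:
        flags = near[(t, window)]
        a = int((flags & path_mask).sum())
        c = int((flags & ~path_mask).sum())
        table = ContingencyTable(a, n_path - a, c, n_non - c)
        testable = n_instances[t] > 0
        p = fisher_exact_one_sided(table) if testable else float("nan")
        results.append(
            EnrichmentResult(
                mod_type=t, window=window, table=table,
                odds_ratio=table.odds_ratio(), p=p, q=float("nan"),
                n_foreground_proteins=n_foreground_proteins, testable=testable,
            )
        )
    testable_idx = [i for i, r in enumerate(results) if r.testable]
    qs = bh_fdr([results[i].p for i in testable_idx])
    for i, q in zip(testable_idx, qs):
        results[i].q = q
    results.sort(key=lambda r: (not r.testable, r.q if r.testable else 1.0,
                                r.mod_type))
    return results


def test_enrichment(records: Proteome, source: str = "dbsnp",
                    mod_types=CORE_MOD_TYPES, window: int = 8,
                    protein_subset: set[str] | None = None) -> list[EnrichmentResult]:
    """Windowed PTM-proximity enrichment of pathogenic mutated residues.

    Foreground = pathogenic residues, background = all other mutated
    residues, both inside the bias-controlled protein set (by default
    :func:`pathogenic_protein_set` of the same source). Per modification
    type: a 2x2 [pathogenic x nearby-PTM] table, one-sided Fisher's exact
    test, and BH q across the tested types; results sorted by q. Types with
    zero PTM instances in the subset are flagged untestable (NaN p/q) rather
    than silently dropped.
    """
    mod_types = tuple(mod_types)
    if protein_subset is None:
        protein_subset = pathogenic_protein_set(records, source)
    if not protein_subset:
        raise EmptyForegroundError(
            f"no protein carries a {PATHOGENIC_CATEGORY[source]!r} mutation"
        )
    _, _, _, path_mask, near, n_instances = _residue_arrays(
        records, protein_subset, source, mod_types, (window,)
    )
    if path_mask.size == 0 or not path_mask.any():
        raise EmptyForegroundError("no pathogenic mutated residues in subset")
    return _results_from_masks(path_mask, near, n_instances, mod_types,
                               window, len(protein_subset))


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """EnrichmentResult list as a tidy table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "mod_type": r.mod_type, "window": r.window,
                "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                "odds_ratio": r.odds_ratio, "p": r.p, "q": r.q,
                "n_foreground_proteins": r.n_foreground_proteins,
                "testable": r.testable,
            }
            for r in results
        ]
    )


def rank_mutations_by_nearby_ptms(records: Proteome, window: int = 8,
                                  source: str | None = None) -> pd.DataFrame:
    """Rank mutated residues by how many modifications fall in their window.

    Counts modification instances of ANY type within ``window`` of each
    unique mutated residue (optionally restricted to mutations of one
    ``source``). Sorted by count descending, ties broken by
    (accession, position). Columns: accession, position, wt_residue,
    is_pathogenic, n_nearby_ptms.
    """
    rows = []
    for acc in sorted(records):
        rec = records[acc]
        muts = [m for m in rec.mutations if source is None or m.source == source]
        if not muts:
            continue
        by_pos: dict[int, bool] = {}
        for m in muts:
            by_pos[m.position] = by_pos.get(m.position, False) or m.is_pathogenic
        ptm_pos = np.fromiter(
            sorted(m.position for m in rec.modifications), dtype=np.int64
        )
        for pos in sorted(by_pos):
            if ptm_pos.size:
                lo = np.searchsorted(ptm_pos, pos - window, side="left")
                hi = np.searchsorted(ptm_pos, pos + window, side="right")
                n_near = int(hi - lo)
            else:
                n_near = 0
            rows.append((acc, pos, rec.sequence[pos - 1], by_pos[pos], n_near))
    df = pd.DataFrame(
        rows, columns=["accession", "position", "wt_residue", "is_pathogenic",
                       "n_nearby_ptms"]
    )
    df = df.sort_values(
        ["n_nearby_ptms", "accession", "position"],
        ascending=[False, True, True], kind="mergesort",
    ).reset_index(drop=True)
    return df
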