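"""Statistical primitives shared by every analysis stage.

The workhorse is the one-sided (enrichment-tail) Fisher's exact test: with
the margins of a 2x2 table fixed, the count ``a`` of foreground items carrying
the feature follows a hypergeometric law, and the p-value is
``P[X >= a]``. The survival function is evaluated through log-gamma terms, so
tables with totals up to ~1e6 are numerically stable. Multiplicity is handled
with Benjamini–Hochberg q-values, applied within each analysis family (the
six modification types; the twenty amino acids), never pooled across
families.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTableError
from .models import AA_ALPHABET, AnnotationCounts, ContingencyTable

__all__ = [
    "fisher_exact_one_sided",
    "bh_fdr",
    "annotation_counts",
    "annotation_correlations",
    "study_bias_test",
    "aa_bias_test",
]


def _as_table(t) -> ContingencyTable:
    if isinstance(t, ContingencyTable):
        return t
    return ContingencyTable(*t)


def fisher_exact_one_sided(t: ContingencyTable | tuple) -> float:
    """Right-tail Fisher's exact p-value for a 2x2 table.

    Returns ``P[X >= a]`` for hypergeometric X with population ``a+b+c+d``,
    ``a+c`` feature carriers and ``a+b`` draws. Equals exactly 1 when ``a``
    sits at its minimum feasible value (in particular ``a == 0``).
    """
    t = _as_table(t)
    n = t.total
    if n == 0:
        raise DegenerateTableError("all-zero contingency table")
    p = float(sps.hypergeom.sf(t.a - 1, n, t.a + t.c, t.a + t.b))
    return min(p, 1.0)


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, returned in input order."""
    ps = list(pvalues)
    if not ps:
        return []
    arr = np.asarray(ps, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


# ---------------------------------------------------------------------------
# Annotation-count statistics (study bias)

_COUNT_VARS = ("n_go", "n_mutations", "n_ptms", "length")


def annotation_counts(records, source: str = "dbsnp") -> list[AnnotationCounts]:
    """Per-protein annotation tallies over a parsed proteome."""
    out = []
    for acc in records:
        r = records[acc]
        muts = [m for m in r.mutations if m.source == source]
        out.append(
            AnnotationCounts(
                accession=acc,
                n_go=len(r.go_terms),
                n_mutations=len(muts),
                n_ptms=len(r.modifications),
                length=r.length,
                has_pathogenic=any(m.is_pathogenic for m in muts),
            )
        )
    return out


def _pairwise(df: pd.DataFrame, method: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    corr = {"pearson": sps.pearsonr, "spearman": sps.spearmanr}[method]
    k = len(_COUNT_VARS)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i, vi in enumerate(_COUNT_VARS):
        for j, vj in enumerate(_COUNT_VARS):
            if j < i:
                continue
            x, y = df[vi].to_numpy(float), df[vj].to_numpy(float)
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # zero variance: undefined, left NaN
            res = corr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = list(_COUNT_VARS)
    return pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx)


def annotation_correlations(counts: Iterable[AnnotationCounts], method: str = "pearson"):
    """Pairwise correlations among per-protein annotation counts and length.

    Computed on the full protein set and again on the subset carrying a
    pathogenic mutation (mirroring the red/blue split of well-studied versus
    other proteins). Returns a dict with ``r``/``p`` DataFrames for both.
    Pairs with a zero-variance member are NaN.
    """
    rows = [(c.n_go, c.n_mutations, c.n_ptms, c.length, c.has_pathogenic) for c in counts]
    if len(rows) < 3:
        raise ValueError("need at least 3 proteins for correlation analysis")
    df = pd.DataFrame(rows, columns=[*_COUNT_VARS, "has_pathogenic"])
    r_all, p_all = _pairwise(df, method)
    sub = df[df["has_pathogenic"]]
    if len(sub) >= 3:
        r_path, p_path = _pairwise(sub, method)
    else:
        r_path = p_path = None
    return {"r": r_all, "p": p_all, "r_pathogenic": r_path, "p_pathogenic": p_path,
            "n": len(df), "n_pathogenic": int(df["has_pathogenic"].sum())}


def study_bias_table(counts: Iterable[AnnotationCounts], annotation: str,
                     threshold: int = 10) -> ContingencyTable:
    """2x2 table [has pathogenic mutation x (annotation count >= threshold)]."""
    attr = {"go": "n_go", "ptm": "n_ptms", "mutations": "n_mutations"}[annotation]
    a = b = c = d = 0
    for ct in counts:
        rich = getattr(ct, attr) >= threshold
        if ct.has_pathogenic:
            a, b = a + rich, b + (not rich)
        else:
            c, d = c + rich, d + (not rich)
    return ContingencyTable(a, b, c, d)


def study_bias_test(counts: Iterable[AnnotationCounts], annotation: str,
                    threshold: int = 10) -> float:
    """One-sided Fisher p for pathogenic-mutation proteins being annotation-rich.

    Tests whether proteins with at least one pathogenic mutation are enriched
    among proteins with at least ``threshold`` annotations of the given kind
    (``'go'`` or ``'ptm'``), over the full proteome.
    """
    return fisher_exact_one_sided(study_bias_table(list(counts), annotation, threshold))


# ---------------------------------------------------------------------------
# Amino-acid composition bias


def aa_bias_test(foreground_residues: Iterable[str],
                 background_residues: Iterable[str]) -> pd.DataFrame:
    """Per-amino-acid enrichment of the foreground residue multiset.

    For each of the 20 amino acids, a one-sided Fisher's exact test on
    [foreground vs background x is-this-AA vs not], BH-corrected across the
    20 tests. Returns a DataFrame indexed by amino acid, sorted by p then q,
    with columns a, b, c, d, odds_ratio, p, q.
    """
    fg = Counter(foreground_residues)
    bg = Counter(background_residues)
    n_fg, n_bg = sum(fg.values()), sum(bg.values())
    if n_fg == 0 or n_bg == 0:
        raise ValueError("both residue multisets must be non-empty")
    rows = []
    for aa in AA_ALPHABET:
        t = ContingencyTable(fg[aa], n_fg - fg[aa], bg[aa], n_bg - bg[aa])
        rows.append((aa, t.a, t.b, t.c, t.d, t.odds_ratio(), fisher_exact_one_sided(t)))
    df = pd.DataFrame(rows, columns=["aa", "a", "b", "c", "d", "odds_ratio", "p"])
    df["q"] = bh_fdr(df["p"].tolist())
    df = df.set_index("aa").sort_values(["p", "q"], kind="mergesort")
    return df
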