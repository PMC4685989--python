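"""Independent reference implementations used only to check the package.

These deliberately share no code with ptmvar: the Fisher oracle enumerates
hypergeometric tables with exact integer arithmetic, the proximity oracle is
a quadratic scan over all (mutation, modification) pairs, and the BH oracle
follows the step-up definition literally.
"""

from fractions import Fraction
from math import comb


def fisher_one_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Right-tail Fisher p by exhaustive enumeration with exact fractions."""
    n_fg, k_feat, n = a + b, a + c, a + b + c + d
    a_max = min(k_feat, n_fg)
    num = sum(comb(n_fg, x) * comb(n - n_fg, k_feat - x)
              for x in range(a, a_max + 1))
    return float(Fraction(num, comb(n, k_feat)))


def bh_oracle(pvalues):
    """Benjamini–Hochberg step-up, literal definition, input order kept."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


def nearby_oracle(record, position, mod_type, window):
    """Quadratic scan: any modification of mod_type within |delta| <= window."""
    return any(
        m.mod_type == mod_type and abs(m.position - position) <= window
        for m in record.modifications
    )


def collect_oracle(records, subset, source, mod_types, windows):
    """Residue-unique recount by brute force.

    Returns {(accession, position): (wt, is_pathogenic, {(type, w): bool})}.
    """
    out = {}
    for acc in subset:
        rec = records.resolve(acc)
        for m in rec.mutations:
            if m.source != source:
                continue
            key = (rec.primary_accession, m.position)
            wt, flag, flags = out.get(
                key,
                (rec.sequence[m.position - 1], False,
                 {(t, w): nearby_oracle(rec, m.position, t, w)
                  for t in mod_types for w in windows}),
            )
            out[key] = (wt, flag or m.is_pathogenic, flags)
    return out


def rank_oracle(records, window):
    """Brute-force count of all modifications near each mutated residue."""
    rows = {}
    for acc in records:
        rec = records[acc]
        for m in rec.mutations:
            key = (acc, m.position)
            n_near = sum(
                1 for mod in rec.modifications
                if abs(mod.position - m.position) <= window
            )
            prev = rows.get(key)
            pathog = m.is_pathogenic or (prev[1] if prev else False)
            rows[key] = (rec.sequence[m.position - 1], pathog, n_near)
    return rows
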