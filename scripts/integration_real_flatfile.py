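#!/usr/bin/env python
"""Optional integration run against a real protein annotation download.

Not part of the test suite: it requires an externally obtained
ProteomeScout-style flat file (and optionally a UniProt humsavar release),
converted to the dialect documented in ptmvar.flatfile. Prints the analysis-
set counts and the per-type enrichment report for windows 0 and 8 so they
can be compared against published values.

Usage::

    python scripts/integration_real_flatfile.py --flatfile FILE \
        [--humsavar FILE] [--source dbsnp|humsavar]
"""

import argparse

from ptmvar.enrichment import (
    collect_mutated_residues,
    enrichment_to_frame,
    pathogenic_protein_set,
    test_enrichment,
)
from ptmvar.flatfile import parse_flatfile
from ptmvar.humsavar import crossref, disease_fraction, parse_humsavar


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--flatfile", required=True)
    parser.add_argument("--humsavar", default=None)
    parser.add_argument("--source", choices=["dbsnp", "humsavar"],
                        default="dbsnp")
    args = parser.parse_args()

    records = parse_flatfile(args.flatfile)
    print(f"{len(records)} protein records parsed")
    if args.humsavar:
        variants = parse_humsavar(args.humsavar)
        overall = disease_fraction(variants)
        restricted = disease_fraction(variants, restrict_to_disease_proteins=True)
        print(f"humsavar: {overall['n_total']} variants, "
              f"{overall['n_disease']} Disease "
              f"({100 * overall['fraction']:.0f}%); restricted to "
              f"disease proteins: {100 * restricted['fraction']:.0f}%")
        records, report = crossref(variants, records)
        print(f"crossref: {report.n_matched} matched, "
              f"{report.n_residue_mismatch} residue mismatches, "
              f"{report.n_accession_unmatched} accession unmatched")

    subset = pathogenic_protein_set(records, args.source)
    print(f"{len(subset)} proteins with a pathogenic/Disease mutation "
          f"({args.source})")
    residues = collect_mutated_residues(records, subset, args.source)
    n_path = sum(r.is_pathogenic for r in residues)
    n_ptms = sum(len(records.resolve(a).modifications) for a in subset)
    print(f"analysis set: {len(residues)} mutated residues "
          f"({n_path} pathogenic), {n_ptms} PTMs")
    for window in (0, 8):
        print(f"\nwindow {window}:")
        df = enrichment_to_frame(
            test_enrichment(records, source=args.source, window=window))
        print(df.to_string(index=False))


if __name__ == "__main__":
    main()
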