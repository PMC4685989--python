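# Methods

## The question and the counting rule

The package tests whether pathogenic missense mutations are enriched within
a linear-sequence window of post-translational modification sites. All
counting is residue-unique: annotations are collapsed onto (protein,
position) pairs before any statistic is computed. A residue hit by several
recorded mutations contributes once, and it is pathogenic if at least one of
its mutations is (OR-collapse). "Within *w* amino acids" is |Δ| ≤ *w*
**including** Δ = 0, so the window-8 feature subsumes the on-site (window-0)
feature; the two windows are tested separately. Windows clip at sequence
termini — no padding, no wrap.

Positions are 1-based on the mature sequence, counting the initiator
methionine as position 1, in both file dialects and the API.

## Study-bias control

Proteins carrying a known pathogenic mutation are systematically better
annotated — more GO terms, more PTMs, more mutations of every kind — which
would confound any naive foreground/background comparison
(`stats.study_bias_test` quantifies this on a 2×2 of
[has-pathogenic × annotation count ≥ 10], and `annotation_correlations`
shows the count/length correlations). The control is a strict filter: both
foreground (pathogenic residues) and background (all other mutated
residues) are restricted to proteins with ≥ 1 pathogenic mutation, so the
two groups share the same study-intensity distribution. The background
deliberately includes unannotated mutations: the 2×2 rows are "pathogenic"
versus "everything else", which keeps them disjoint and exhaustive.

## The test

Per modification type: a one-sided (enrichment-tail) Fisher's exact test,
p = P[X ≥ a] for hypergeometric X with the table's margins fixed, evaluated
through the log-gamma-based hypergeometric survival function so totals up
to ~10⁶ residues are stable; p is exactly 1 when a is at its minimum
feasible value. Multiplicity within the family of tested modification types
is corrected with Benjamini–Hochberg q-values; families are never pooled
(the six core types form one family, the twenty amino acids of the
composition test another). Both raw p and q are always reported. Types with
zero modification instances inside the bias-controlled subset are flagged
untestable (NaN p/q) rather than assigned p = 1 or dropped: a test that
could not run is different from a negative result.

The core vocabulary is Phosphoserine, Phosphothreonine, Phosphotyrosine,
Ubiquitination, N6-acetyllysine and N-Glycosylation — the types with enough
annotations for per-type testing; anything else is preserved as
`Other:<label>` and excluded from per-type tests by default (it still
counts in the any-type ranking).

## Composition-matched resampling

Pathogenic mutations skew toward arginine (`aa_bias_test` measures this
per amino acid, BH-corrected across the 20), and residue identity is
correlated with surface exposure and modifiability, so composition alone
could in principle manufacture proximity enrichment. The control draws
pseudo-foregrounds of exactly the real foreground's size and wild-type
amino-acid composition — sampling without replacement within each residue
class — from the **non-pathogenic** residues of the bias-controlled set,
and reruns the identical per-type test with the remaining non-pathogenic
residues as background. The real pathogenic residues are excluded from the
candidate pool: the control asks whether composition alone produces
enrichment, and contaminating candidates with truly co-localized residues
would bias it toward the alternative. Default 10 trials; each trial's
generator is seeded `master_seed + 1 + trial`, all logged in the report,
and every draw is audited against the exact target composition.

One caveat worth knowing: when a strong true effect includes on-site hits
(Δ = 0), the wild-type identity of modified residues (e.g. lysine for
ubiquitination) becomes mildly predictive of proximity, so
composition-matched trials run slightly hot — a property of composition
matching itself, not of the implementation; under a null proteome the
trial significance rate is nominal.

## The synthetic proteome generator

`SyntheticConfig` defaults are the package's study conditions and emulate
the scale of a well-studied disease-protein set: 2,000 proteins of 200–800
residues (i.i.d. composition, uniform by default with a Swiss-Prot-average
table available), per-eligible-residue modification rates
{pS 0.15, pT 0.08, pY 0.08, Ub 0.12, acK 0.08, N-gly 0.08} (~15–20 sites
per protein), per-residue mutation rate 0.05 (~25 mutations per protein),
base pathogenic-label probability 0.05. That yields bias-controlled sets of
roughly a thousand proteins with a few percent pathogenic residues —
comparable in order of magnitude to real disease-protein analysis sets.

Structure the generator plants, and nothing else:

- modifications only on chemically eligible residues (S/T/Y/K/K/N), at most
  one per residue (types competing for the same chemistry, e.g.
  ubiquitination vs acetylation on lysine, exclude each other, in core-type
  order);
- mutation probability multiplied by `arginine_skew` at arginines
  (emulating the arginine excess among disease mutations);
- a pathogenic label with probability `base_pathogenic_prob`, multiplied by
  the relative risk `rho` when the residue lies within `window_w` of a
  modification of one of `rho_mod_types` (capped at 1 with a warning);
  `rho = 1` is the exact null;
- optionally a second, distinct substitution on a mutated residue
  (`multi_mutation_prob`, default 0.02), labeled independently — collapse
  is the pipeline's job, the generator never pre-collapses;
- GO terms i.i.d. Poisson (mean 8) per protein.

Deliberately absent: sequence motifs (no N-X-S/T sequon), domains, protein
families, disorder, realistic mutation spectra beyond the arginine knob,
and annotation-intensity differences between proteins. Passing tests
therefore demonstrate the statistics behave correctly under the stated
sampling model — exact null calibration, recovery and specificity of a
planted effect, exact agreement with brute-force counting — not that any
particular biological dataset will show an effect. Every planted fact is
returned in a ground-truth ledger sufficient to recompute any pipeline
statistic independently.

## File dialects

The protein flat file is a documented ProteomeScout-**like** TSV dialect
(header row; `"; "`-separated annotation tokens; `"S 259-Phosphoserine"`
modifications; `"V263A:pathogenic"` mutations): the analysis depends only
on these fields, and the package does not claim byte-compatibility with any
particular ProteomeScout release, whose exact schema lives outside the
file itself. A thin adapter for a real release is future work
(`scripts/integration_real_flatfile.py` is the entry point for that).

The variant index is UniProt-humsavar-style whitespace-aligned text. Data
rows are recognized by their `VAR_NNNNNN` id and `p.Xaa123Xaa` change token
(three-letter codes mapped to one-letter); preamble and footer lines are
skipped; non-missense changes (deletions, frameshifts, extensions) are
skipped with a tally. Category matching is on the exact 2015-era tokens
`Disease` / `Polymorphism` / `Unclassified`, case-sensitive; newer
vocabularies (`LP/P`, `LB/B`) are folded in only through an explicit
`category_map`, because silent remapping would change what "disease
fraction" means across releases. Accessions are used verbatim — an isoform
suffix (`P04049-2`) is a distinct accession.

Cross-referencing attaches a variant to a record when the accession
resolves (primary or alternate; attribution is always to the primary
record) **and** the wild-type residue matches the sequence at that
position; every input variant lands in exactly one bucket of the mapping
report (matched / residue-mismatch / accession-unmatched). On parsing,
tokens violating residue or position invariants are dropped with logged
counts in lenient mode (isoform and version mismatches are expected in real
data) or abort the parse in strict mode; identical duplicate tokens are
de-duplicated.

## Numerical and design details

- Correlation flavor: Pearson on raw counts by default (the count/length
  relationships are approximately linear), Spearman by option; large-sample
  p-values. Zero-variance pairs yield NaN rather than an arbitrary value.
- Odds ratio of a 2×2: (a·d)/(b·c), +inf when only the denominator is 0,
  NaN when both are.
- Ranking ties (equal nearby-modification counts) break deterministically
  by (accession, position); the ranking counts modification instances of
  any type, so two different modifications at one position count twice.
- Enrichment results are sorted by q (untestable types last); residue
  totals are conserved across types at a fixed window (a+b and c+d are the
  foreground/background sizes, identical for every type).
- Output manifests embed tool version, input SHA-256 digests, parameters
  and seed, but no timestamp: reruns on identical inputs must be
  byte-identical, so wall-clock time goes to the log stream only.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; fixing the seed fixes every downstream number, including file
  bytes.
- Degenerate inputs are explicit signals, not silent defaults: an all-zero
  table, an empty variant list, an empty foreground, an infeasible
  composition target (which names the short residue class and suggests
  proportional downsampling) each raise a dedicated exception.

## Validation strategy and problem sizes

The test suite checks the statistics against independent oracles: Fisher
p-values against exact integer enumeration (exhaustive for all tables with
total ≤ 24, plus a seeded sweep to total 60, at 1e-12 absolute), BH against
a literal step-up implementation, and the counting pipeline against a
quadratic scan over all (mutation, modification) pairs on ≤ 50-protein
fixtures, including the |Δ| = 8/9 boundary and OR-collapse. Calibration
uses 200 seeded null proteomes (ρ = 1, arginine skew 3, 2,000 proteins
each) and effect recovery 100 seeded runs (ρ = 8 on ubiquitination only,
base 0.01) — sizes chosen so the full suite completes in a few minutes on
one CPU while leaving the binomial noise on the measured rates well inside
the asserted bands. The acceptance script reuses these regimes at 60 and
40 runs respectively.

## Known limitations

- The generator's i.i.d. sequences lack compositional autocorrelation
  (real sequences have low-complexity regions and domains), which makes
  the composition-matched control slightly better behaved than on real
  proteomes.
- The bias-control strategy conditions on having ≥ 1 pathogenic mutation;
  it does not model *degrees* of study intensity within that set.
- Window proximity is linear-sequence only; structural adjacency and
  surface accessibility are out of scope (the composition control is the
  only guard against surface-exposure confounding).
- Only simple missense substitutions are analyzed; indels and frameshifts
  are skipped at parse time.
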