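"""Synthetic proteome generator with planted ground truth.

Sequences are i.i.d. draws from a configurable amino-acid composition;
modifications land only on chemically eligible residues (S for
phosphoserine, K for ubiquitination and acetylation, N for N-glycosylation,
...) at a per-type, per-eligible-residue rate; mutations land per residue at
``mutation_rate``, multiplied by ``arginine_skew`` on arginines to emulate
the arginine excess among disease mutations. A mutation is labeled
pathogenic with probability ``base_pathogenic_prob`` — multiplied by the
relative risk ``rho`` when the residue lies within ``window_w`` of a
modification of one of ``rho_mod_types``. ``rho=1`` is the null; larger
values plant a PTM-proximity/pathogenicity co-localization of known size.

Defaults emulate the scale of a well-studied human disease-protein set
(~500-residue proteins carrying a few dozen mutations and ~15-20 modification
sites each, ~5-9%% of mutations pathogenic). Sequence motifs, domains and
protein families are deliberately absent: the statistics under test never
consult them, and leaving them out keeps the planted truth exact.

Every planted fact (mutation labels, near-PTM status at generation time) is
returned in a ground-truth ledger sufficient to recompute any pipeline
statistic independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .flatfile import Proteome
from .models import (
    AA_ALPHABET,
    CORE_MOD_TYPES,
    MOD_RESIDUE,
    HumsavarVariant,
    Modification,
    Mutation,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

_AA_BYTES = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: Swiss-Prot average amino-acid frequencies (percent), normalized on use.
HUMAN_AA_FREQS = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}

DEFAULT_PTM_RATE = {
    "Phosphoserine": 0.15,
    "Phosphothreonine": 0.08,
    "Phosphotyrosine": 0.08,
    "Ubiquitination": 0.12,
    "N6-acetyllysine": 0.08,
    "N-Glycosylation": 0.08,
}


@dataclass(slots=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the package's study conditions."""

    n_proteins: int = 2000
    length_range: tuple[int, int] = (200, 800)
    #: AA -> probability; None = uniform over the 20 amino acids.
    aa_composition: dict[str, float] | None = None
    #: mod_type -> probability per chemically eligible residue.
    ptm_rate: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PTM_RATE))
    mutation_rate: float = 0.05
    base_pathogenic_prob: float = 0.05
    #: relative risk of a pathogenic label near a PTM; 1 = null.
    rho: float = 1.0
    #: which PTM types carry the rho boost; None = all generated types.
    rho_mod_types: tuple[str, ...] | None = None
    window_w: int = 8
    arginine_skew: float = 1.0
    #: probability a non-pathogenic mutation is labeled 'non-pathogenic'
    #: rather than left unannotated.
    nonpathogenic_annot_prob: float = 0.3
    #: probability a mutated residue carries a second, distinct substitution
    #: (labeled independently — collapse is the pipeline's job, not ours).
    multi_mutation_prob: float = 0.02
    #: mean number of GO terms per protein (Poisson).
    go_mean: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length_range {self.length_range}")
        for name in ("mutation_rate", "base_pathogenic_prob",
                     "nonpathogenic_annot_prob", "multi_mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for t, r in self.ptm_rate.items():
            if t not in MOD_RESIDUE:
                raise ValueError(f"unknown mod_type {t!r} in ptm_rate")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"ptm_rate[{t!r}]={r} must lie in [0, 1]")
        if self.rho < 0 or self.arginine_skew < 0 or self.go_mean < 0:
            raise ValueError("rho, arginine_skew and go_mean must be >= 0")
        if self.aa_composition is not None:
            if set(self.aa_composition) != set(AA_ALPHABET):
                raise ValueError("aa_composition must cover exactly the 20 amino acids")
            total = math.fsum(self.aa_composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"aa_composition sums to {total}, not 1")
        if self.rho * self.base_pathogenic_prob > 1.0:
            logger.warning(
                "rho * base_pathogenic_prob = %.3g exceeds 1; boosted label "
                "probability will be capped at 1",
                self.rho * self.base_pathogenic_prob,
            )


@dataclass(frozen=True, slots=True)
class PlantedMutation:
    """One generated mutation with the facts that produced its label."""

    accession: str
    position: int
    wt_residue: str
    mut_residue: str
    category: str
    near_rho_ptm: bool


@dataclass(slots=True)
class GroundTruth:
    """Everything the generator planted, for independent recomputation."""

    config: SyntheticConfig
    mutations: list[PlantedMutation] = field(default_factory=list)

    def pathogenic_accessions(self) -> set[str]:
        return {m.accession for m in self.mutations if m.category == "pathogenic"}

    def near_far_rates(self) -> tuple[float, float]:
        """Empirical P(pathogenic | near rho-PTM) and P(pathogenic | far)."""
        near_n = near_k = far_n = far_k = 0
        for m in self.mutations:
            if m.near_rho_ptm:
                near_n += 1
                near_k += m.category == "pathogenic"
            else:
                far_n += 1
                far_k += m.category == "pathogenic"
        return (near_k / near_n if near_n else float("nan"),
                far_k / far_n if far_n else float("nan"))

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("accession\tposition\twt\tmut\tcategory\tnear_rho_ptm\n")
            for m in self.mutations:
                fh.write(
                    f"{m.accession}\t{m.position}\t{m.wt_residue}\t"
                    f"{m.mut_residue}\t{m.category}\t{int(m.near_rho_ptm)}\n"
                )


def _other_residue(rng: np.random.Generator, wt_idx: int,
                   exclude_idx: int | None = None) -> int:
    """A residue index != wt (and != exclude when given), uniform."""
    while True:
        r = int(rng.integers(0, 20))
        if r != wt_idx and r != exclude_idx:
            return r


def generate_proteome(config: SyntheticConfig) -> tuple[Proteome, GroundTruth]:
    """Generate a proteome and its ground-truth ledger. Deterministic in seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.aa_composition is None:
        probs = None
    else:
        probs = np.array([config.aa_composition[aa] for aa in AA_ALPHABET])
        probs = probs / probs.sum()
    rho_types = tuple(config.rho_mod_types) if config.rho_mod_types is not None \
        else tuple(t for t in CORE_MOD_TYPES if config.ptm_rate.get(t, 0) > 0)
    r_idx = _AA_INDEX["R"]
    proteome = Proteome()
    truth = GroundTruth(config=config)
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    go_counts = rng.poisson(config.go_mean, size=config.n_proteins)
    for i in range(config.n_proteins):
        acc = f"SYN{i + 1:05d}"
        L = int(lengths[i])
        if probs is None:
            seq_idx = rng.integers(0, 20, size=L)
        else:
            seq_idx = rng.choice(20, size=L, p=probs)
        sequence = _AA_BYTES[seq_idx].tobytes().decode("ascii")

        mods: list[Modification] = []
        rho_ptm_pos: list[np.ndarray] = []
        # a residue carries at most one modification: types competing for the
        # same residue chemistry (ubiquitination vs acetylation on lysine)
        # exclude each other, in CORE_MOD_TYPES order
        occupied = np.zeros(L, dtype=bool)
        for t in CORE_MOD_TYPES:
            rate = config.ptm_rate.get(t, 0.0)
            if rate <= 0:
                continue
            elig = np.flatnonzero((seq_idx == _AA_INDEX[MOD_RESIDUE[t]]) & ~occupied)
            hit0 = elig[rng.random(elig.size) < rate]
            occupied[hit0] = True
            hit = hit0 + 1  # 1-based
            mods.extend(
                Modification(residue=MOD_RESIDUE[t], position=int(p), mod_type=t)
                for p in hit
            )
            if t in rho_types:
                rho_ptm_pos.append(hit)
        mods.sort(key=lambda m: (m.position, m.mod_type))
        rho_pos = (np.sort(np.concatenate(rho_ptm_pos))
                   if rho_ptm_pos else np.zeros(0, dtype=np.int64))

        p_mut = np.full(L, config.mutation_rate)
        if config.arginine_skew != 1.0:
            p_mut[seq_idx == r_idx] = min(
                1.0, config.mutation_rate * config.arginine_skew)
        mut_pos0 = np.flatnonzero(rng.random(L) < p_mut)  # 0-based
        if rho_pos.size and mut_pos0.size:
            pos1 = mut_pos0 + 1
            w = config.window_w
            near = (np.searchsorted(rho_pos, pos1 - w, side="left")
                    < np.searchsorted(rho_pos, pos1 + w, side="right"))
        else:
            near = np.zeros(mut_pos0.size, dtype=bool)

        p_path = np.where(
            near,
            min(1.0, config.base_pathogenic_prob * config.rho),
            config.base_pathogenic_prob,
        )
        n_mut = mut_pos0.size
        wt_i = seq_idx[mut_pos0]
        # uniform over the 19 residues != wt
        r = rng.integers(0, 19, size=n_mut)
        first_i = r + (r >= wt_i)
        second = rng.random(n_mut) < config.multi_mutation_prob
        pathogenic1 = rng.random(n_mut) < p_path
        annot1 = rng.random(n_mut) < config.nonpathogenic_annot_prob
        pathogenic2 = rng.random(n_mut) < p_path
        annot2 = rng.random(n_mut) < config.nonpathogenic_annot_prob
        mutations: list[Mutation] = []
        for j in range(n_mut):
            picks = [(int(first_i[j]), bool(pathogenic1[j]), bool(annot1[j]))]
            if second[j]:
                picks.append(
                    (_other_residue(rng, int(wt_i[j]), int(first_i[j])),
                     bool(pathogenic2[j]), bool(annot2[j]))
                )
            for mut_i, pathogenic, annot in picks:
                if pathogenic:
                    category = "pathogenic"
                elif annot:
                    category = "non-pathogenic"
                else:
                    category = "unannotated"
                mutations.append(
                    Mutation(
                        position=int(mut_pos0[j]) + 1,
                        wt_residue=AA_ALPHABET[int(wt_i[j])],
                        mut_residue=AA_ALPHABET[mut_i],
                        clinical_significance=category, source="dbsnp",
                    )
                )
                truth.mutations.append(
                    PlantedMutation(
                        accession=acc, position=int(mut_pos0[j]) + 1,
                        wt_residue=AA_ALPHABET[int(wt_i[j])],
                        mut_residue=AA_ALPHABET[mut_i],
                        category=category, near_rho_ptm=bool(near[j]),
                    )
                )

        go_terms = [
            f"GO:{int(g):07d}"
            for g in np.sort(rng.integers(1, 10_000_000, size=int(go_counts[i])))
        ]
        proteome.add(
            ProteinRecord(
                primary_accession=acc,
                sequence=sequence,
                alt_accessions=[f"ALT{i + 1:05d}"],
                gene_name=f"GEN{i + 1:05d}",
                species="synthetic",
                modifications=mods,
                mutations=mutations,
                go_terms=sorted(set(go_terms)),
            )
        )
    return proteome, truth


# ---------------------------------------------------------------------------
# Writers (flat-file writing lives in flatfile.py; re-exported for symmetry)

from .flatfile import write_flatfile  # noqa: E402  (public re-export)

_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}

_CATEGORY_MAP = {
    "pathogenic": "Disease",
    "non-pathogenic": "Polymorphism",
    "unannotated": "Unclassified",
}


def write_humsavar(records: Proteome | dict, path) -> list[HumsavarVariant]:
    """Write every dbSNP-sourced mutation as a humsavar-style data row.

    Categories map pathogenic -> Disease, non-pathogenic -> Polymorphism,
    unannotated -> Unclassified. A short preamble and footer are emitted so
    parsers must demonstrate block detection. Returns the variants written,
    in file order.
    """
    written: list[HumsavarVariant] = []
    ftid_counter = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("Synthetic human polymorphisms and disease mutations\n")
        fh.write("\n")
        fh.write("Gene      AC         FTId         Change         Category"
                 "       dbSNP        Disease name\n")
        fh.write("_" * 90 + "\n")
        for acc in sorted(records):
            rec = records[acc]
            for m in sorted(
                (m for m in rec.mutations if m.source == "dbsnp"),
                key=lambda m: (m.position, m.mut_residue),
            ):
                ftid_counter += 1
                ftid = f"VAR_{ftid_counter:06d}"
                category = _CATEGORY_MAP[m.clinical_significance]
                change = (f"p.{_ONE_TO_THREE[m.wt_residue]}{m.position}"
                          f"{_ONE_TO_THREE[m.mut_residue]}")
                disease = ("Synthetic disorder" if category == "Disease" else "-")
                fh.write(
                    f"{rec.gene_name:<9} {rec.primary_accession:<10} "
                    f"{ftid:<12} {change:<14} {category:<14} {'-':<12} "
                    f"{disease}\n"
                )
                written.append(
                    HumsavarVariant(
                        gene=rec.gene_name, accession=rec.primary_accession,
                        ftid=ftid, position=m.position,
                        wt_residue=m.wt_residue, mut_residue=m.mut_residue,
                        category=category, dbsnp_id="",
                        disease_name="" if disease == "-" else disease,
                    )
                )
        fh.write("-" * 90 + "\n")
        fh.write(f"{len(written)} variants listed.\n")
    return written
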