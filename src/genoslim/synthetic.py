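"""Synthetic genomes, reference proteomes, and toy metabolic models.

The generators emulate the structure of the real design problem — an
ordered bacterial gene annotation with interspersed essential genes, a
closely related reference proteome with known orthology, and a metabolic
model whose GPRs make planted regions growth-neutral while their flanks
are growth-essential — so every pipeline stage is testable with known
ground truth and without downloads.

Planted dispensable regions are gene-index windows that the generator
guarantees to be the maximal runs of non-essential genes: the genes
immediately flanking each planted window are forced essential, and
non-planted runs of non-essential genes are capped at a few genes.

All generators are pure functions of their spec and seed; each draws
from its own RNG stream derived from the seed by a fixed offset, so
adding one generator never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .annotation import GeneFeature, GenomeAnnotation
from .errors import ValidationError
from .homology import DISPENSABLE, ESSENTIAL, EssentialityMap
from .models import ModelDocument, Reaction

_AA = "ACDEFGHIKLMNPQRSTVWY"

# back-translation table (NCBI table 11, bacterial)
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE11.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_TABLE11.stop_codons)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SynthesisSpec:
    """Parameters of one synthetic study genome.

    ``planted_regions`` are inclusive gene-index windows (start, end)
    that will be dispensable ground truth; they must leave room for an
    essential flanking gene on each side.  ``max_background_run`` caps
    the length (in genes) of non-essential runs outside planted regions
    so the planted windows are the unambiguous longest dispensable
    stretches.
    """

    n_genes: int = 120
    mean_gene_len: int = 300  # bp; proteins average ~mean_gene_len/3 residues
    intergenic_len: int = 50
    essential_fraction: float = 0.3
    planted_regions: tuple[tuple[int, int], ...] = ()
    mutation_rate: float = 0.05
    seed: int = 0
    max_background_run: int = 3
    sequence_id: str = "synchr1"

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not (0.0 <= self.essential_fraction <= 1.0):
            raise ValidationError("essential_fraction must lie in [0, 1]")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValidationError("mutation_rate must lie in [0, 1)")
        prev_end = -2
        for a, b in self.planted_regions:
            if not (1 <= a <= b <= self.n_genes - 2):
                raise ValidationError(
                    f"planted region ({a}, {b}) must fit inside [1, {self.n_genes - 2}] "
                    "to leave room for essential flanks"
                )
            if a <= prev_end + 1:
                raise ValidationError("planted regions must be separated by >= 1 gene")
            prev_end = b


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# Genome + truth
# ---------------------------------------------------------------------------


def _essentiality_labels(spec: SynthesisSpec, rng: np.random.Generator) -> np.ndarray:
    ess = rng.random(spec.n_genes) < spec.essential_fraction
    planted = np.zeros(spec.n_genes, dtype=bool)
    for a, b in spec.planted_regions:
        ess[a : b + 1] = False
        planted[a : b + 1] = True
        ess[a - 1] = True
        ess[b + 1] = True
    # cap background non-essential runs so planted regions stay maximal
    run = 0
    for i in range(spec.n_genes):
        if planted[i] or ess[i]:
            run = 0
            continue
        run += 1
        if run > spec.max_background_run:
            ess[i] = True
            run = 0
    return ess


def generate_genome(spec: SynthesisSpec) -> tuple[GenomeAnnotation, EssentialityMap]:
    """Deterministic synthetic genome with essentiality ground truth.

    Proteins are random amino-acid strings of roughly ``mean_gene_len/3``
    residues; each CDS is back-translated (table 11) into the genome
    sequence so GFF3+FASTA extraction reproduces the proteins exactly.
    """
    rng = _rng(spec.seed, 0)
    ess = _essentiality_labels(spec, rng)

    mean_aa = max(10, spec.mean_gene_len // 3 - 1)
    features: list[GeneFeature] = []
    chunks: list[str] = []
    pos = 0
    for i in range(spec.n_genes):
        gap = spec.intergenic_len
        chunks.append("".join(rng.choice(list("ACGT"), size=gap)))
        pos += gap
        n_aa = int(max(10, round(rng.normal(mean_aa, 0.15 * mean_aa))))
        protein = "M" + "".join(rng.choice(list(_AA), size=n_aa - 1))
        codons = [_CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein]
        cds = "".join(codons) + _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
        strand = "+" if rng.random() < 0.5 else "-"
        chunks.append(cds if strand == "+" else _revcomp(cds))
        start, end = pos, pos + len(cds)
        pos = end
        features.append(
            GeneFeature(
                locus_tag=f"SYN_{(i + 1) * 5:05d}",
                start=start,
                end=end,
                strand=strand,
                product="conserved hypothetical protein" if not ess[i] else "essential core protein",
                protein=protein,
            )
        )
    chunks.append("".join(rng.choice(list("ACGT"), size=spec.intergenic_len)))
    pos += spec.intergenic_len
    ann = GenomeAnnotation(spec.sequence_id, pos, features, sequence="".join(chunks))
    labels = {
        f.locus_tag: (ESSENTIAL if ess[i] else DISPENSABLE) for i, f in enumerate(features)
    }
    return ann, EssentialityMap(labels, {l: None for l in labels})


# ---------------------------------------------------------------------------
# Reference proteome
# ---------------------------------------------------------------------------


def generate_reference_proteome(
    ann: GenomeAnnotation, mutation_rate: float, seed: int
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Paired reference proteome with known orthology.

    Each reference protein is the source protein with i.i.d. residue
    substitutions at ``mutation_rate``; the returned ortholog truth maps
    each locus to its reference id and is a bijection.  Record order is
    shuffled so downstream matching cannot rely on ordering.
    """
    if not (0.0 <= mutation_rate < 1.0):
        raise ValidationError("mutation_rate must lie in [0, 1)")
    rng = _rng(seed, 1)
    records: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    for i, f in enumerate(ann.features):
        if f.protein is None:
            raise ValidationError(f"{f.locus_tag}: feature lacks a protein sequence")
        residues = list(f.protein)
        mask = rng.random(len(residues)) < mutation_rate
        for j in np.flatnonzero(mask):
            choices = _AA.replace(residues[j], "") if residues[j] in _AA else _AA
            residues[j] = choices[rng.integers(len(choices))]
        ref_id = f"REF_{(i + 1) * 5:05d}"
        records.append((ref_id, "".join(residues)))
        truth[f.locus_tag] = ref_id
    order = rng.permutation(len(records))
    return [records[k] for k in order], truth


# ---------------------------------------------------------------------------
# Toy metabolic model
# ---------------------------------------------------------------------------


def generate_toy_model(
    ann: GenomeAnnotation,
    truth: EssentialityMap,
    uptake_bound: float = 10.0,
    seed: int = 0,
    n_essential_modules: int = 8,
    n_redundant: int = 4,
) -> ModelDocument:
    """Toy model in which the truth's essential genes are growth-essential.

    Carbon enters through one uptake reaction (bounded at
    ``uptake_bound``), a constitutive backbone converts it to precursor
    P, and the essential genes are grouped into AND-GPR "module"
    reactions each producing a distinct biomass component.  Biomass
    consumes 10 carbon equivalents per unit growth, so the maximal
    growth rate is ``uptake_bound / 10`` and scales linearly with the
    bound.  Deleting any essential gene silences its module and drops
    growth to zero; non-essential genes appear only in OR-GPR reactions
    redundant with the constitutive backbone or in dead-end side
    reactions, so deleting any subset of them leaves maximal growth
    unchanged.
    """
    loci = ann.loci()
    missing = set(truth.labels) ^ set(loci)
    if missing:
        raise ValidationError("annotation and essentiality truth are inconsistent")
    rng = _rng(seed, 2)
    essentials = [l for l in loci if truth.labels[l] == ESSENTIAL]
    others = [l for l in loci if truth.labels[l] != ESSENTIAL]

    k = max(1, min(n_essential_modules, len(essentials))) if essentials else 0
    modules: list[list[str]] = [[] for _ in range(k)]
    for idx, locus in enumerate(essentials):
        modules[idx % k].append(locus)

    mets = {"C": "c", "P": "c"}
    big = 1000.0
    reactions = [
        Reaction("R_uptake", {"C": 1.0}, 0.0, uptake_bound, ""),
        Reaction("R_main", {"C": -1.0, "P": 1.0}, 0.0, big, ""),
    ]
    biomass_stoich: dict[str, float] = {}
    for j, module in enumerate(modules, start=1):
        mid = f"X{j}"
        mets[mid] = "c"
        reactions.append(
            Reaction(f"R_ess_{j}", {"C": -1.0, mid: 1.0}, 0.0, big, " and ".join(module))
        )
        biomass_stoich[mid] = -1.0
    biomass_stoich["P"] = -(10.0 - k)
    if 10.0 - k <= 0:
        raise ValidationError("n_essential_modules must be < 10")
    reactions.append(Reaction("R_bio", biomass_stoich, 0.0, big, ""))

    # non-essential genes: OR groups on redundant parallel or dead-end reactions
    shuffled = [others[i] for i in rng.permutation(len(others))]
    n_groups = max(1, min(max(n_redundant * 2, 1), len(shuffled))) if shuffled else 0
    for g in range(n_groups):
        group = shuffled[g::n_groups]
        if not group:
            continue
        gpr = " or ".join(group)
        if g < n_redundant:
            reactions.append(Reaction(f"R_dup_{g + 1}", {"C": -1.0, "P": 1.0}, 0.0, big, gpr))
        else:
            mid = f"D{g + 1 - n_redundant}"
            mets[mid] = "c"
            # dead-end product: never consumed, so steady state pins flux at 0
            reactions.append(Reaction(f"R_side_{g + 1 - n_redundant}", {"C": -1.0, mid: 1.0}, 0.0, big, gpr))

    return ModelDocument(f"toy_{ann.sequence_id}", mets, reactions, "R_bio")
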