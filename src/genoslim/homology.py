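"""Cross-strain essentiality transfer via reciprocal best hits.

Essential-gene labels measured in a well-studied reference strain are
carried over to a closely related target strain by pairing orthologs:
each protein is aligned against the other proteome (Smith–Waterman local
alignment, affine gaps, BLOSUM62), hit significance is scored with the
Karlin–Altschul E-value E = K·m·n·exp(-λS), and a pair is accepted only
if the two proteins are each other's best hit below a stringent E-value
cutoff (default 1e-10).  Loci with an accepted partner inherit the
partner's essential/dispensable label; unpaired loci stay ``unknown``.

Alignment scoring is delegated to Biopython's PairwiseAligner; an
independent brute-force dynamic program validates it in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from .annotation import AA_ALPHABET, GenomeAnnotation
from .errors import ValidationError

#: Default Karlin–Altschul parameters for gapped BLOSUM62 (open 11, extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041

#: Default bidirectional-best-hit significance cutoff.
DEFAULT_E_CUTOFF = 1e-10

ESSENTIAL = "essential"
DISPENSABLE = "dispensable"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0 or not math.isfinite(self.score):
            raise ValidationError("hit requires evalue >= 0 and finite score")


@dataclass
class EssentialityMap:
    """Per-locus label with transfer provenance.

    ``labels`` maps every locus of an annotation to essential /
    dispensable / unknown; ``provenance`` records the reference id the
    label was transferred from (``None`` iff the label was not
    transferred).
    """

    labels: dict[str, str]
    provenance: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, label in self.labels.items():
            if label not in (ESSENTIAL, DISPENSABLE, UNKNOWN):
                raise ValidationError(f"{locus}: unknown label {label!r}")
        self.provenance = {l: self.provenance.get(l) for l in self.labels}

    def label(self, locus: str) -> str:
        return self.labels.get(locus, UNKNOWN)

    def essential_loci(self) -> set[str]:
        return {l for l, lab in self.labels.items() if lab == ESSENTIAL}

    def protected_loci(
        self, protect_unknown: bool = False, always_protect: set[str] | frozenset[str] = frozenset()
    ) -> set[str]:
        """Loci that region search / Cas3 planning must not delete.

        Unknown-label genes are deletable by default (only mapped
        essentials are protected); ``protect_unknown`` flips that, and
        ``always_protect`` adds an explicit locus list (e.g. rRNA/tRNA
        features outside the transfer's reach).
        """
        out = self.essential_loci() | set(always_protect)
        if protect_unknown:
            out |= {l for l, lab in self.labels.items() if lab == UNKNOWN}
        return out


# ---------------------------------------------------------------------------
# Alignment and E-values
# ---------------------------------------------------------------------------


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValidationError(f"{name}: empty protein sequence")
    for i, ch in enumerate(seq):
        if ch not in AA_ALPHABET:
            raise ValidationError(f"{name}: unknown residue {ch!r} at position {i}")


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load(matrix_name),
        # a gap of length k costs gap_open + k*gap_extend (BLAST convention)
        open_gap_score=-(gap_open + gap_extend),
        extend_gap_score=-gap_extend,
    )
    return aligner


def local_align(
    a: str,
    b: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """Optimal Smith–Waterman local alignment score under affine gaps.

    A gap of length k costs ``gap_open + k*gap_extend``.  The score floor
    is 0 (the empty local alignment).  Symmetric in its arguments for a
    symmetric substitution matrix.
    """
    _check_protein(a, "query")
    _check_protein(b, "subject")
    return float(_aligner(substitution_matrix, gap_open, gap_extend).score(a, b))


def estimate_evalue(
    score: float, query_len: int, subject_len: int, K: float = KA_K, lam: float = KA_LAMBDA
) -> float:
    """Karlin–Altschul expectation value E = K·m·n·exp(-λS).

    Strictly decreasing in the score and linear in each sequence length.
    No finite-size length correction is applied.
    """
    if query_len < 1 or subject_len < 1:
        raise ValidationError("sequence lengths must be >= 1")
    if K <= 0 or lam <= 0:
        raise ValidationError("K and lambda must be positive")
    return K * query_len * subject_len * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# Best hits and reciprocal best hits
# ---------------------------------------------------------------------------

Proteome = dict[str, str]  # id -> protein sequence


def best_hits(
    queries: Proteome,
    subjects: Proteome,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    substitution_matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    K: float = KA_K,
    lam: float = KA_LAMBDA,
) -> dict[str, AlignmentHit]:
    """Best qualifying subject per query.

    For each query the subject with the smallest E-value among hits with
    E <= ``e_cutoff`` is kept; ties break by higher score, then
    lexicographic subject id.  Queries with no qualifying hit are absent
    from the result.
    """
    if not queries or not subjects:
        raise ValidationError("proteomes must be non-empty")
    out: dict[str, AlignmentHit] = {}
    subject_items = sorted(subjects.items())
    for qid, qseq in sorted(queries.items()):
        best: tuple[float, float, str] | None = None
        for sid, sseq in subject_items:
            score = local_align(qseq, sseq, substitution_matrix, gap_open, gap_extend)
            ev = estimate_evalue(score, len(qseq), len(sseq), K, lam)
            if ev > e_cutoff:
                continue
            key = (ev, -score, sid)
            if best is None or key < best:
                best = key
                out[qid] = AlignmentHit(qid, sid, score, ev)
    return out


def reciprocal_best_hits(
    A: Proteome,
    B: Proteome,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    **align_kwargs,
) -> dict[str, str]:
    """One-to-one ortholog pairing by bidirectional best hit.

    ``(a, b)`` is included iff b is a's best hit in B and a is b's best
    hit in A, both below the cutoff.  The result is a bijective partial
    map and is symmetric under swapping A and B.
    """
    fwd = best_hits(A, B, e_cutoff, **align_kwargs)
    rev = best_hits(B, A, e_cutoff, **align_kwargs)
    return {
        a: hit.subject_id
        for a, hit in fwd.items()
        if rev.get(hit.subject_id) is not None and rev[hit.subject_id].subject_id == a
    }


def read_hit_table(path) -> dict[str, AlignmentHit]:
    """Adapter: best hits from an external tabular hit file.

    Accepts an outfmt-6-like TSV with columns
    ``query, subject, score, evalue`` (extra columns ignored) so that
    real-genome runs can use an external search engine's output instead
    of the built-in aligner.  Keeps the best hit per query under the same
    tie rule as :func:`best_hits`.
    """
    best: dict[str, tuple] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"hit table line has <4 columns: {line!r}")
            qid, sid, score, ev = parts[0], parts[1], float(parts[2]), float(parts[3])
            key = (ev, -score, sid)
            if qid not in best or key < best[qid][0]:
                best[qid] = (key, AlignmentHit(qid, sid, score, ev))
    return {q: hit for q, (_, hit) in best.items()}


def transfer_essentiality(
    ann: GenomeAnnotation,
    rbh: dict[str, str],
    reference_essentials: set[str] | frozenset[str],
    reference_ids: set[str] | None = None,
) -> EssentialityMap:
    """Carry reference essential/dispensable labels onto the annotation.

    A locus mapped to a reference essential becomes essential; mapped to
    any other reference gene, dispensable; unmapped loci are unknown.
    Reference essentials absent from the reference proteome (when given)
    trigger a warning, not an error.
    """
    unknown_keys = set(rbh) - set(ann.loci())
    if unknown_keys:
        raise ValidationError(f"RBH keys not in annotation: {sorted(unknown_keys)[:5]}")
    if reference_ids is not None:
        missing = set(reference_essentials) - set(reference_ids)
        if missing:
            warnings.warn(
                f"{len(missing)} reference essentials absent from reference proteome",
                stacklevel=2,
            )
    labels: dict[str, str] = {}
    provenance: dict[str, str | None] = {}
    for locus in ann.loci():
        ref = rbh.get(locus)
        if ref is None:
            labels[locus] = UNKNOWN
            provenance[locus] = None
        else:
            labels[locus] = ESSENTIAL if ref in reference_essentials else DISPENSABLE
            provenance[locus] = ref
    return EssentialityMap(labels, provenance)
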