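"""Ordered, strand-aware gene annotations.

All coordinates inside the package are 0-based half-open on a single linear
coordinate line; conversion to/from 1-based inclusive GenBank coordinates
happens only at format boundaries (see :mod:`genoslim.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: Residues accepted in protein strings: the 20 standard amino acids plus X.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class GeneFeature:
    """One gene on the genome.

    Parameters
    ----------
    locus_tag:
        Unique identifier within one annotation (e.g. ``SYN_00015``).
    start, end:
        0-based half-open genomic span of the gene body.
    strand:
        ``'+'`` or ``'-'``.
    product:
        Free-text product description.
    protein:
        Amino-acid sequence (may be ``None`` for RNA genes).
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein: str | None = None

    def __post_init__(self) -> None:
        if not self.locus_tag:
            raise ValidationError("locus_tag must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"{self.locus_tag}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.locus_tag}: strand must be '+' or '-'")
        if self.protein is not None:
            bad = set(self.protein) - AA_ALPHABET
            if bad:
                raise ValidationError(
                    f"{self.locus_tag}: illegal protein residues {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start_site(self) -> int:
        """Strand-aware translational start coordinate.

        For a minus-strand gene the annotated start codon sits at the higher
        coordinate, so the start site is ``end``; for plus-strand genes it is
        ``start``.
        """
        return self.start if self.strand == "+" else self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class GenomeAnnotation:
    """An ordered list of gene features on one replicon.

    Features are kept sorted by ``start``; locus tags are unique.  The
    nucleotide sequence is optional — window arithmetic only needs
    coordinates — but generators attach one so that GFF3+FASTA round trips
    exercise real translation.
    """

    sequence_id: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        seen: set[str] = set()
        for f in self.features:
            if f.locus_tag in seen:
                raise ValidationError(f"duplicate locus_tag {f.locus_tag!r}")
            seen.add(f.locus_tag)
            if f.end > self.length:
                raise ValidationError(
                    f"{f.locus_tag} extends past sequence end ({f.end} > {self.length})"
                )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )
        self._index = {f.locus_tag: i for i, f in enumerate(self.features)}

    # -- lookups -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.features)

    def index_of(self, locus_tag: str) -> int:
        try:
            return self._index[locus_tag]
        except KeyError:
            raise ValidationError(f"unknown locus_tag {locus_tag!r}") from None

    def get(self, locus_tag: str) -> GeneFeature:
        return self.features[self.index_of(locus_tag)]

    def loci(self) -> list[str]:
        return [f.locus_tag for f in self.features]

    def without_sequence(self) -> "GenomeAnnotation":
        return GenomeAnnotation(self.sequence_id, self.length, list(self.features))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return (
            self.sequence_id == other.sequence_id
            and self.length == other.length
            and self.features == other.features
            and self.sequence == other.sequence
        )
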