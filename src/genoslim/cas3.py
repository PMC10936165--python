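"""CRISPR-Cas3 progressive-deletion planning and tiling-PCR simulation.

Cas3's helicase–exonuclease activity produces large spontaneous
deletions extending bidirectionally from a single targeted protospacer,
stopping only when further erosion would remove an essential gene.  The
planner models three things:

* the maximal deletion window around a target coordinate — the open
  span between the nearest protected genes on either side;
* a simulated deletion library: per-colony left/right extents drawn
  independently (uniform by default, geometric processivity decay as an
  option), truncated to the window, with a configurable escaper
  fraction (colonies that survive induction undeleted);
* a positional tiling-PCR screen: a band is produced iff both primer
  binding sites survive the deletion and the post-deletion amplicon is
  short enough to amplify, and the band pattern is inverted into inner
  (certainly deleted) and outer (possibly deleted) boundary intervals.

Primer logic is purely coordinate-based: no thermodynamics, no sequence
check, and no PAM/gRNA design — the target is abstracted to its
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .errors import ValidationError
from .homology import EssentialityMap

#: Largest product a routine long-range PCR is assumed to amplify (bp).
DEFAULT_MAX_AMPLICON = 20_000


@dataclass(frozen=True)
class DeletionEvent:
    """One simulated Cas3 outcome (0-based half-open deletion interval).

    Escaper colonies are represented with ``left_end == right_end ==
    protospacer_pos`` (length 0); real deletions satisfy
    ``left_end <= protospacer_pos < right_end``.
    """

    protospacer_pos: int
    left_end: int
    right_end: int

    def __post_init__(self) -> None:
        if self.left_end > self.right_end:
            raise ValidationError("left_end must not exceed right_end")
        if self.length > 0 and not (self.left_end <= self.protospacer_pos < self.right_end):
            raise ValidationError("deletion must contain the protospacer")

    @property
    def length(self) -> int:
        return self.right_end - self.left_end

    def overlaps(self, start: int, end: int) -> bool:
        return self.left_end < end and start < self.right_end


@dataclass(frozen=True)
class PrimerPair:
    """A primer pair by binding coordinates; fwd binds upstream of rev."""

    name: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int

    def __post_init__(self) -> None:
        if not (self.fwd_start < self.fwd_end <= self.rev_start < self.rev_end):
            raise ValidationError(
                f"{self.name}: fwd interval must lie strictly upstream of rev interval"
            )

    @property
    def expected_amplicon(self) -> int:
        return self.rev_end - self.fwd_start


def max_deletion_window(
    ann: GenomeAnnotation,
    ess: EssentialityMap,
    protospacer_pos: int,
    protect_unknown: bool = False,
    always_protect: frozenset[str] = frozenset(),
) -> tuple[int, int]:
    """Widest interval a Cas3 deletion from ``protospacer_pos`` may span.

    Returns (end of nearest protected gene to the left, start of nearest
    protected gene to the right); genome edges are used where no
    protected gene exists on a side.  Targeting inside a protected gene
    is an error.
    """
    if not (0 <= protospacer_pos < ann.length):
        raise ValidationError("protospacer outside the genome")
    protected = ess.protected_loci(protect_unknown, always_protect)
    left, right = 0, ann.length
    for f in ann.features:
        if f.locus_tag not in protected:
            continue
        if f.start <= protospacer_pos < f.end:
            raise ValidationError(
                f"protospacer {protospacer_pos} lies inside protected gene {f.locus_tag}"
            )
        if f.end <= protospacer_pos:
            left = max(left, f.end)
        elif f.start > protospacer_pos:
            right = min(right, f.start)
    return (left, right)


def simulate_deletion_library(
    window: tuple[int, int],
    protospacer_pos: int,
    n: int,
    endpoint_model: str = "uniform",
    p: float | None = None,
    escaper_prob: float = 0.0,
    seed: int = 0,
) -> list[DeletionEvent]:
    """Draw ``n`` independent deletion outcomes within ``window``.

    Left and right extents are drawn independently per side: uniform
    over the permitted range, or truncated geometric with per-bp
    continuation probability ``1 - p`` (``geometric`` model; mean extent
    ~1/p before truncation).  A colony is an escaper (length 0) with
    probability ``escaper_prob``.
    """
    wl, wr = window
    if not (wl <= protospacer_pos < wr):
        raise ValidationError("protospacer must lie inside the window")
    if n < 1:
        raise ValidationError("n must be >= 1")
    if endpoint_model not in ("uniform", "geometric"):
        raise ValidationError(f"unknown endpoint model {endpoint_model!r}")
    if endpoint_model == "geometric" and not (p and 0.0 < p <= 1.0):
        raise ValidationError("geometric model requires p in (0, 1]")
    if not (0.0 <= escaper_prob <= 1.0):
        raise ValidationError("escaper_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    max_left = protospacer_pos - wl
    max_right = wr - protospacer_pos  # >= 1

    events = []
    for _ in range(n):
        if rng.random() < escaper_prob:
            events.append(DeletionEvent(protospacer_pos, protospacer_pos, protospacer_pos))
            continue
        if endpoint_model == "uniform":
            lext = int(rng.integers(0, max_left + 1))
            rext = int(rng.integers(1, max_right + 1))
        else:
            lext = min(int(rng.geometric(p)) - 1, max_left)
            rext = min(int(rng.geometric(p)), max_right)
        events.append(
            DeletionEvent(protospacer_pos, protospacer_pos - lext, protospacer_pos + rext)
        )
    return events


def deletion_length_histogram(events: list[DeletionEvent], bin_width: int) -> pd.DataFrame:
    """Counts and frequencies of deletion lengths in fixed-width bins.

    Bins are ``[k*bin_width, (k+1)*bin_width)``; counts sum to the
    number of events and frequencies to 1.  Empty input yields an empty
    table.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    columns = ["bin_start", "bin_end", "count", "frequency"]
    if not events:
        return pd.DataFrame(columns=columns)
    lengths = np.array([e.length for e in events])
    bins = lengths // bin_width
    rows = []
    for b in range(int(bins.max()) + 1):
        count = int((bins == b).sum())
        if count:
            rows.append((b * bin_width, (b + 1) * bin_width, count, count / len(events)))
    return pd.DataFrame(rows, columns=columns)


def make_tiling_panel(
    start: int, end: int, spacing: int = 2000, primer_len: int = 20, prefix: str = "P"
) -> list[PrimerPair]:
    """Evenly spaced primer pairs tiling [start, end) with ~``spacing`` bp amplicons."""
    if end - start < spacing:
        raise ValidationError("interval shorter than the tiling spacing")
    pairs = []
    k = 0
    pos = start
    while pos + spacing <= end:
        pairs.append(
            PrimerPair(
                f"{prefix}{k + 1}",
                fwd_start=pos,
                fwd_end=pos + primer_len,
                rev_start=pos + spacing - primer_len,
                rev_end=pos + spacing,
            )
        )
        pos += spacing
        k += 1
    return pairs


def simulate_tiling_pcr(
    event: DeletionEvent,
    panel: list[PrimerPair],
    max_amplicon: int = DEFAULT_MAX_AMPLICON,
) -> list[bool]:
    """Band presence per primer pair for one colony.

    A band appears iff both binding sites are intact (disjoint from the
    deletion) and the post-deletion product — the expected amplicon
    shortened by the deleted overlap between the primers — is at most
    ``max_amplicon``.
    """
    row = []
    for pp in panel:
        intact = not event.overlaps(pp.fwd_start, pp.fwd_end) and not event.overlaps(
            pp.rev_start, pp.rev_end
        )
        deleted_inside = max(
            0, min(event.right_end, pp.rev_end) - max(event.left_end, pp.fwd_start)
        )
        amplicon = pp.expected_amplicon - deleted_inside
        row.append(bool(intact and amplicon <= max_amplicon))
    return row


def band_matrix(
    events: list[DeletionEvent],
    panel: list[PrimerPair],
    max_amplicon: int = DEFAULT_MAX_AMPLICON,
) -> pd.DataFrame:
    """Rows = colonies, columns = primer pairs in genomic order."""
    ordered = sorted(panel, key=lambda p: p.fwd_start)
    data = [simulate_tiling_pcr(e, ordered, max_amplicon) for e in events]
    return pd.DataFrame(data, columns=[p.name for p in ordered])


@dataclass(frozen=True)
class InferredBounds:
    """Deletion boundary evidence from one band pattern.

    ``inner`` is guaranteed deleted (every deletion consistent with the
    pattern covers it); ``outer`` is the loosest interval consistent
    with all present bands; both are ``None`` when the evidence is
    absent/empty.  ``contradictory`` flags patterns no single deletion
    can produce.
    """

    outer: tuple[int, int] | None
    inner: tuple[int, int] | None
    contradictory: bool = False


def infer_deletion_bounds(
    row: list[bool],
    panel: list[PrimerPair],
    max_amplicon: int = DEFAULT_MAX_AMPLICON,
    seq_length: int | None = None,
) -> InferredBounds:
    """Invert a tiling band pattern into deletion boundary intervals.

    Present bands certify their primers intact; absent bands whose
    wild-type amplicon is amplifiable implicate at least one of their
    not-certified primers.  The outer interval is the gap between the
    nearest certified-intact primers flanking the implicated evidence;
    the inner interval is the span every consistent single deletion must
    cover (between the leftmost implicated band's rightmost candidate
    and the rightmost implicated band's leftmost candidate).  For data
    generated by :func:`simulate_tiling_pcr`, inner ⊆ deletion ⊆ outer.
    """
    if len(row) != len(panel):
        raise ValidationError("band row and panel lengths differ")
    ordered = sorted(zip(panel, row), key=lambda t: t[0].fwd_start)
    intact: set[tuple[int, int]] = set()
    for pp, present in ordered:
        if present:
            intact.add((pp.fwd_start, pp.fwd_end))
            intact.add((pp.rev_start, pp.rev_end))

    candidate_sets: list[list[tuple[int, int]]] = []
    contradictory = False
    for pp, present in ordered:
        if present or pp.expected_amplicon > max_amplicon:
            continue  # present, or absence is uninformative (WT product too long)
        candidates = [
            iv
            for iv in ((pp.fwd_start, pp.fwd_end), (pp.rev_start, pp.rev_end))
            if iv not in intact
        ]
        if not candidates:
            contradictory = True  # absent band but both primers certified intact
            continue
        candidate_sets.append(candidates)

    if not candidate_sets:
        return InferredBounds(None, None, contradictory)

    # inner: every consistent deletion reaches into the leftmost and the
    # rightmost implicated band's candidate region
    left_inner = min(max(e for _s, e in cands) for cands in candidate_sets)
    right_inner = max(min(s for s, _e in cands) for cands in candidate_sets)
    inner = (left_inner, right_inner) if left_inner < right_inner else None

    lo_anchor = min(s for cands in candidate_sets for s, _e in cands)
    hi_anchor = max(e for cands in candidate_sets for _s, e in cands)
    outer_left = max([0] + [e for _s, e in intact if e <= lo_anchor])
    fallback_right = seq_length if seq_length is not None else hi_anchor
    outer_right = min([fallback_right] + [s for s, _e in intact if s >= hi_anchor])
    if inner is not None:
        for s, e in intact:
            if s < inner[1] and inner[0] < e:
                contradictory = True
    return InferredBounds((outer_left, outer_right), inner, contradictory)
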