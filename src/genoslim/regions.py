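"""Iterative search for the longest contiguous dispensable genome regions.

A gene window is deletable when (i) it contains no protected locus
(transferred essentials, plus optional unknowns and an always-protect
list) and (ii) knocking out all its genes leaves the FBA maximum growth
rate at — within a configurable fraction — the wild-type maximum.  The
search returns the longest deletable window, excludes it, and iterates,
mirroring the longest-first MILP genome-reduction strategy
(MinGenome-style).

Two interchangeable engines implement the single-window optimum:

``scan``
    An exact expanding-window sweep.  Its correctness rests on
    feasibility monotonicity: deleting more genes can never increase the
    FBA optimum, so every superwindow of an infeasible window is
    infeasible and a two-pointer sweep over each unprotected run finds
    the per-start maximal windows in O(run) FBA solves.

``milp``
    A mixed-integer formulation (HiGHS through scipy.optimize.milp)
    with per-gene deletion binaries, window contiguity enforced by start
    indicators, the GPR network linearized, and the flux polytope with
    the growth floor embedded as constraints.  A second lexicographic
    solve reproduces the scan engine's tie rule (leftmost, then fewest
    genes), so both engines return identical regions by contract.

Window length is the genomic span (end of last gene minus start of first
gene, intergenic DNA included); reports also carry the start-site-to-
start-site distance convention used in published dispensable-region
tables (see :func:`region_length_footnote`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds as OptBounds

from .annotation import GenomeAnnotation
from .errors import SolverError, ValidationError
from .fba import apply_deletions, fba
from .homology import EssentialityMap
from .models import ModelDocument, gpr_genes, parse_gpr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DispensableRegion:
    """A contiguous deletable gene window.

    ``length_span`` is ``end_coord - start_coord`` (0-based half-open
    window covering the member gene bodies and enclosed intergenic DNA);
    ``length_footnote`` is the strand-aware start-site distance between
    the boundary genes.
    """

    rank: int
    first_locus: str
    last_locus: str
    start_coord: int
    end_coord: int
    length_footnote: int
    length_span: int
    first_index: int
    last_index: int

    def __post_init__(self) -> None:
        if self.length_span <= 0 or self.start_coord >= self.end_coord:
            raise ValidationError("region must have positive span")

    @property
    def n_genes(self) -> int:
        return self.last_index - self.first_index + 1

    def gene_window(self) -> tuple[int, int]:
        return (self.first_index, self.last_index)


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the region search.

    ``mu_fraction`` is the fraction of the wild-type maximal growth rate
    that must be preserved ("growth fixed at the maximum" is implemented
    as mu >= mu_fraction * mu_max; the default backs off by 1e-6 because
    strict LP equality is numerically brittle).  ``min_region_len`` is
    the bp span below which the search stops; ``cumulative`` re-applies
    prior deletions to the model (and re-fixes mu_max) before searching
    the next region instead of evaluating each region against the intact
    model.
    """

    mu_fraction: float = 1.0 - 1e-6
    min_region_len: int = 1
    max_regions: int | None = None
    protect_unknown: bool = False
    cumulative: bool = False
    engine: str = "scan"  # scan | milp
    uptake_reaction_id: str | None = None
    uptake_bound: float | None = None
    always_protect: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0.0 < self.mu_fraction <= 1.0):
            raise ValidationError("mu_fraction must lie in (0, 1]")
        if self.engine not in ("scan", "milp"):
            raise ValidationError(f"unknown engine {self.engine!r}")


def _prepared_model(model: ModelDocument, cfg: SearchConfig) -> ModelDocument:
    if cfg.uptake_reaction_id is not None and cfg.uptake_bound is not None:
        r = model.reaction(cfg.uptake_reaction_id)
        if r.lower_bound < 0:
            return model.with_bounds(cfg.uptake_reaction_id, -cfg.uptake_bound, r.upper_bound)
        return model.with_bounds(cfg.uptake_reaction_id, r.lower_bound, cfg.uptake_bound)
    return model


class _SearchContext:
    """Shared state for one search: protected mask, mu_max, FBA cache."""

    def __init__(
        self,
        ann: GenomeAnnotation,
        ess: EssentialityMap,
        model: ModelDocument,
        cfg: SearchConfig,
    ):
        self.ann = ann
        self.cfg = cfg
        self.model = _prepared_model(model, cfg)
        protected = ess.protected_loci(cfg.protect_unknown, cfg.always_protect)
        self.protected_mask = np.array([f.locus_tag in protected for f in ann.features])
        wild = fba(self.model)
        if wild.status != "optimal":
            raise SolverError(f"wild-type FBA status {wild.status}; cannot fix growth")
        self.mu_max = wild.objective_value
        self._cache: dict[frozenset, float] = {}

    def growth_after(self, gene_indices: range) -> float:
        deleted = frozenset(
            self.ann.features[i].locus_tag
            for i in gene_indices
            if self.ann.features[i].protein is not None
        )
        if deleted not in self._cache:
            result = fba(apply_deletions(self.model, deleted))
            self._cache[deleted] = (
                result.objective_value if result.status == "optimal" else 0.0
            )
        return self._cache[deleted]

    def feasible(self, i: int, j: int) -> bool:
        if self.protected_mask[i : j + 1].any():
            return False
        return self.growth_after(range(i, j + 1)) >= self.cfg.mu_fraction * self.mu_max


def window_is_deletable(
    ann: GenomeAnnotation,
    ess: EssentialityMap,
    model: ModelDocument,
    window: tuple[int, int],
    cfg: SearchConfig = SearchConfig(),
    _ctx: _SearchContext | None = None,
) -> bool:
    """True iff the gene-index window [i, j] may be deleted.

    Windows containing a protected locus are rejected without invoking
    FBA; otherwise the knockout model's maximal growth must stay at or
    above ``cfg.mu_fraction`` of the wild-type maximum.
    """
    i, j = window
    if not (0 <= i <= j < len(ann)):
        raise ValidationError(f"window {window} outside annotation of {len(ann)} genes")
    ctx = _ctx or _SearchContext(ann, ess, model, cfg)
    return ctx.feasible(i, j)


def _make_region(ann: GenomeAnnotation, i: int, j: int, rank: int) -> DispensableRegion:
    first, last = ann.features[i], ann.features[j]
    return DispensableRegion(
        rank=rank,
        first_locus=first.locus_tag,
        last_locus=last.locus_tag,
        start_coord=first.start,
        end_coord=last.end,
        length_footnote=abs(first.start_site - last.start_site),
        length_span=last.end - first.start,
        first_index=i,
        last_index=j,
    )


def _allowed_mask(ctx: _SearchContext, excluded) -> np.ndarray:
    allowed = ~ctx.protected_mask.copy()
    for a, b in excluded:
        allowed[a : b + 1] = False
    return allowed


def _runs(allowed: np.ndarray) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, ok in enumerate(allowed):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(allowed) - 1))
    return runs


def _window_key(ann: GenomeAnnotation, i: int, j: int) -> tuple[int, int, int]:
    span = ann.features[j].end - ann.features[i].start
    return (-span, ann.features[i].start, j - i + 1)


def _longest_window_scan(ctx: _SearchContext, excluded) -> tuple[int, int] | None:
    ann = ctx.ann
    best: tuple[int, int] | None = None
    best_key = None
    for lo, hi in _runs(_allowed_mask(ctx, excluded)):
        e = lo  # exclusive end of the maximal feasible window starting at i
        for i in range(lo, hi + 1):
            if e < i:
                e = i
            while e <= hi and ctx.feasible(i, e):
                e += 1
            if e - 1 >= i:
                key = _window_key(ann, i, e - 1)
                if best_key is None or key < best_key:
                    best, best_key = (i, e - 1), key
    return best


# ---------------------------------------------------------------------------
# MILP engine
# ---------------------------------------------------------------------------


class _Lp:
    """Incremental sparse constraint assembler for scipy.optimize.milp."""

    def __init__(self):
        self.n = 0
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integrality: list[int] = []
        self.rows: list[dict[int, float]] = []
        self.row_lb: list[float] = []
        self.row_ub: list[float] = []

    def var(self, lb: float, ub: float, integer: bool = False) -> int:
        self.lb.append(lb)
        self.ub.append(ub)
        self.integrality.append(1 if integer else 0)
        self.n += 1
        return self.n - 1

    def add(self, coeffs: dict[int, float], lb: float, ub: float) -> None:
        self.rows.append(coeffs)
        self.row_lb.append(lb)
        self.row_ub.append(ub)

    def solve(self, objective: dict[int, float]):
        A = sparse.lil_matrix((len(self.rows), self.n))
        for r, coeffs in enumerate(self.rows):
            for c, v in coeffs.items():
                A[r, c] = v
        c = np.zeros(self.n)
        for k, v in objective.items():
            c[k] = v
        res = milp(
            c,
            constraints=LinearConstraint(A.tocsr(), self.row_lb, self.row_ub),
            bounds=OptBounds(np.array(self.lb), np.array(self.ub)),
            integrality=np.array(self.integrality),
        )
        return res


def _build_window_milp(ctx: _SearchContext, excluded):
    """MILP over deletion binaries with the flux polytope embedded.

    Returns (lp, y_vars, span_objective) where ``y_vars`` maps gene
    index -> binary-variable column.  GPR activity is linearized
    upper-bound-wise (sufficient because maximization pushes activity up
    and leaves are binary-valued).
    """
    ann, model, cfg = ctx.ann, ctx.model, ctx.cfg
    allowed = _allowed_mask(ctx, excluded)
    lp = _Lp()
    y: dict[int, int] = {i: lp.var(0, 1, integer=True) for i in np.flatnonzero(allowed)}

    # contiguity: start indicators, at most one 0->1 transition
    z: dict[int, int] = {}
    for i in y:
        z[i] = lp.var(0, 1, integer=True)
        prev = y.get(i - 1)
        if prev is None:
            lp.add({y[i]: 1.0, z[i]: -1.0}, -np.inf, 0.0)  # z_i >= y_i
        else:
            lp.add({y[i]: 1.0, prev: -1.0, z[i]: -1.0}, -np.inf, 0.0)
    if z:
        lp.add({zi: 1.0 for zi in z.values()}, -np.inf, 1.0)

    # span objective: gene lengths plus enclosed intergenic gaps
    objective: dict[int, float] = {}
    for i, yi in y.items():
        objective[yi] = float(ann.features[i].length)
    pair_vars: dict[int, int] = {}
    for i in y:
        if i + 1 in y:
            gap = ann.features[i + 1].start - ann.features[i].end
            p = lp.var(0, 1)
            pair_vars[i] = p
            lp.add({p: 1.0, y[i]: -1.0}, -np.inf, 0.0)
            lp.add({p: 1.0, y[i + 1]: -1.0}, -np.inf, 0.0)
            lp.add({p: 1.0, y[i]: -1.0, y[i + 1]: -1.0}, -1.0, np.inf)  # p >= y_i + y_{i+1} - 1
            objective[p] = float(gap)

    # gene id -> deletion binary (only deletable, protein-coding genes)
    gene_to_y = {
        ann.features[i].locus_tag: yi
        for i, yi in y.items()
        if ann.features[i].protein is not None
    }

    # flux polytope with GPR-linked activity
    v: dict[str, int] = {}
    for r in model.reactions:
        v[r.id] = lp.var(min(r.lower_bound, 0.0), r.upper_bound)

    def linearize(node) -> int | None:
        """Activity variable in [0,1], upper-bounded by the GPR value.

        Returns ``None`` for subtrees whose value is constantly 1."""
        if isinstance(node, str):
            yi = gene_to_y.get(node)
            if yi is None:
                return None  # gene can never be deleted here
            t = lp.var(0, 1)
            lp.add({t: 1.0, yi: 1.0}, -np.inf, 1.0)  # t <= 1 - y
            return t
        op, children = node
        child_vars = [linearize(c) for c in children]
        if op == "and":
            concrete = [cv for cv in child_vars if cv is not None]
            if not concrete:
                return None
            t = lp.var(0, 1)
            for cv in concrete:
                lp.add({t: 1.0, cv: -1.0}, -np.inf, 0.0)  # t <= child
            return t
        # or: constant-1 child makes the node constant 1
        if any(cv is None for cv in child_vars):
            return None
        t = lp.var(0, 1)
        lp.add({t: 1.0, **{cv: -1.0 for cv in child_vars}}, -np.inf, 0.0)  # t <= sum
        return t

    for r in model.reactions:
        tree = parse_gpr(r.gpr)
        if tree is None or not (gpr_genes(tree) & set(gene_to_y)):
            continue
        t = linearize(tree)
        if t is None:
            continue
        lp.add({v[r.id]: 1.0, t: -r.upper_bound}, -np.inf, 0.0)  # v <= ub * t
        if r.lower_bound < 0:
            lp.add({v[r.id]: 1.0, t: -r.lower_bound}, 0.0, np.inf)  # v >= lb * t
        # lb >= 0: the variable bound v >= 0 already covers the inactive case

    met_rows: dict[str, dict[int, float]] = {m: {} for m in model.metabolites}
    for r in model.reactions:
        for m, coeff in r.stoichiometry.items():
            met_rows[m][v[r.id]] = coeff
    for m, row in met_rows.items():
        if row:
            lp.add(row, 0.0, 0.0)

    lp.add({v[model.objective_id]: 1.0}, cfg.mu_fraction * ctx.mu_max, np.inf)
    return lp, y, z, objective


def _longest_window_milp(ctx: _SearchContext, excluded) -> tuple[int, int] | None:
    lp, y, _z, span_obj = _build_window_milp(ctx, excluded)
    if not y:
        return None
    res = lp.solve({k: -w for k, w in span_obj.items()})  # milp minimizes
    if res.status == 2:
        return None
    if res.status != 0:
        raise SolverError(f"window MILP failed: {res.message}")
    best_span = int(round(-res.fun))
    if best_span <= 0:
        return None

    # second lexicographic solve: fix the span, prefer leftmost then fewest
    # genes (minimize start_coord * (n_genes+1) + gene_count, all integral)
    lp2, y2, z2, span_obj2 = _build_window_milp(ctx, excluded)
    lp2.add(dict(span_obj2), best_span, best_span)
    n_plus_1 = len(ctx.ann) + 1
    tie_obj: dict[int, float] = {}
    for i, yi in y2.items():
        tie_obj[z2[i]] = float(ctx.ann.features[i].start) * n_plus_1
        tie_obj[yi] = tie_obj.get(yi, 0.0) + 1.0
    res2 = lp2.solve(tie_obj)
    if res2.status != 0:
        raise SolverError(f"window MILP tie-break failed: {res2.message}")
    chosen = sorted(int(i) for i, yi in y2.items() if res2.x[yi] > 0.5)
    if not chosen:
        return None
    i, j = chosen[0], chosen[-1]
    if chosen != list(range(i, j + 1)):
        raise SolverError("MILP produced a non-contiguous window")
    return (i, j)


# ---------------------------------------------------------------------------
# Public search operations
# ---------------------------------------------------------------------------


def longest_dispensable_window(
    ann: GenomeAnnotation,
    ess: EssentialityMap,
    model: ModelDocument,
    cfg: SearchConfig = SearchConfig(),
    excluded: tuple[tuple[int, int], ...] = (),
    _ctx: _SearchContext | None = None,
    _rank: int = 1,
) -> DispensableRegion | None:
    """Longest deletable contiguous window disjoint from ``excluded``.

    Returns ``None`` when no deletable window reaches
    ``cfg.min_region_len``.  Ties go to the leftmost window, then the
    one with fewest genes.
    """
    ctx = _ctx or _SearchContext(ann, ess, model, cfg)
    engine = _longest_window_scan if cfg.engine == "scan" else _longest_window_milp
    found = engine(ctx, excluded)
    if found is None:
        return None
    region = _make_region(ann, found[0], found[1], _rank)
    if region.length_span < cfg.min_region_len:
        return None
    return region


def enumerate_regions(
    ann: GenomeAnnotation,
    ess: EssentialityMap,
    model: ModelDocument,
    cfg: SearchConfig = SearchConfig(),
) -> list[DispensableRegion]:
    """Longest-first iterative enumeration of dispensable regions.

    Each accepted region is added to the exclusion set before the next
    search; in cumulative mode its genes are additionally knocked out of
    the model and the growth ceiling re-fixed.  Ranks follow discovery
    order; in the default (non-cumulative) mode spans are non-increasing
    across ranks.
    """
    ctx = _SearchContext(ann, ess, model, cfg)
    regions: list[DispensableRegion] = []
    excluded: list[tuple[int, int]] = []
    while cfg.max_regions is None or len(regions) < cfg.max_regions:
        region = longest_dispensable_window(
            ann, ess, model, cfg, tuple(excluded), _ctx=ctx, _rank=len(regions) + 1
        )
        if region is None:
            break
        if regions and not cfg.cumulative and region.length_span > regions[-1].length_span:
            raise SolverError("engine returned increasing region lengths")
        regions.append(region)
        excluded.append(region.gene_window())
        if cfg.cumulative:
            deleted = frozenset(
                ann.features[i].locus_tag
                for i in range(region.first_index, region.last_index + 1)
                if ann.features[i].protein is not None
            )
            cumulative_model = apply_deletions(ctx.model, deleted)
            ctx = _SearchContext(ann, ess, cumulative_model, cfg)
        logger.info(
            "rank %d: %s..%s span %d bp",
            region.rank,
            region.first_locus,
            region.last_locus,
            region.length_span,
        )
    return regions


def region_length_footnote(
    ann: GenomeAnnotation, first_locus: str, last_locus: str, strand_aware: bool = True
) -> int:
    """Start-site-to-start-site length of a reported region.

    The published convention measures a dispensable cluster between the
    start site of its first gene and the start site of its last gene.
    ``strand_aware`` (default) takes the annotated translational start
    (the higher coordinate for minus-strand genes); the naive fallback
    uses the leftmost coordinate of each gene for robustness checks.
    """
    a = ann.get(first_locus)
    b = ann.get(last_locus)
    if strand_aware:
        return abs(a.start_site - b.start_site)
    return abs(a.start - b.start)


def brute_force_regions(
    ann: GenomeAnnotation,
    ess: EssentialityMap,
    model: ModelDocument,
    cfg: SearchConfig = SearchConfig(),
    max_genes: int = 300,
) -> list[DispensableRegion]:
    """Exhaustive-enumeration oracle for :func:`enumerate_regions`.

    Evaluates every contiguous window with :func:`window_is_deletable`
    and selects greedily longest-first under the same tie rule
    (leftmost, fewest genes).  Only valid for small annotations and the
    default non-cumulative iteration semantics.
    """
    n = len(ann)
    if n > max_genes:
        raise ValidationError(f"brute force limited to {max_genes} genes, got {n}")
    if cfg.cumulative:
        raise ValidationError("brute-force oracle covers non-cumulative mode only")
    ctx = _SearchContext(ann, ess, model, cfg)
    protected_prefix = np.concatenate([[0], np.cumsum(ctx.protected_mask)])
    feasible: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i, n):
            if protected_prefix[j + 1] - protected_prefix[i] > 0:
                break  # every larger window from i also contains the protected locus
            if ctx.feasible(i, j):
                feasible.append((i, j))
    feasible.sort(key=lambda w: _window_key(ann, w[0], w[1]))
    picked: list[tuple[int, int]] = []
    for i, j in feasible:
        span = ann.features[j].end - ann.features[i].start
        if span < cfg.min_region_len:
            continue
        if any(not (j < a or b < i) for a, b in picked):
            continue
        picked.append((i, j))
        if cfg.max_regions is not None and len(picked) >= cfg.max_regions:
            break
    return [_make_region(ann, i, j, rank) for rank, (i, j) in enumerate(picked, start=1)]
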