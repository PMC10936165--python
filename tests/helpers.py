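"""Independent oracles and instance builders shared by the tests.

Everything here is deliberately implemented apart from the package:
the alignment oracle is a plain O(nm) affine-gap dynamic program, the
FBA oracle goes through cobrapy/GLPK, and the GPR oracle evaluates the
boolean expression through Python's own ``eval``.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

from genoslim.homology import EssentialityMap
from genoslim.models import ModelDocument, gpr_to_string
from genoslim.synthetic import SynthesisSpec, generate_genome, generate_toy_model

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_affine_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Brute-force Smith–Waterman with affine gaps (Gotoh recurrences).

    A gap of length k costs gap_open + k*gap_extend.  Three-state DP:
    M (match/mismatch), X (gap in b), Y (gap in a); local floor at 0.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1]][b[j - 1]]
            M[i, j] = max(0.0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open - gap_extend, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open - gap_extend, Y[i, j - 1] - gap_extend)
            best = max(best, M[i, j], X[i, j], Y[i, j])
    return float(best)


def gpr_truth_table_oracle(tree, deleted: set[str]) -> bool:
    """Evaluate a GPR tree by rendering it to Python and using eval()."""
    if tree is None:
        return True
    expr = gpr_to_string(tree)
    genes = set()

    def collect(node):
        if isinstance(node, str):
            genes.add(node)
        else:
            for c in node[1]:
                collect(c)

    collect(tree)
    env = {g: (g not in deleted) for g in genes}
    return bool(eval(expr, {"__builtins__": {}}, env))


def cobra_fba_oracle(model: ModelDocument, deleted: set[str] = frozenset()) -> float:
    """Maximal objective flux computed by cobrapy with the GLPK backend."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {m: cobra.Metabolite(m, compartment=c) for m, c in model.metabolites.items()}
    reactions = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        reactions.append(cr)
    cm.add_reactions(reactions)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[m]: coeff for m, coeff in r.stoichiometry.items()}
        )
        cm.reactions.get_by_id(r.id).gene_reaction_rule = r.gpr
    cm.objective = model.objective_id
    if deleted:
        present = {g.id for g in cm.genes}
        cobra.manipulation.knock_out_model_genes(cm, [g for g in deleted if g in present])
    sol = cm.optimize()
    if sol.status != "optimal":
        return 0.0
    return float(sol.objective_value)


def random_instance(
    seed: int,
    n_genes: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple:
    """A synthetic genome + truth + toy model with random planted regions.

    Returns (spec, annotation, truth, model).  Planted regions have
    distinct gene counts so the expected ranking is unambiguous.
    """
    rng = rng or np.random.default_rng(seed)
    if n_genes is None:
        n_genes = int(rng.integers(50, 301))
    sizes = sorted(rng.choice(np.arange(5, 1 + min(30, n_genes // 4)), size=3, replace=False))[::-1]
    planted = []
    cursor = 2
    for size in sizes:
        start = cursor + int(rng.integers(1, 6))
        end = start + int(size) - 1
        if end > n_genes - 2:
            break
        planted.append((start, end))
        cursor = end + 2
    spec = SynthesisSpec(
        n_genes=n_genes,
        mean_gene_len=150,
        intergenic_len=30,
        essential_fraction=float(rng.uniform(0.2, 0.5)),
        planted_regions=tuple(planted),
        seed=seed,
    )
    ann, truth = generate_genome(spec)
    model = generate_toy_model(
        ann,
        truth,
        seed=seed,
        n_essential_modules=int(rng.integers(3, 9)),
        n_redundant=int(rng.integers(2, 6)),
    )
    return spec, ann, truth, model


def region_tuples(regions) -> list[tuple[int, int, int, int]]:
    """(rank, first_index, last_index, length_span) for comparisons."""
    return [(r.rank, r.first_index, r.last_index, r.length_span) for r in regions]


def planted_windows(spec: SynthesisSpec) -> list[tuple[int, int]]:
    return [tuple(w) for w in spec.planted_regions]


def truth_map(labels: dict[str, str]) -> EssentialityMap:
    return EssentialityMap(dict(labels), {l: None for l in labels})
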