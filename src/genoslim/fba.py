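"""Flux balance analysis with GPR-mediated gene knockouts.

FBA maximizes the biomass objective flux v_bio subject to steady-state
mass balance S·v = 0 and per-reaction bounds lb <= v <= ub.  Gene
knockouts act through GPR rules: a reaction whose GPR evaluates inactive
under the deleted gene set is constrained to zero flux.

The LP is solved with HiGHS through :func:`scipy.optimize.linprog`
(deterministic, single-threaded); cobrapy/GLPK serves as an independent
oracle in the test suite, never as the implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .errors import SolverError, ValidationError
from .models import ModelDocument, evaluate_gpr

logger = logging.getLogger(__name__)

#: LP feasibility tolerance passed to HiGHS.
LP_TOLERANCE = 1e-9
#: Tolerance used when reporting/asserting mass balance at the optimum.
MASS_BALANCE_TOLERANCE = 1e-6


@dataclass(frozen=True)
class FluxResult:
    """Outcome of one FBA solve."""

    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    status: str = "optimal"  # optimal | infeasible | unbounded


def stoichiometric_matrix(model: ModelDocument) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense S (metabolites x reactions) with row/column id lists."""
    met_ids = list(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxn_ids = [r.id for r in model.reactions]
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, r in enumerate(model.reactions):
        for m, coeff in r.stoichiometry.items():
            S[met_index[m], j] = coeff
    return S, met_ids, rxn_ids


def fba(model: ModelDocument) -> FluxResult:
    """Maximize the objective reaction's flux at steady state.

    Returns a :class:`FluxResult` whose status is reported faithfully;
    solver breakdowns (as opposed to model infeasibility) raise
    :class:`~genoslim.errors.SolverError`.
    """
    S, met_ids, rxn_ids = stoichiometric_matrix(model)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(model.objective_id)] = -1.0  # linprog minimizes
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(len(met_ids)),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOLERANCE},
    )
    if res.status == 0:
        fluxes = dict(zip(rxn_ids, res.x))
        residual = float(np.abs(S @ res.x).max()) if len(met_ids) else 0.0
        if residual > MASS_BALANCE_TOLERANCE:
            raise SolverError(
                f"mass-balance residual {residual:.2e} exceeds tolerance at optimum"
            )
        return FluxResult(-res.fun, fluxes, "optimal")
    if res.status == 2:
        return FluxResult(float("nan"), {}, "infeasible")
    if res.status == 3:
        return FluxResult(float("inf"), {}, "unbounded")
    raise SolverError(f"LP solver failed: {res.message}")


def apply_deletions(model: ModelDocument, deleted: set[str] | frozenset[str]) -> ModelDocument:
    """Return a copy with zeroed bounds on reactions whose GPR is inactive.

    The input model is untouched; applying the same deletion set twice is
    idempotent.
    """
    deleted = frozenset(deleted)
    if not deleted:
        return ModelDocument(
            model.id, dict(model.metabolites), list(model.reactions), model.objective_id
        )
    reactions = []
    for r in model.reactions:
        if r.gpr and not evaluate_gpr(r.gpr_tree, deleted):
            reactions.append(replace(r, lower_bound=0.0, upper_bound=0.0))
        else:
            reactions.append(r)
    return ModelDocument(model.id, dict(model.metabolites), reactions, model.objective_id)


def max_growth(
    model: ModelDocument,
    uptake_reaction_id: str,
    uptake_bound: float,
) -> float:
    """Maximal growth rate with the named uptake bounded at ``uptake_bound``.

    The bound is applied to whichever side of the exchange limits uptake:
    reactions written in the import direction (lb >= 0) get
    ``ub = uptake_bound``; reactions using the negative-flux exchange
    convention get ``lb = -uptake_bound``.  Infeasible models report a
    growth rate of 0.
    """
    r = model.reaction(uptake_reaction_id)  # raises for unknown id
    if uptake_bound < 0:
        raise ValidationError("uptake_bound must be non-negative")
    if r.lower_bound < 0:
        bounded = model.with_bounds(uptake_reaction_id, -uptake_bound, r.upper_bound)
    else:
        bounded = model.with_bounds(uptake_reaction_id, r.lower_bound, uptake_bound)
    logger.info(
        "max_growth: %s bounded at %g on model %s", uptake_reaction_id, uptake_bound, model.id
    )
    result = fba(bounded)
    if result.status == "infeasible":
        return 0.0
    if result.status == "unbounded":
        raise SolverError("growth objective unbounded; check exchange bounds")
    return result.objective_value
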