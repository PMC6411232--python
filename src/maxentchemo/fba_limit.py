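"""The homogeneous (beta = infinity) limit: lexicographic linear programming
and the zero-flux network reduction built on top of it."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_core import (
    FluxPolytope,
    InfeasiblePolytopeError,
    Medium,
    MetabolicNetwork,
    build_polytope,
)

__all__ = ["fba_solve", "reduce_network", "ReductionReport"]

_Z_REL_TOL = 1e-9  # stage-2 relative tolerance on the optimal growth rate


def fba_solve(polytope: FluxPolytope) -> np.ndarray:
    """Lexicographic optimum: maximize z, then minimize the enzymatic cost
    with z pinned (within a relative tolerance) at its optimum.

    Raises InfeasiblePolytopeError for an empty polytope and ValueError for
    an unbounded growth objective (missing bounds in the input model).
    """
    A_eq = polytope.E if polytope.E.shape[0] else None
    b_eq = polytope.d if polytope.E.shape[0] else None
    bounds = list(zip(polytope.lb, polytope.ub))

    stage1 = linprog(-polytope.tilt, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                     method="highs")
    if stage1.status == 2:
        raise InfeasiblePolytopeError("flux polytope is empty")
    if stage1.status == 3:
        raise ValueError("growth objective is unbounded; model lacks bounds")
    if stage1.status != 0:
        raise RuntimeError(f"stage-1 LP failed: {stage1.message}")
    z_opt = -stage1.fun

    if not np.any(polytope.cost):
        return stage1.x

    # stage 2: min cost subject to tilt . v >= z_opt - tol
    slack = _Z_REL_TOL * max(1.0, abs(z_opt))
    stage2 = linprog(
        polytope.cost,
        A_ub=-polytope.tilt[None, :],
        b_ub=np.array([-(z_opt - slack)]),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if stage2.status == 3:
        raise ValueError("enzymatic cost is unbounded below")
    if stage2.status != 0:
        # fall back to the stage-1 vertex rather than failing outright
        return stage1.x
    return stage2.x


@dataclass
class ReductionReport:
    xi_grid: list[float]
    infeasible_xi: list[float] = field(default_factory=list)
    removed_reactions: list[str] = field(default_factory=list)
    removed_metabolites: list[str] = field(default_factory=list)
    kept_reactions: int = 0
    kept_metabolites: int = 0


def reduce_network(
    network: MetabolicNetwork,
    medium: Medium,
    xi_grid: np.ndarray | list[float],
    tol: float = 1e-8,
) -> tuple[MetabolicNetwork, ReductionReport]:
    """Remove reactions whose lexicographic FBA flux is below ``tol`` at
    every xi in the grid, then drop metabolites orphaned by the removal.

    Infeasible grid points are recorded in the report and skipped; if every
    grid point is infeasible the reduction is refused.
    """
    xi_grid = [float(x) for x in xi_grid]
    if not xi_grid:
        raise ValueError("xi grid must be non-empty")
    report = ReductionReport(xi_grid=xi_grid)
    active = np.zeros(network.n_reactions, dtype=bool)
    n_rxn = network.n_reactions
    for xi in xi_grid:
        poly = build_polytope(network, medium, xi)
        try:
            v = fba_solve(poly)
        except InfeasiblePolytopeError:
            report.infeasible_xi.append(xi)
            continue
        active |= np.abs(v[:n_rxn]) > tol
    if len(report.infeasible_xi) == len(xi_grid):
        raise InfeasiblePolytopeError(
            "every xi grid point was infeasible; cannot reduce"
        )

    keep_r = np.nonzero(active)[0]
    report.removed_reactions = [
        network.reaction_ids[k] for k in np.nonzero(~active)[0]
    ]
    S = network.stoich.tocsc()[:, keep_r].tocsr()
    row_use = np.asarray((S != 0).sum(axis=1)).ravel() > 0
    keep_m = np.nonzero(row_use)[0]
    report.removed_metabolites = [
        network.metabolite_ids[i] for i in np.nonzero(~row_use)[0]
    ]
    kept_met_ids = [network.metabolite_ids[i] for i in keep_m]
    kept_rxn_ids = [network.reaction_ids[k] for k in keep_r]
    kept_met_set = set(kept_met_ids)

    bdef = network.biomass_rate_def
    if bdef is not None:
        if bdef.kind == "reaction" and bdef.reaction_id not in kept_rxn_ids:
            raise RuntimeError("reduction removed the biomass reaction")
        if bdef.kind == "affine":
            missing = set(bdef.weights or {}) - set(kept_rxn_ids)
            if missing:
                raise RuntimeError(
                    f"reduction removed growth-functional reactions {missing}"
                )

    split_map = None
    if network.split_map is not None:
        kept = set(kept_rxn_ids)
        split_map = {}
        for orig, (fwd, bwd, sign) in network.split_map.items():
            fwd_k = fwd if fwd in kept else None
            bwd_k = bwd if (bwd in kept if bwd else False) else None
            if fwd_k or bwd_k:
                split_map[orig] = (fwd_k or bwd_k,
                                   bwd_k if fwd_k else None,
                                   sign if fwd_k else -sign)

    reduced = MetabolicNetwork(
        metabolite_ids=kept_met_ids,
        reaction_ids=kept_rxn_ids,
        stoich=sparse.csr_matrix(S[keep_m, :]),
        reversible=network.reversible[keep_r],
        lb=network.lb[keep_r],
        ub=network.ub[keep_r],
        exchange_ids=[m for m in network.exchange_ids if m in kept_met_set],
        excretable={m: f for m, f in network.excretable.items()
                    if m in kept_met_set},
        maintenance={m: v for m, v in network.maintenance.items()
                     if m in kept_met_set},
        biomass_coeff={m: v for m, v in network.biomass_coeff.items()
                       if m in kept_met_set},
        cost=network.cost[keep_r],
        budget=network.budget,
        biomass_rate_def=bdef,
        split_map=split_map,
    )
    report.kept_reactions = reduced.n_reactions
    report.kept_metabolites = reduced.n_metabolites
    return reduced, report


def impute_missing_costs(
    cost: np.ndarray, missing: np.ndarray | None = None
) -> np.ndarray:
    """Fill missing (NaN) cost coefficients with the median of the rest."""
    cost = np.asarray(cost, dtype=float).copy()
    mask = np.isnan(cost) if missing is None else np.asarray(missing, bool)
    if mask.all():
        raise ValueError("no cost coefficients available to take a median of")
    med = float(np.median(cost[~mask]))
    cost[mask] = med
    return cost


def default_reduction_grid(
    xi_max: float, n: int = 30, xi_min: float | None = None
) -> np.ndarray:
    """Logarithmically spaced xi grid for the reduction sweep."""
    if xi_min is None:
        xi_min = max(xi_max * 1e-4, 1e-6)
    if not (0 < xi_min < xi_max) or math.isinf(xi_max):
        raise ValueError("need 0 < xi_min < xi_max < inf")
    return np.geomspace(xi_min, xi_max, n)
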