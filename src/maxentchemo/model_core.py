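"""Domain types for metabolic networks, media and toxicity, and construction
of the density-dependent flux polytope.

Units convention (used throughout the package):

* fluxes           mmol/gDW/h
* concentrations   mM
* dilution rate D  1/h
* cell density X   gDW/L
* xi = X/D         gDW*h/L  (inverse cell-specific perfusion rate)
* enzyme costs     mg*h/mmol, budget C in mg/mgDW
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

__all__ = [
    "MetabolicNetwork",
    "Medium",
    "ToxicityModel",
    "FluxPolytope",
    "BiomassRateDef",
    "InfeasiblePolytopeError",
    "split_reversible",
    "reassemble_net_fluxes",
    "uptake_bound",
    "build_polytope",
    "growth_inhibition",
    "death_rate",
    "net_growth",
]


class InfeasiblePolytopeError(RuntimeError):
    """Raised when an operation requires a non-empty polytope and none exists."""


@dataclass(frozen=True)
class BiomassRateDef:
    """Definition of the biomass synthesis rate z.

    Either a named reaction (``kind='reaction'``: z equals the flux of
    ``reaction_id``) or an affine functional of reaction fluxes
    (``kind='affine'``: z = (sum_k w_k v_k - e) / y).
    """

    kind: str  # 'reaction' | 'affine'
    reaction_id: str | None = None
    weights: dict[str, float] | None = None
    e: float = 0.0
    y: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("reaction", "affine"):
            raise ValueError(f"unknown biomass rate kind {self.kind!r}")
        if self.kind == "reaction" and not self.reaction_id:
            raise ValueError("kind='reaction' requires reaction_id")
        if self.kind == "affine":
            if not self.weights:
                raise ValueError("kind='affine' requires weights")
            if self.y <= 0:
                raise ValueError("affine biomass yield y must be positive")


@dataclass
class MetabolicNetwork:
    """Static description of a cell's metabolism.

    ``stoich`` has one row per metabolite and one column per reaction
    (positive = produced). Exchange metabolites additionally carry an
    uptake variable u_i when a polytope is built; ``excretable`` encodes
    whether the excretion bound L_i is 0 (False) or infinite (True).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    stoich: sparse.csr_matrix
    reversible: np.ndarray  # bool per reaction
    lb: np.ndarray  # per reaction
    ub: np.ndarray
    exchange_ids: list[str]
    excretable: dict[str, bool]
    maintenance: dict[str, float] = field(default_factory=dict)  # e_i
    biomass_coeff: dict[str, float] = field(default_factory=dict)  # y_i
    cost: np.ndarray | None = None  # alpha_k per reaction
    budget: float = math.inf  # C
    biomass_rate_def: BiomassRateDef | None = None
    split_map: dict[str, tuple[str, str | None, float]] | None = None

    def __post_init__(self) -> None:
        self.stoich = sparse.csr_matrix(self.stoich)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if self.cost is None:
            self.cost = np.zeros(len(self.reaction_ids))
        self.cost = np.asarray(self.cost, dtype=float)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n_met, n_rxn = len(self.metabolite_ids), len(self.reaction_ids)
        if self.stoich.shape != (n_met, n_rxn):
            raise ValueError(
                f"stoich shape {self.stoich.shape} != ({n_met}, {n_rxn})"
            )
        for arr, name in ((self.reversible, "reversible"), (self.lb, "lb"),
                          (self.ub, "ub"), (self.cost, "cost")):
            if len(arr) != n_rxn:
                raise ValueError(f"{name} length {len(arr)} != {n_rxn} reactions")
        bad = np.nonzero(self.lb > self.ub)[0]
        if bad.size:
            raise ValueError(
                f"lb > ub for reactions {[self.reaction_ids[i] for i in bad]}"
            )
        bad = np.nonzero(~self.reversible & (self.lb < 0))[0]
        if bad.size:
            raise ValueError(
                "irreversible reactions with negative lb: "
                f"{[self.reaction_ids[i] for i in bad]}"
            )
        if np.any(self.cost < 0):
            raise ValueError("reaction costs alpha_k must be non-negative")
        if not self.budget > 0:
            raise ValueError("enzyme budget C must be positive")
        met_set = set(self.metabolite_ids)
        for m in self.exchange_ids:
            if m not in met_set:
                raise ValueError(f"exchange metabolite {m!r} not in metabolite_ids")
        if any(v < 0 for v in self.maintenance.values()):
            raise ValueError("maintenance demands e_i must be non-negative")
        if any(v < 0 for v in self.biomass_coeff.values()):
            raise ValueError("biomass coefficients y_i must be non-negative")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rxn_id: str) -> int:
        return self.reaction_ids.index(rxn_id)


@dataclass(frozen=True)
class Medium:
    """Feed definition: per exchanged metabolite, the feed concentration
    c_i (mM) and the maximal uptake rate V_i (mmol/gDW/h, inf allowed)."""

    feed: dict[str, float]  # c_i
    v_max: dict[str, float]  # V_i

    def __post_init__(self) -> None:
        for m, c in self.feed.items():
            if c < 0:
                raise ValueError(f"negative feed concentration for {m!r}")
        for m, v in self.v_max.items():
            if v < 0:
                raise ValueError(f"negative maximal uptake for {m!r}")

    def concentration(self, met: str) -> float:
        return self.feed.get(met, 0.0)

    def max_uptake(self, met: str) -> float:
        return self.v_max.get(met, 0.0)


@dataclass(frozen=True)
class ToxicityModel:
    """Multiplicative growth inhibition K(s) = prod (1 + s_i/K_i)^-1 and a
    linear death rate sigma(s) = sum tau_i s_i."""

    inhibition: dict[str, float] = field(default_factory=dict)  # K_i, mM
    death: dict[str, float] = field(default_factory=dict)  # tau_i, 1/h/mM

    def __post_init__(self) -> None:
        for m, k in self.inhibition.items():
            if not k > 0:
                raise ValueError(f"inhibition constant K for {m!r} must be > 0")
        for m, t in self.death.items():
            if t < 0:
                raise ValueError(f"death coefficient tau for {m!r} must be >= 0")


NONE_TOXICITY = ToxicityModel()


@dataclass
class FluxPolytope:
    """The feasible set {v : E v = d, l <= v <= u} with the affine growth
    functional z(v) = tilt . v + z_offset.

    Variable names are prefixed by kind: ``rxn:<id>`` for reaction fluxes,
    ``upt:<met>``/``exc:<met>`` for the uptake/excretion split of exchange
    fluxes, ``slack:crowding`` for the enzyme-budget slack. ``uptake_map``
    expresses each net uptake u_i as a linear combination of variables.
    """

    var_names: list[str]
    E: np.ndarray
    d: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    tilt: np.ndarray
    z_offset: float
    cost: np.ndarray  # per-variable enzymatic cost (0 on non-reaction vars)
    uptake_map: dict[str, dict[int, float]]
    closed_exchanges: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        if self.E.size == 0:
            self.E = np.zeros((0, len(self.var_names)))
        self.d = np.asarray(self.d, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.tilt = np.asarray(self.tilt, dtype=float)
        self.cost = np.asarray(self.cost, dtype=float)
        n = len(self.var_names)
        if self.E.shape[1] != n or len(self.lb) != n or len(self.ub) != n:
            raise ValueError("inconsistent polytope dimensions")
        if not np.all(np.isfinite(self.tilt)):
            raise ValueError("growth functional must have finite coefficients")

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    def var_index(self, name: str) -> int:
        return self.var_names.index(name)

    def z_of(self, v: np.ndarray) -> float:
        return float(self.tilt @ np.asarray(v)) + self.z_offset

    def uptake_of(self, v: np.ndarray, met: str) -> float:
        return float(sum(c * v[i] for i, c in self.uptake_map[met].items()))

    def contains(self, v: np.ndarray, tol: float = 1e-8) -> bool:
        v = np.asarray(v, dtype=float)
        scale = max(1.0, float(np.max(np.abs(v))))
        if np.any(v < self.lb - tol * scale) or np.any(v > self.ub + tol * scale):
            return False
        if self.E.shape[0]:
            res = self.E @ v - self.d
            if np.max(np.abs(res)) > tol * scale:
                return False
        return True

    def feasible_point(self) -> np.ndarray | None:
        """A feasible point, or None if the polytope is empty."""
        res = linprog(
            c=np.zeros(self.n_vars),
            A_eq=self.E if self.E.shape[0] else None,
            b_eq=self.d if self.E.shape[0] else None,
            bounds=list(zip(self.lb, self.ub)),
            method="highs",
        )
        return res.x if res.status == 0 else None

    @property
    def is_empty(self) -> bool:
        return self.feasible_point() is None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def split_reversible(network: MetabolicNetwork) -> MetabolicNetwork:
    """Replace reversible reactions by irreversible forward/backward pairs.

    A reaction with lb < 0 < ub becomes ``<id>`` on [0, ub] and ``<id>__rev``
    on [0, -lb] with negated stoichiometry; a reverse-only reaction
    (ub <= 0) becomes the single flipped reaction ``<id>__rev``. The cost
    alpha_k is assigned to both directions so that sum alpha_k |r_k| is
    linear in the split variables. The mapping needed to reassemble net
    fluxes is stored in ``split_map`` as orig_id -> (fwd_id, bwd_id, sign).
    """
    if not np.any(network.reversible) and np.all(network.lb >= 0):
        out = replace(network)
        out.split_map = {
            r: (r, None, 1.0) for r in network.reaction_ids
        }
        return out

    S = network.stoich.tocsc()
    cols, ids, lbs, ubs, costs = [], [], [], [], []
    split_map: dict[str, tuple[str, str | None, float]] = {}
    weights = {}
    bdef = network.biomass_rate_def
    if bdef is not None and bdef.kind == "affine":
        weights = dict(bdef.weights or {})
    new_weights: dict[str, float] = {}

    for k, rid in enumerate(network.reaction_ids):
        col = S[:, k]
        lo, hi = network.lb[k], network.ub[k]
        w = weights.get(rid, 0.0)
        if lo >= 0:
            cols.append(col)
            ids.append(rid)
            lbs.append(lo)
            ubs.append(hi)
            costs.append(network.cost[k])
            split_map[rid] = (rid, None, 1.0)
            if w:
                new_weights[rid] = w
        elif hi <= 0:
            # reverse-only: single flipped variable, net flux = -v
            rev = rid + "__rev"
            cols.append(-col)
            ids.append(rev)
            lbs.append(-hi)
            ubs.append(-lo if np.isfinite(lo) else math.inf)
            costs.append(network.cost[k])
            split_map[rid] = (rev, None, -1.0)
            if w:
                new_weights[rev] = -w
        else:
            fwd, bwd = rid, rid + "__rev"
            cols.append(col)
            ids.append(fwd)
            lbs.append(0.0)
            ubs.append(hi)
            costs.append(network.cost[k])
            cols.append(-col)
            ids.append(bwd)
            lbs.append(0.0)
            ubs.append(-lo if np.isfinite(lo) else math.inf)
            costs.append(network.cost[k])
            split_map[rid] = (fwd, bwd, 1.0)
            if w:
                new_weights[fwd] = w
                new_weights[bwd] = -w

    new_bdef = bdef
    if bdef is not None and bdef.kind == "affine":
        new_bdef = BiomassRateDef(
            kind="affine", weights=new_weights, e=bdef.e, y=bdef.y
        )

    return MetabolicNetwork(
        metabolite_ids=list(network.metabolite_ids),
        reaction_ids=ids,
        stoich=sparse.hstack([sparse.csc_matrix(c) for c in cols]).tocsr(),
        reversible=np.zeros(len(ids), dtype=bool),
        lb=np.array(lbs),
        ub=np.array(ubs),
        exchange_ids=list(network.exchange_ids),
        excretable=dict(network.excretable),
        maintenance=dict(network.maintenance),
        biomass_coeff=dict(network.biomass_coeff),
        cost=np.array(costs),
        budget=network.budget,
        biomass_rate_def=new_bdef,
        split_map=split_map,
    )


def reassemble_net_fluxes(
    network: MetabolicNetwork, v: np.ndarray | dict[str, float]
) -> dict[str, float]:
    """Map split fluxes back to net fluxes of the original reactions."""
    if network.split_map is None:
        raise ValueError("network carries no split map (not produced by "
                         "split_reversible)")
    if not isinstance(v, dict):
        v = {rid: float(v[i]) for i, rid in enumerate(network.reaction_ids)}
    net = {}
    for orig, (fwd, bwd, sign) in network.split_map.items():
        val = sign * v[fwd]
        if bwd is not None:
            val -= v[bwd]
        net[orig] = val
    return net


def uptake_bound(c_i: float, v_i: float, xi: float) -> float:
    """Maximal uptake U_i = min(V_i, c_i / xi); U_i = V_i at xi = 0 or for
    an infinite feed concentration."""
    if c_i < 0 or v_i < 0 or xi < 0:
        raise ValueError("uptake_bound arguments must be non-negative")
    if xi == 0 or math.isinf(c_i):
        return v_i
    return min(v_i, c_i / xi)


def build_polytope(
    network: MetabolicNetwork, medium: Medium, xi: float
) -> FluxPolytope:
    """Assemble the flux polytope at culture density parameter xi.

    Equality rows encode, for every metabolite,
    sum_k N_ik r_k + u_i = e_i + y_i z (z substituted by its affine
    definition); exchange fluxes are split into an uptake variable in
    [0, U_i] and, where excretable, an excretion variable in [0, inf);
    a finite enzyme budget adds the crowding row
    sum_k alpha_k r_k + slack = C with slack in [0, C].
    """
    if np.any(network.lb < 0) or np.any(network.reversible):
        raise ValueError("build_polytope requires a split (irreversible) "
                         "network; call split_reversible first")
    if xi < 0:
        raise ValueError("xi must be non-negative")

    n_rxn = network.n_reactions
    var_names = [f"rxn:{r}" for r in network.reaction_ids]
    lb = list(network.lb)
    ub = list(network.ub)
    cost = list(network.cost)
    tilt_entries: dict[int, float] = {}

    bdef = network.biomass_rate_def
    if bdef is None:
        raise ValueError("network has no biomass rate definition")
    if bdef.kind == "reaction":
        z_offset = 0.0
        k = network.reaction_index(bdef.reaction_id)
        tilt_entries[k] = 1.0
    else:
        z_offset = -bdef.e / bdef.y
        for rid, w in (bdef.weights or {}).items():
            tilt_entries[network.reaction_index(rid)] = w / bdef.y

    # uptake / excretion variables
    uptake_map: dict[str, dict[int, float]] = {}
    closed: list[str] = []
    upt_index: dict[str, int] = {}
    exc_index: dict[str, int] = {}
    for met in network.exchange_ids:
        c_i = medium.concentration(met)
        v_i = medium.max_uptake(met)
        u_cap = uptake_bound(c_i, v_i, xi)
        i = len(var_names)
        var_names.append(f"upt:{met}")
        lb.append(0.0)
        ub.append(u_cap)
        cost.append(0.0)
        upt_index[met] = i
        uptake_map[met] = {i: 1.0}
        if network.excretable.get(met, False):
            j = len(var_names)
            var_names.append(f"exc:{met}")
            lb.append(0.0)
            ub.append(math.inf)
            cost.append(0.0)
            exc_index[met] = j
            uptake_map[met][j] = -1.0
        if math.isfinite(c_i) and math.isfinite(v_i):
            closed.append(met)

    n = len(var_names)
    tilt = np.zeros(n)
    for k, w in tilt_entries.items():
        tilt[k] = w

    rows: list[np.ndarray] = []
    rhs: list[float] = []
    S = network.stoich.tocsr()
    met_pos = {m: i for i, m in enumerate(network.metabolite_ids)}
    for met in network.metabolite_ids:
        row = np.zeros(n)
        srow = S.getrow(met_pos[met])
        row[srow.indices] = srow.data
        if met in upt_index:
            row[upt_index[met]] += 1.0
            if met in exc_index:
                row[exc_index[met]] -= 1.0
        e_i = network.maintenance.get(met, 0.0)
        y_i = network.biomass_coeff.get(met, 0.0)
        # move y_i * z to the left-hand side using z = tilt.v + z_offset
        if y_i:
            row -= y_i * tilt
        rows.append(row)
        rhs.append(e_i + y_i * z_offset)

    C = network.budget
    if math.isfinite(C):
        row = np.zeros(n + 1)
        row[:n_rxn] = network.cost
        row[n] = 1.0  # slack
        var_names.append("slack:crowding")
        lb.append(0.0)
        ub.append(C)
        cost.append(0.0)
        tilt = np.append(tilt, 0.0)
        rows = [np.append(r, 0.0) for r in rows]
        rows.append(row)
        rhs.append(C)
        n += 1

    return FluxPolytope(
        var_names=var_names,
        E=np.array(rows) if rows else np.zeros((0, n)),
        d=np.array(rhs),
        lb=np.array(lb),
        ub=np.array(ub),
        tilt=tilt,
        z_offset=z_offset,
        cost=np.array(cost),
        uptake_map=uptake_map,
        closed_exchanges=closed,
        meta={"xi": xi, "network": network, "medium": medium},
    )


def growth_inhibition(s: dict[str, float], tox: ToxicityModel) -> float:
    """Multiplicative inhibition factor K(s) in (0, 1]."""
    k = 1.0
    for met, K_i in tox.inhibition.items():
        s_i = s.get(met, 0.0)
        if s_i < 0:
            raise ValueError(f"negative concentration for {met!r}")
        k *= 1.0 / (1.0 + s_i / K_i)
    return k


def death_rate(s: dict[str, float], tox: ToxicityModel) -> float:
    """Linear death rate sigma(s) = sum tau_i s_i (1/h)."""
    sigma = 0.0
    for met, tau in tox.death.items():
        s_i = s.get(met, 0.0)
        if s_i < 0:
            raise ValueError(f"negative concentration for {met!r}")
        sigma += tau * s_i
    return sigma


def net_growth(z: float, s: dict[str, float], tox: ToxicityModel) -> float:
    """Net growth rate lambda = z * K(s) - sigma(s)."""
    return z * growth_inhibition(s, tox) - death_rate(s, tox)
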