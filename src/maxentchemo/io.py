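"""Readers, writers and fixture generation.

Formats
-------
* model, ``json`` dialect: a single JSON document with ``metabolites``
  (id, maintenance, biomass_coeff, exchange, excretable), ``reactions``
  (id, metabolites mapping, lb, ub, reversible, cost), ``budget`` and
  ``biomass`` (either ``{"reaction": id}`` or
  ``{"weights": {...}, "e": ..., "y": ...}``). The literal string "inf"
  (or "-inf") is accepted wherever a bound may be infinite.
* model, ``sbml`` dialect: read through cobrapy (optional dependency);
  boundary/exchange reactions define the exchange metabolites and the
  objective defines the biomass reaction.
* medium: TSV with columns metabolite_id, c_mM, V_max (+ optional
  amino_acid flag column); "inf" allowed.
* toxicity: TSV with columns metabolite_id, K_inhib_mM, tau_per_h_per_mM;
  either value may be empty.
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd
from scipy import sparse

from .model_core import (
    BiomassRateDef,
    FluxPolytope,
    Medium,
    MetabolicNetwork,
    ToxicityModel,
)

__all__ = [
    "read_model",
    "write_model",
    "read_medium",
    "write_medium",
    "read_toxicity",
    "make_fixture_polytope",
]


def _num(x) -> float:
    if isinstance(x, str):
        s = x.strip().lower()
        if s == "inf":
            return math.inf
        if s == "-inf":
            return -math.inf
        return float(x)
    return float(x)


def read_model(path: str, dialect: str = "json") -> MetabolicNetwork:
    if dialect in ("json", "json_tsv"):
        return _read_model_json(path)
    if dialect == "sbml":
        return _read_model_sbml(path)
    raise ValueError(f"unknown model dialect {dialect!r}")


def _read_model_json(path: str) -> MetabolicNetwork:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    mets = doc["metabolites"]
    rxns = doc["reactions"]
    met_ids = [m["id"] for m in mets]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    if len(met_pos) != len(met_ids):
        raise ValueError("duplicate metabolite ids")
    rows, cols, vals = [], [], []
    lb, ub, rev, cost, rids = [], [], [], [], []
    for j, r in enumerate(rxns):
        rids.append(r["id"])
        for met, coeff in r["metabolites"].items():
            if met not in met_pos:
                raise ValueError(
                    f"reaction {r['id']!r} references unknown metabolite {met!r}"
                )
            rows.append(met_pos[met])
            cols.append(j)
            vals.append(float(coeff))
        lo, hi = _num(r.get("lb", 0.0)), _num(r.get("ub", math.inf))
        if lo > hi:
            raise ValueError(f"reaction {r['id']!r} has lb > ub")
        lb.append(lo)
        ub.append(hi)
        rev.append(bool(r.get("reversible", lo < 0)))
        cost.append(float(r.get("cost", 0.0)))
    bm = doc.get("biomass")
    bdef = None
    if bm:
        if "reaction" in bm:
            bdef = BiomassRateDef(kind="reaction", reaction_id=bm["reaction"])
        else:
            bdef = BiomassRateDef(kind="affine", weights=dict(bm["weights"]),
                                  e=float(bm.get("e", 0.0)),
                                  y=float(bm.get("y", 1.0)))
    return MetabolicNetwork(
        metabolite_ids=met_ids,
        reaction_ids=rids,
        stoich=sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(rids))
        ),
        reversible=np.array(rev),
        lb=np.array(lb),
        ub=np.array(ub),
        exchange_ids=[m["id"] for m in mets if m.get("exchange", False)],
        excretable={m["id"]: bool(m.get("excretable", False))
                    for m in mets if m.get("exchange", False)},
        maintenance={m["id"]: float(m["maintenance"]) for m in mets
                     if m.get("maintenance")},
        biomass_coeff={m["id"]: float(m["biomass_coeff"]) for m in mets
                       if m.get("biomass_coeff")},
        cost=np.array(cost),
        budget=_num(doc.get("budget", "inf")),
        biomass_rate_def=bdef,
        split_map={r: (r, None, 1.0) for r in rids}
        if not any(rev) and all(v >= 0 for v in lb) else None,
    )


def _read_model_sbml(path: str) -> MetabolicNetwork:
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading SBML requires the cobra package") from exc
    model = cobra.io.read_sbml_model(path)
    exchanges = {}
    internal_rxns = []
    for rxn in model.reactions:
        if rxn.boundary:
            # exchange reactions define the exchangeable metabolites
            for met in rxn.metabolites:
                exchanges[met.id] = True
        else:
            internal_rxns.append(rxn)
    met_ids = [m.id for m in model.metabolites]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    lb, ub, rev, rids = [], [], [], []
    for j, rxn in enumerate(internal_rxns):
        rids.append(rxn.id)
        for met, coeff in rxn.metabolites.items():
            rows.append(met_pos[met.id])
            cols.append(j)
            vals.append(float(coeff))
        lb.append(float(rxn.lower_bound))
        ub.append(float(rxn.upper_bound))
        rev.append(rxn.lower_bound < 0)
    objective = [r.id for r in internal_rxns
                 if r.objective_coefficient]
    bdef = (BiomassRateDef(kind="reaction", reaction_id=objective[0])
            if objective else None)
    return MetabolicNetwork(
        metabolite_ids=met_ids,
        reaction_ids=rids,
        stoich=sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(rids))
        ),
        reversible=np.array(rev),
        lb=np.array(lb),
        ub=np.array(ub),
        exchange_ids=sorted(exchanges),
        excretable={m: True for m in exchanges},
        biomass_rate_def=bdef,
    )


def write_model(network: MetabolicNetwork, path: str) -> None:
    """Write the JSON dialect (inverse of read_model for that dialect)."""
    S = network.stoich.tocsc()

    def enc(x: float):
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        return x

    mets = []
    exch = set(network.exchange_ids)
    for m in network.metabolite_ids:
        entry: dict = {"id": m}
        if m in exch:
            entry["exchange"] = True
            entry["excretable"] = bool(network.excretable.get(m, False))
        if network.maintenance.get(m):
            entry["maintenance"] = network.maintenance[m]
        if network.biomass_coeff.get(m):
            entry["biomass_coeff"] = network.biomass_coeff[m]
        mets.append(entry)
    rxns = []
    for j, r in enumerate(network.reaction_ids):
        col = S.getcol(j).tocoo()
        rxns.append({
            "id": r,
            "metabolites": {network.metabolite_ids[i]: float(v)
                            for i, v in zip(col.row, col.data)},
            "lb": enc(float(network.lb[j])),
            "ub": enc(float(network.ub[j])),
            "reversible": bool(network.reversible[j]),
            "cost": float(network.cost[j]),
        })
    doc: dict = {"metabolites": mets, "reactions": rxns,
                 "budget": enc(network.budget)}
    bdef = network.biomass_rate_def
    if bdef is not None:
        if bdef.kind == "reaction":
            doc["biomass"] = {"reaction": bdef.reaction_id}
        else:
            doc["biomass"] = {"weights": bdef.weights, "e": bdef.e,
                              "y": bdef.y}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_medium(
    path: str,
    amino_acid_rule: bool = False,
    v_g: float = 0.5,
) -> Medium:
    """Read a medium TSV. With ``amino_acid_rule``, rows flagged as amino
    acids whose V_max is missing get V_max = v_g / 10."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"metabolite_id", "c_mM", "V_max"}
    if not required <= set(df.columns):
        raise ValueError(f"medium file needs columns {sorted(required)}")
    feed, vmax = {}, {}
    for _, row in df.iterrows():
        met = row["metabolite_id"]
        c = _num(row["c_mM"])
        if c < 0:
            raise ValueError(f"negative feed concentration for {met!r}")
        feed[met] = c
        raw_v = row["V_max"]
        is_aa = str(row.get("amino_acid", "")).strip().lower() in (
            "1", "true", "yes"
        )
        if raw_v is None or (isinstance(raw_v, float) and math.isnan(raw_v)) \
                or str(raw_v).strip() == "":
            if amino_acid_rule and is_aa:
                vmax[met] = v_g / 10.0
            else:
                vmax[met] = 0.0
        else:
            vmax[met] = _num(raw_v)
    return Medium(feed=feed, v_max=vmax)


def write_medium(medium: Medium, path: str) -> None:
    rows = []
    for met in sorted(set(medium.feed) | set(medium.v_max)):
        rows.append({
            "metabolite_id": met,
            "c_mM": "inf" if math.isinf(medium.concentration(met))
            else medium.concentration(met),
            "V_max": "inf" if math.isinf(medium.max_uptake(met))
            else medium.max_uptake(met),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_toxicity(path: str) -> ToxicityModel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"metabolite_id", "K_inhib_mM", "tau_per_h_per_mM"}
    if not required <= set(df.columns):
        raise ValueError(f"toxicity file needs columns {sorted(required)}")
    inhibition, death = {}, {}

    def given(x) -> bool:
        return not (x is None or (isinstance(x, float) and math.isnan(x))
                    or str(x).strip() == "")

    for _, row in df.iterrows():
        met = row["metabolite_id"]
        if given(row["K_inhib_mM"]):
            inhibition[met] = _num(row["K_inhib_mM"])
        if given(row["tau_per_h_per_mM"]):
            death[met] = _num(row["tau_per_h_per_mM"])
    return ToxicityModel(inhibition=inhibition, death=death)


def make_fixture_polytope(n_vars: int, n_eq: int, seed: int) -> FluxPolytope:
    """Random bounded polytope with a guaranteed interior point.

    The interior point is drawn first and the box placed strictly around
    it, so the result is never empty. The growth functional is a random
    affine form. Reproducible by seed.
    """
    if not n_vars >= n_eq >= 0:
        raise ValueError("need n_vars >= n_eq >= 0")
    rng = np.random.default_rng(seed)
    x0 = rng.normal(size=n_vars)
    lb = x0 - rng.uniform(0.5, 1.5, size=n_vars)
    ub = x0 + rng.uniform(0.5, 1.5, size=n_vars)
    if n_eq:
        E = rng.normal(size=(n_eq, n_vars))
        d = E @ x0
    else:
        E = np.zeros((0, n_vars))
        d = np.zeros(0)
    tilt = rng.normal(size=n_vars)
    tilt /= np.linalg.norm(tilt)
    return FluxPolytope(
        var_names=[f"v{i}" for i in range(n_vars)],
        E=E, d=d, lb=lb, ub=ub, tilt=tilt, z_offset=0.0,
        cost=np.zeros(n_vars), uptake_map={}, closed_exchanges=[],
        meta={"seed": seed, "interior_point": x0},
    )
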