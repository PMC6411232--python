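"""Exactly solvable four-flux metabolic network with an overflow switch.

The network consumes glucose (v_g), makes an intermediate that is either
respired (v_o, capped at R) or excreted as lactate (-v_l), and produces ATP
(v_atp = 2 v_g + 18 v_o). Biomass synthesis is z = (v_atp - e) / y. After
eliminating v_o and v_l, the feasible set at a given xi is the planar
polygon

    0 <= v_g <= U,   2 v_g <= v_atp <= min(38 v_g, 2 v_g + 18 R),

with U = min(V_g, c_g / xi), and the tilted density is proportional to
exp(beta * v_atp / y). Moments are evaluated by integrating the exponential
analytically along v_atp and adaptively along v_g, giving near machine
precision results that serve as the oracle for the approximate engines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .model_core import Medium, MetabolicNetwork, ToxicityModel, BiomassRateDef, uptake_bound
from .moments_exact import MomentResult

__all__ = [
    "ToyParams",
    "toy_network",
    "toy_medium",
    "toy_toxicity",
    "toy_moments",
    "toy_fba_vertex",
    "toy_medium_depth_fba",
    "TOY_FLUX_NAMES",
]

TOY_FLUX_NAMES = ["v_g", "v_o", "v_l", "v_atp"]


@dataclass(frozen=True)
class ToyParams:
    """Parameters of the simple network (defaults: mammalian-cell values)."""

    V_g: float = 0.5  # max glucose uptake, mmol/gDW/h
    R: float = 0.45  # respiratory capacity, mmol/gDW/h
    e: float = 1.0  # ATP maintenance demand, mmol/gDW/h
    y: float = 348.0  # biomass yield on ATP, mmol/gDW
    tau: float = 0.0022  # death rate per unit lactate, 1/h/mM
    c_g: float = 15.0  # glucose feed concentration, mM

    def __post_init__(self) -> None:
        if self.V_g < 0 or self.R < 0 or self.e < 0 or self.tau < 0 or self.c_g < 0:
            raise ValueError("toy parameters must be non-negative")
        if not self.y > 0:
            raise ValueError("biomass yield y must be positive")

    @property
    def lambda_max(self) -> float:
        """Maximum growth rate at xi = 0, beta = infinity."""
        return (2 * self.V_g + 18 * min(self.R, 2 * self.V_g) - self.e) / self.y

    @classmethod
    def from_config(cls, path: str) -> "ToyParams":
        """Read ``key = value`` lines; '#' comments and blank lines ignored."""
        values: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line or line.startswith("["):
                    continue
                if "=" not in line:
                    raise ValueError(f"cannot parse config line: {raw!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                values[key] = float(val)
        known = {"V_g", "R", "e", "y", "tau", "c_g"}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown toy parameters: {sorted(unknown)}")
        return cls(**values)


def toy_network(params: ToyParams | None = None) -> MetabolicNetwork:
    """The simple network as a MetabolicNetwork (already irreversible).

    Reactions: ``glyc`` (glc -> 2 P + 2 ATP, flux v_g), ``oxid``
    (P -> 18 ATP, flux v_o in [0, R]), ``atp_use`` (ATP sink, flux v_atp),
    ``lac_exc`` (P -> lac, flux w = -v_l). The glucose uptake cap
    min(V_g, c_g/xi) is applied when the polytope is built.
    """
    p = params or ToyParams()
    mets = ["P", "ATP", "glc", "lac"]
    rxns = ["glyc", "oxid", "atp_use", "lac_exc"]
    S = np.array(
        [
            #  glyc  oxid  atp_use  lac_exc
            [2.0, -1.0, 0.0, -1.0],  # P
            [2.0, 18.0, -1.0, 0.0],  # ATP
            [-1.0, 0.0, 0.0, 0.0],  # glc
            [0.0, 0.0, 0.0, 1.0],  # lac
        ]
    )
    net = MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=rxns,
        stoich=S,
        reversible=np.zeros(4, dtype=bool),
        lb=np.zeros(4),
        ub=np.array([math.inf, p.R, math.inf, math.inf]),
        exchange_ids=["glc", "lac"],
        excretable={"glc": False, "lac": True},
        biomass_rate_def=BiomassRateDef(
            kind="affine", weights={"atp_use": 1.0}, e=p.e, y=p.y
        ),
        split_map={r: (r, None, 1.0) for r in rxns},
    )
    return net


def toy_medium(params: ToyParams | None = None) -> Medium:
    p = params or ToyParams()
    return Medium(feed={"glc": p.c_g, "lac": 0.0},
                  v_max={"glc": p.V_g, "lac": 0.0})


def toy_toxicity(params: ToyParams | None = None) -> ToxicityModel:
    p = params or ToyParams()
    return ToxicityModel(death={"lac": p.tau})


# ---------------------------------------------------------------------------
# closed-form beta = infinity vertex
# ---------------------------------------------------------------------------

def toy_fba_vertex(xi: float, params: ToyParams | None = None) -> dict[str, float]:
    """Growth-maximizing vertex: glucose uptake at its cap, respiration
    saturated up to capacity, remainder overflowing to lactate."""
    p = params or ToyParams()
    if xi < 0:
        raise ValueError("xi must be non-negative")
    U = uptake_bound(p.c_g, p.V_g, xi)
    v_g = U
    v_o = min(p.R, 2 * U)
    v_l = v_o - 2 * U
    v_atp = 2 * U + 18 * v_o
    return {
        "v_g": v_g,
        "v_o": v_o,
        "v_l": v_l,
        "v_atp": v_atp,
        "z": (v_atp - p.e) / p.y,
    }


def toy_medium_depth_fba(params: ToyParams | None = None) -> float:
    """Medium depth at beta = infinity: the largest xi with
    z(xi) >= sigma(s_w(xi)). Returns math.inf when maintenance e = 0."""
    p = params or ToyParams()
    if p.e == 0:
        return math.inf

    def net_rate(xi: float) -> float:
        v = toy_fba_vertex(xi, p)
        s_w = -v["v_l"] * xi
        return v["z"] - p.tau * s_w

    xi_oxid = 38 * p.c_g / p.e
    # in the purely oxidative regime lactate is zero and the root is exact
    if 2 * uptake_bound(p.c_g, p.V_g, xi_oxid) <= p.R:
        return xi_oxid

    # otherwise the root sits in the overflow regime: bracket from above
    hi = xi_oxid
    while net_rate(hi) > 0:
        hi *= 2
        if hi > 1e15:
            return math.inf
    lo = hi / 2
    while net_rate(lo) <= 0:
        hi = lo
        lo /= 2
        if lo < 1e-12:
            raise RuntimeError("no positive-growth regime found")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if net_rate(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-12 * hi:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# quadrature moments
# ---------------------------------------------------------------------------

def _phi0(u: float) -> float:
    return -math.expm1(-u)


def _phi1(u: float) -> float:
    # int_0^u x e^-x dx, series below u = 1e-3 to avoid cancellation
    if u < 1e-3:
        return u * u * (0.5 + u * (-1 / 3 + u * (0.125 + u * (-1 / 30 + u / 144))))
    return 1.0 - math.exp(-u) * (1.0 + u)


def _phi2(u: float) -> float:
    # int_0^u x^2 e^-x dx
    if u < 1e-3:
        u3 = u**3
        return u3 * (1 / 3 + u * (-0.25 + u * (0.1 + u * (-1 / 36 + u / 168))))
    return 2.0 - math.exp(-u) * (u * u + 2.0 * u + 2.0)


def _inner(q: int, a_lo: float, a_hi: float, t: float, a_ref: float) -> float:
    """exp(-t (a_ref - a_hi)) * int_{a_lo}^{a_hi} a^q exp(t (a - a_hi)) da."""
    L = a_hi - a_lo
    if L <= 0:
        return 0.0
    scale = math.exp(t * (a_hi - a_ref)) if t else 1.0
    if t == 0:
        if q == 0:
            j = L
        elif q == 1:
            j = a_hi * L - 0.5 * L * L
        else:
            j = a_hi**2 * L - a_hi * L * L + L**3 / 3
        return scale * j
    u = t * L
    if q == 0:
        j = _phi0(u) / t
    elif q == 1:
        j = a_hi * _phi0(u) / t - _phi1(u) / t**2
    else:
        j = (a_hi**2 * _phi0(u) / t - 2 * a_hi * _phi1(u) / t**2
             + _phi2(u) / t**3)
    return scale * j


def _point_mass(p: ToyParams, v: dict[str, float]) -> MomentResult:
    return MomentResult(
        var_names=TOY_FLUX_NAMES,
        mean=np.array([v["v_g"], v["v_o"], v["v_l"], v["v_atp"]]),
        var=np.zeros(4),
        z_mean=v["z"],
        z_var=0.0,
        log_z=None,
        method="toy-vertex",
        converged=True,
        meta={"cov_g_atp": 0.0},
    )


def toy_moments(
    xi: float,
    beta: float,
    params: ToyParams | None = None,
    *,
    dimensionless: bool = False,
) -> MomentResult:
    """Moments of (v_g, v_o, v_l, v_atp) and z under the tilted density
    exp(beta * v_atp / y) on the xi-polygon.

    ``dimensionless=True`` interprets ``beta`` as lambda_max * beta. At
    beta = infinity the growth-maximizing vertex is returned with zero
    variances. ``log_z`` is the log of int exp(beta * v_atp / y) over the
    polygon (the constant factor exp(-beta * e / y) of z is dropped).
    """
    p = params or ToyParams()
    if xi < 0:
        raise ValueError("xi must be non-negative")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if dimensionless and not math.isinf(beta):
        beta = beta / p.lambda_max
    if math.isinf(beta):
        return _point_mass(p, toy_fba_vertex(xi, p))

    U = uptake_bound(p.c_g, p.V_g, xi)
    t = beta / p.y

    if U <= 0:
        # polygon degenerates to the origin
        res = _point_mass(p, {"v_g": 0.0, "v_o": 0.0, "v_l": 0.0,
                              "v_atp": 0.0, "z": -p.e / p.y})
        res.method = "toy-quadrature"
        res.log_z = -math.inf
        return res

    if p.R == 0:
        return _segment_moments(U, t, p)

    a_max = 2 * U + 18 * min(p.R, 2 * U)

    def upper(g: float) -> float:
        return min(38 * g, 2 * g + 18 * p.R)

    def integrand(q: int, pw: int):
        def f(g: float) -> float:
            return g**pw * _inner(q, 2 * g, upper(g), t, a_max)
        return f

    pieces = [0.0, U] if p.R / 2 >= U else [0.0, p.R / 2, U]
    raw = {}
    err = 0.0
    for (pw, q) in ((0, 0), (1, 0), (0, 1), (2, 0), (0, 2), (1, 1)):
        total = 0.0
        for lo, hi in zip(pieces[:-1], pieces[1:]):
            val, abserr = quad(integrand(q, pw), lo, hi,
                               epsabs=1e-300, epsrel=1e-11, limit=400)
            total += val
            err = max(err, abserr / max(abs(total), 1e-300))
        raw[(pw, q)] = total
    m00 = raw[(0, 0)]
    if m00 <= 0:
        raise RuntimeError("toy polygon has zero mass (degenerate geometry)")
    mg = raw[(1, 0)] / m00
    ma = raw[(0, 1)] / m00
    var_g = max(raw[(2, 0)] / m00 - mg * mg, 0.0)
    var_a = max(raw[(0, 2)] / m00 - ma * ma, 0.0)
    cov = raw[(1, 1)] / m00 - mg * ma
    return _assemble(p, mg, ma, var_g, var_a, cov,
                     log_z=math.log(m00) + t * a_max, err=err)


def _segment_moments(U: float, t: float, p: ToyParams) -> MomentResult:
    """R = 0: the polygon collapses to the segment v_atp = 2 v_g."""
    s = 2 * t  # density on g is exp(2 t g)
    if s == 0:
        mg, eg2 = U / 2, U * U / 3
    else:
        # integrate with shift at g = U: int_0^U g^q e^{s(g-U)} dg
        m0 = _inner(0, 0.0, U, s, U)
        m1 = _inner(1, 0.0, U, s, U)
        m2 = _inner(2, 0.0, U, s, U)
        mg, eg2 = m1 / m0, m2 / m0
    var_g = max(eg2 - mg * mg, 0.0)
    log_z = (math.log(U) if s == 0 else math.log(_inner(0, 0.0, U, s, U)) + s * U)
    return _assemble(p, mg, 2 * mg, var_g, 4 * var_g, 2 * var_g,
                     log_z=log_z, err=0.0)


def _assemble(p: ToyParams, mg: float, ma: float, var_g: float,
              var_a: float, cov: float, log_z: float, err: float) -> MomentResult:
    mean_o = (ma - 2 * mg) / 18
    mean_l = (ma - 38 * mg) / 18
    var_o = max(var_a + 4 * var_g - 4 * cov, 0.0) / 324
    var_l = max(var_a + 1444 * var_g - 76 * cov, 0.0) / 324
    return MomentResult(
        var_names=TOY_FLUX_NAMES,
        mean=np.array([mg, mean_o, mean_l, ma]),
        var=np.array([var_g, var_o, var_l, var_a]),
        z_mean=(ma - p.e) / p.y,
        z_var=var_a / p.y**2,
        log_z=log_z,
        method="toy-quadrature",
        converged=True,
        error_estimate=err,
        meta={"cov_g_atp": cov},
    )
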