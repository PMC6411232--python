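"""Self-consistent chemostat steady states over tilted flux distributions.

The primary parametrization is (xi, beta_prime): given those, the polytope
is built, a moment engine evaluates the tilted distribution, metabolite
concentrations follow from mass balance (s_i = c_i - <u_i> xi), and the
closure K(s), sigma(s), beta = beta_prime / K, <lambda> = <z> K - sigma,
D = <lambda>, X = xi D requires no iteration. Fixed-beta solutions are a
one-dimensional root find on beta_prime layered on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fba_limit import fba_solve
from .model_core import (
    FluxPolytope,
    InfeasiblePolytopeError,
    Medium,
    MetabolicNetwork,
    ToxicityModel,
    build_polytope,
    death_rate,
    growth_inhibition,
)
from .moments_ep import EPOptions, ep_moments
from .moments_exact import MomentResult, rejection_sample, sample_moments
from .toy_model import ToyParams, toy_moments

__all__ = [
    "SteadyState",
    "SweepResult",
    "PhaseDiagram",
    "solve_at",
    "solve_fixed_beta",
    "sweep",
    "classify_stability",
    "medium_depth",
    "phase_diagram",
    "perturb_costs",
    "fba_engine",
    "quadrature_engine",
    "ep_engine",
    "rejection_engine",
]

_NEG_S_TOL = 1e-8


@dataclass
class SteadyState:
    """One self-consistent chemostat solution."""

    xi: float
    beta_prime: float
    beta: float
    s: dict[str, float]
    u_mean: dict[str, float]
    z_mean: float
    K: float
    sigma: float
    lam: float
    D: float
    X: float
    feasible: bool
    converged: bool
    stability: str = "unknown"
    engine: str = ""
    meta: dict = field(default_factory=dict)

    def mass_balance_residual(self, medium: Medium) -> float:
        """max_i |D (c_i - s_i) - X <u_i>| over closed exchanges."""
        worst = 0.0
        for met, s_i in self.s.items():
            c_i = medium.concentration(met)
            res = abs(self.D * (c_i - s_i) - self.X * self.u_mean[met])
            worst = max(worst, res / max(1.0, abs(self.D * c_i)))
        return worst


def _washout(xi: float, beta_prime: float, engine_name: str,
             reason: str) -> SteadyState:
    return SteadyState(
        xi=xi, beta_prime=beta_prime, beta=math.nan, s={}, u_mean={},
        z_mean=math.nan, K=math.nan, sigma=math.nan, lam=math.nan,
        D=math.nan, X=math.nan, feasible=False, converged=False,
        engine=engine_name, meta={"reason": reason},
    )


# ---------------------------------------------------------------------------
# moment engines: callables (polytope, beta_prime) -> MomentResult
# ---------------------------------------------------------------------------

def fba_engine():
    """Point-mass engine for the beta = infinity limit."""

    def engine(polytope: FluxPolytope, beta_prime: float) -> MomentResult:
        v = fba_solve(polytope)
        return MomentResult(
            var_names=list(polytope.var_names), mean=v,
            var=np.zeros(polytope.n_vars), z_mean=polytope.z_of(v),
            z_var=0.0, method="fba", converged=True,
        )

    return engine


def quadrature_engine(params: ToyParams | None = None):
    """Near-exact quadrature engine; only valid on toy-network polytopes."""
    p = params or ToyParams()

    def engine(polytope: FluxPolytope, beta_prime: float) -> MomentResult:
        xi = polytope.meta.get("xi")
        if xi is None or "rxn:glyc" not in polytope.var_names:
            raise ValueError("quadrature engine requires a toy-model polytope")
        tm = toy_moments(xi, beta_prime, p)
        v_g, v_o, v_l, v_atp = tm.mean
        w = -v_l
        mapping = {
            "rxn:glyc": (v_g, tm.var[0]),
            "rxn:oxid": (v_o, tm.var[1]),
            "rxn:atp_use": (v_atp, tm.var[3]),
            "rxn:lac_exc": (w, tm.var[2]),
            "upt:glc": (v_g, tm.var[0]),
            "upt:lac": (0.0, 0.0),
            "exc:lac": (w, tm.var[2]),
        }
        mean = np.zeros(polytope.n_vars)
        var = np.zeros(polytope.n_vars)
        for i, name in enumerate(polytope.var_names):
            mean[i], var[i] = mapping[name]
        return MomentResult(
            var_names=list(polytope.var_names), mean=mean, var=var,
            z_mean=tm.z_mean, z_var=tm.z_var, log_z=tm.log_z,
            method="toy-quadrature", converged=tm.converged,
            error_estimate=tm.error_estimate,
        )

    return engine


def ep_engine(options: EPOptions | None = None):
    opt = options or EPOptions()

    def engine(polytope: FluxPolytope, beta_prime: float) -> MomentResult:
        return ep_moments(polytope, beta_prime, opt)

    return engine


def rejection_engine(n: int = 100_000, seed: int = 0):
    def engine(polytope: FluxPolytope, beta_prime: float) -> MomentResult:
        samples = rejection_sample(polytope, beta_prime, n, seed)
        return sample_moments(samples, polytope=polytope)

    return engine


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def solve_at(
    xi: float,
    beta_prime: float,
    network: MetabolicNetwork,
    medium: Medium,
    tox: ToxicityModel,
    engine,
) -> SteadyState:
    """Steady state at fixed (xi, beta_prime).

    beta_prime = inf dispatches to the FBA point engine. A washout
    (D < 0), an empty polytope or a non-converged moment computation is
    returned flagged, never silently patched.
    """
    if xi < 0 or beta_prime < 0:
        raise ValueError("xi and beta_prime must be non-negative")
    polytope = build_polytope(network, medium, xi)
    eng = fba_engine() if math.isinf(beta_prime) else engine
    try:
        mom = eng(polytope, beta_prime)
    except InfeasiblePolytopeError as exc:
        return _washout(xi, beta_prime, "none", f"empty polytope: {exc}")
    if not mom.converged:
        return _washout(xi, beta_prime, mom.method, "moments did not converge")

    u_mean = mom.uptake_means(polytope)
    s: dict[str, float] = {}
    for met in polytope.closed_exchanges:
        c_i = medium.concentration(met)
        s_i = c_i - u_mean[met] * xi
        if s_i < -_NEG_S_TOL * max(1.0, c_i):
            raise RuntimeError(
                f"steady-state concentration of {met!r} is {s_i:.3g} mM < 0; "
                "uptake exceeded its mass-balance bound"
            )
        s[met] = max(s_i, 0.0)

    K = growth_inhibition(s, tox)
    sigma = death_rate(s, tox)
    beta = beta_prime / K if not math.isinf(beta_prime) else math.inf
    lam = mom.z_mean * K - sigma
    D = lam
    X = xi * D
    return SteadyState(
        xi=xi, beta_prime=beta_prime, beta=beta, s=s,
        u_mean={m: u_mean[m] for m in polytope.closed_exchanges},
        z_mean=mom.z_mean, K=K, sigma=sigma, lam=lam, D=D, X=X,
        feasible=D >= 0, converged=True, engine=mom.method,
        meta={"moments": mom},
    )


def solve_fixed_beta(
    xi: float,
    beta: float,
    network: MetabolicNetwork,
    medium: Medium,
    tox: ToxicityModel,
    engine,
    rel_tol: float = 1e-8,
    max_iter: int = 200,
) -> SteadyState:
    """Steady state at fixed (xi, beta): finds beta_prime with
    beta_prime / K(s(xi, beta_prime)) = beta by bisection on [0, beta]
    (K <= 1 guarantees the bracket)."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if beta == 0 or math.isinf(beta) or not tox.inhibition:
        # K == 1 (no inhibition) or the two trivial ends: beta_prime = beta
        return solve_at(xi, beta, network, medium, tox, engine)

    def residual(bp: float) -> tuple[float, SteadyState]:
        st = solve_at(xi, bp, network, medium, tox, engine)
        if not st.converged:
            return math.nan, st
        return bp / st.K - beta, st

    lo, hi = 0.0, beta
    f_hi, st_hi = residual(hi)
    if math.isnan(f_hi):
        st_hi.stability = "unknown"
        return st_hi
    if f_hi <= 0:  # K = 1 along the bracket: beta_prime = beta
        st_hi.beta = beta
        return st_hi
    st = st_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid, st = residual(mid)
        if math.isnan(f_mid):
            st.stability = "unknown"
            return st
        if f_mid > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= rel_tol * beta:
            break
    st.beta = beta
    return st


# ---------------------------------------------------------------------------
# sweeps, stability, phase structure
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    xi_grid: np.ndarray
    curves: dict[float, list[SteadyState]]
    xi_m: dict[float, float] = field(default_factory=dict)
    unstable_windows: dict[float, list[tuple[float, float]]] = field(
        default_factory=dict
    )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for beta, curve in self.curves.items():
            for st in curve:
                row = {
                    "xi": st.xi, "beta": beta, "beta_prime": st.beta_prime,
                    "D_per_h": st.D, "X_gDW_per_L": st.X, "K": st.K,
                    "sigma_per_h": st.sigma, "stability": st.stability,
                    "feasible": st.feasible, "engine": st.engine,
                    "converged": st.converged,
                }
                for met, val in st.s.items():
                    row[f"s_{met}_mM"] = val
                for met, val in st.u_mean.items():
                    row[f"u_{met}"] = val
                rows.append(row)
        return pd.DataFrame(rows)


def classify_stability(
    D: np.ndarray | list[float],
    xi: np.ndarray | list[float],
    slope_tol: float = 1e-12,
) -> list[str]:
    """Stability labels from the sign of dD/dxi along a curve.

    A point where D(xi) increases on either side is unstable; decreasing
    on both sides is stable; slopes within ``slope_tol`` of zero are
    boundary. Endpoints see only a one-sided slope and may only be
    classified stable (decreasing) or unknown.
    """
    D = np.asarray(D, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if len(D) < 3:
        raise ValueError("need at least 3 points to classify stability")
    if np.any(np.diff(xi) <= 0):
        raise ValueError("xi must be strictly increasing")
    slopes = np.diff(D) / np.diff(xi)
    labels = []
    for i in range(len(D)):
        left = slopes[i - 1] if i > 0 else None
        right = slopes[i] if i < len(slopes) else None
        both = [s for s in (left, right) if s is not None]
        if len(both) == 1:
            labels.append("stable" if both[0] < -slope_tol else "unknown")
        elif max(both) > slope_tol:
            labels.append("unstable")
        elif min(both) < -slope_tol:
            labels.append("stable")
        else:
            labels.append("boundary")
    return labels


def sweep(
    xi_grid: np.ndarray | list[float],
    beta_list: list[float],
    network: MetabolicNetwork,
    medium: Medium,
    tox: ToxicityModel,
    engine,
) -> SweepResult:
    """One steady-state curve per beta over the xi grid, with stability
    labels and grid-level medium-depth / unstable-window summaries."""
    xi_grid = np.asarray(list(xi_grid), dtype=float)
    if np.any(np.diff(xi_grid) <= 0):
        raise ValueError("xi grid must be strictly increasing")
    result = SweepResult(xi_grid=xi_grid, curves={})
    for beta in beta_list:
        curve = [
            solve_fixed_beta(xi, beta, network, medium, tox, engine)
            for xi in xi_grid
        ]
        ok = [st for st in curve if st.feasible and st.converged]
        if len(ok) >= 3:
            labels = classify_stability([st.D for st in ok],
                                        [st.xi for st in ok])
            for st, lab in zip(ok, labels):
                st.stability = lab
            windows = []
            start = None
            for st in ok:
                if st.stability == "unstable" and start is None:
                    start = st.xi
                elif st.stability != "unstable" and start is not None:
                    windows.append((start, prev_xi))
                    start = None
                prev_xi = st.xi
            if start is not None:
                windows.append((start, prev_xi))
            result.unstable_windows[beta] = windows
        else:
            result.unstable_windows[beta] = []
        result.xi_m[beta] = ok[-1].xi if ok else math.nan
        result.curves[beta] = curve
    return result


def medium_depth(
    beta: float,
    network: MetabolicNetwork,
    medium: Medium,
    tox: ToxicityModel,
    engine,
    xi_lo: float = 1e-2,
    xi_hi: float = 1e6,
    n_scan: int = 60,
    rel_tol: float = 1e-6,
) -> float:
    """Largest xi with a positive-density steady state (D(xi) = 0 root by
    bisection from the last positive scan point). Returns math.inf when D
    stays positive up to ``xi_hi`` (open-ended, flagged to the caller by
    the infinity itself)."""

    def D_of(xi: float) -> float:
        st = solve_fixed_beta(xi, beta, network, medium, tox, engine)
        if not st.converged or math.isnan(st.D):
            return -math.inf
        return st.D

    grid = np.geomspace(xi_lo, xi_hi, n_scan)
    pos = [x for x in grid if D_of(x) > 0]
    if not pos:
        raise RuntimeError("no xi with positive net growth in the scan range")
    last = pos[-1]
    if last == grid[-1]:
        return math.inf
    lo, hi = last, grid[np.searchsorted(grid, last) + 1]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if D_of(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rel_tol * hi:
            break
    return 0.5 * (lo + hi)


@dataclass
class PhaseDiagram:
    table: pd.DataFrame  # columns: beta, xi, region, X
    xi_m: dict[float, float]
    unstable_windows: dict[float, list[tuple[float, float]]]


def phase_diagram(
    beta_grid: list[float],
    xi_grid: np.ndarray | list[float],
    network: MetabolicNetwork,
    medium: Medium,
    tox: ToxicityModel,
    engine,
) -> PhaseDiagram:
    """Label each (beta, xi) cell infeasible / stable / unstable."""
    if not len(beta_grid) or not len(xi_grid):
        raise ValueError("grids must be non-empty")
    sw = sweep(xi_grid, list(beta_grid), network, medium, tox, engine)
    rows = []
    for beta, curve in sw.curves.items():
        for st in curve:
            if not (st.feasible and st.converged):
                region = "infeasible"
            elif st.stability == "unstable":
                region = "unstable"
            else:
                region = "stable"
            rows.append({"beta": beta, "xi": st.xi, "region": region,
                         "X": st.X if region != "infeasible" else math.nan})
    return PhaseDiagram(
        table=pd.DataFrame(rows),
        xi_m=sw.xi_m,
        unstable_windows=sw.unstable_windows,
    )


def perturb_costs(
    network: MetabolicNetwork, max_rel: float, seed: int
) -> MetabolicNetwork:
    """Multiply every cost alpha_k by an independent uniform factor in
    [1 - max_rel, 1 + max_rel]; reproducible by seed."""
    if not 0 <= max_rel < 1:
        raise ValueError("max_rel must be in [0, 1)")
    rng = np.random.default_rng(seed)
    factors = rng.uniform(1 - max_rel, 1 + max_rel, size=network.n_reactions)
    out = replace(network)
    out.cost = network.cost * factors
    return out
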