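"""Brute-force moment oracles for tilted distributions on small polytopes.

The density is P(v) proportional to exp(beta_prime * z(v)) restricted to
{E v = d, l <= v <= u}. Equality constraints are eliminated once per
polytope by an affine null-space parametrization; sampling then happens in
the reduced coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space, lstsq
from scipy.optimize import linprog

from .model_core import FluxPolytope, InfeasiblePolytopeError

__all__ = [
    "MomentResult",
    "ReducedPolytope",
    "reduce_polytope",
    "rejection_sample",
    "sample_moments",
]


@dataclass
class MomentResult:
    """First two moments of fluxes and of z under a tilted distribution."""

    var_names: list[str]
    mean: np.ndarray
    var: np.ndarray
    z_mean: float
    z_var: float
    log_z: float | None = None
    method: str = ""
    converged: bool = True
    n_iter: int = 0
    error_estimate: float = math.nan
    mean_se: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if np.any(self.var < -1e-12):
            raise ValueError("negative variance in MomentResult")
        self.var = np.maximum(self.var, 0.0)

    def mean_of(self, name: str) -> float:
        return float(self.mean[self.var_names.index(name)])

    def uptake_means(self, polytope: FluxPolytope) -> dict[str, float]:
        """Mean net uptake <u_i> per exchange metabolite."""
        return {
            met: float(sum(c * self.mean[i] for i, c in comb.items()))
            for met, comb in polytope.uptake_map.items()
        }


@dataclass
class ReducedPolytope:
    """Affine parametrization v = x0 + B y of {E v = d} with the box
    constraints mapped along; ``box_lo/box_hi`` bound y itself."""

    polytope: FluxPolytope
    x0: np.ndarray
    B: np.ndarray  # n_vars x dim
    box_lo: np.ndarray
    box_hi: np.ndarray

    @property
    def dim(self) -> int:
        return self.B.shape[1]

    def to_full(self, y: np.ndarray) -> np.ndarray:
        return self.x0 + y @ self.B.T if y.ndim == 2 else self.x0 + self.B @ y

    def inside(self, v: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        lo = self.polytope.lb - tol
        hi = self.polytope.ub + tol
        return np.all((v >= lo) & (v <= hi), axis=-1)


def reduce_polytope(polytope: FluxPolytope, tol: float = 1e-10) -> ReducedPolytope:
    """Eliminate equalities (and variables fixed by their bounds)."""
    n = polytope.n_vars
    E = polytope.E
    d = polytope.d
    width = polytope.ub - polytope.lb
    fixed = np.isfinite(width) & (
        width <= tol * np.maximum(1.0, np.abs(polytope.ub))
    )
    if np.any(fixed):
        extra = np.eye(n)[fixed]
        E = np.vstack([E, extra]) if E.shape[0] else extra
        d = np.concatenate([d, 0.5 * (polytope.lb + polytope.ub)[fixed]])

    if E.shape[0] == 0:
        x0 = np.zeros(n)
        B = np.eye(n)
    else:
        x0, *_ = lstsq(E, d)
        if np.max(np.abs(E @ x0 - d)) > 1e-7 * max(1.0, np.max(np.abs(d))):
            raise InfeasiblePolytopeError("equality system is inconsistent")
        B = null_space(E)
        if B.size == 0:
            B = np.zeros((n, 0))

    if B.shape[1] == 0:
        return ReducedPolytope(polytope, x0, B,
                               np.zeros(0), np.zeros(0))

    # bounding box of y via LPs: min/max y_j s.t. l <= x0 + B y <= u
    bounds_v = list(zip(polytope.lb - x0, polytope.ub - x0))
    # constraints in y: lb - x0 <= B y <= ub - x0
    A_ub = np.vstack([B, -B])
    b_ub = np.concatenate([polytope.ub - x0, -(polytope.lb - x0)])
    keep = np.isfinite(b_ub)
    A_ub, b_ub = A_ub[keep], b_ub[keep]
    lo = np.empty(B.shape[1])
    hi = np.empty(B.shape[1])
    for j in range(B.shape[1]):
        c = np.zeros(B.shape[1])
        c[j] = 1.0
        r1 = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * B.shape[1],
                     method="highs")
        r2 = linprog(-c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * B.shape[1],
                     method="highs")
        if r1.status == 2 or r2.status == 2:
            raise InfeasiblePolytopeError("polytope is empty")
        if r1.status != 0 or r2.status != 0:
            raise InfeasiblePolytopeError(
                "polytope is unbounded or ill-posed in reduced coordinates"
            )
        lo[j], hi[j] = r1.fun, -r2.fun
    del bounds_v
    return ReducedPolytope(polytope, x0, B, lo, hi)


def rejection_sample(
    polytope: FluxPolytope,
    beta_prime: float,
    n: int,
    seed: int,
    *,
    max_tries: int = 400,
    min_accept: float = 1e-4,
    reduced: ReducedPolytope | None = None,
) -> np.ndarray:
    """Draw n i.i.d. samples from exp(beta_prime * z) on the polytope.

    Uniform proposals in the bounding box of the reduced coordinates are
    accepted through the box constraints and then thinned by an exponential
    acceptance step for the tilt, so the returned rows are unweighted draws.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rp = reduced if reduced is not None else reduce_polytope(polytope)
    rng = np.random.default_rng(seed)
    if rp.dim == 0:
        return np.tile(rp.x0, (n, 1))

    # upper bound of z over the box for the exponential-accept step
    t_red = rp.B.T @ polytope.tilt
    z_hi = polytope.tilt @ rp.x0 + polytope.z_offset + float(
        np.sum(np.where(t_red > 0, t_red * rp.box_hi, t_red * rp.box_lo))
    )

    out = np.empty((n, polytope.n_vars))
    got = 0
    proposed = 0
    accepted = 0
    chunk = max(4 * n, 1000)
    for _ in range(max_tries):
        y = rng.uniform(rp.box_lo, rp.box_hi, size=(chunk, rp.dim))
        v = rp.to_full(y)
        ok = rp.inside(v)
        proposed += chunk
        v = v[ok]
        if beta_prime != 0 and len(v):
            z = v @ polytope.tilt + polytope.z_offset
            keep = rng.uniform(size=len(v)) < np.exp(
                np.clip(beta_prime * (z - z_hi), -745, 0)
            )
            v = v[keep]
        accepted += len(v)
        take = min(len(v), n - got)
        out[got:got + take] = v[:take]
        got += take
        if got == n:
            return out
        if proposed >= 10 * chunk and accepted / proposed < min_accept:
            break
    raise RuntimeError(
        f"rejection sampling acceptance rate too low "
        f"({accepted}/{proposed}); use quadrature or EP instead"
    )


def sample_moments(
    samples: np.ndarray,
    weights: np.ndarray | None = None,
    polytope: FluxPolytope | None = None,
) -> MomentResult:
    """Weighted means/variances with standard errors from a sample matrix."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    m = samples.shape[0]
    if m < 2:
        raise ValueError("need at least 2 samples")
    if weights is None:
        w = np.ones(m)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != m or np.any(w < 0) or not np.sum(w) > 0:
            raise ValueError("degenerate weights")
    wsum = w.sum()
    p = w / wsum
    mean = p @ samples
    dev = samples - mean
    var = p @ dev**2
    n_eff = wsum**2 / np.sum(w**2)
    se = np.sqrt(var / max(n_eff - 1, 1))

    if polytope is not None:
        z = samples @ polytope.tilt + polytope.z_offset
        z_mean = float(p @ z)
        z_var = float(p @ (z - z_mean) ** 2)
        names = list(polytope.var_names)
    else:
        z_mean = math.nan
        z_var = 0.0
        names = [f"v{i}" for i in range(samples.shape[1])]

    return MomentResult(
        var_names=names,
        mean=mean,
        var=var,
        z_mean=z_mean,
        z_var=z_var,
        method="sampling",
        converged=True,
        n_iter=m,
        error_estimate=float(np.max(se)) if len(se) else 0.0,
        mean_se=se,
        meta={"n_eff": float(n_eff)},
    )
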