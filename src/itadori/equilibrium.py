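"""Coexistence equilibrium of the knotweed–psyllid model.

At an equilibrium (L*, A*, S*, R*) with all components positive, the
per-unit-biomass predation pressure c = eσL/(1 + heσS) is pinned to the
unique positive root c* of

    mu_s + c = (k_r k_s / mu_r) (1 - e^{-(mu_s + c) tau_s}),

which exists exactly when the stand would grow without insects
(mu_r mu_s < k_r k_s (1 - e^{-mu_s tau_s})).  The adults-per-stem ratio
is pinned to phi(S), the positive root of
b_p(phi) e^{-tau_p mu_l(S)} = mu_a phi.  Substituting both reduces the
four equilibrium balances to a single scalar equation for S*:

    mu_l(S*) (1 + h e σ S*) c*/(eσ) = S* b_p(phi(S*)) (1 - e^{-tau_p mu_l(S*)}),

after which A* = S* phi(S*), L* = (1 + heσS*) c*/(eσ), R* = k_r S*/mu_r.
For large handling time h the left side outgrows the right everywhere
and no equilibrium exists — the regime of ineffective biocontrol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import ModelParameters
from .functions import Biology, ricker_biology

__all__ = [
    "EquilibriumState",
    "growth_condition_holds",
    "solve_cstar",
    "phi",
    "phi_domain_min",
    "solve_equilibrium",
]

_BISECT_TOL = 1e-12


@dataclass
class EquilibriumState:
    """Equilibrium components plus the residuals of the four balances."""

    exists: bool
    L_star: float = float("nan")
    A_star: float = float("nan")
    S_star: float = float("nan")
    R_star: float = float("nan")
    c_star: float = float("nan")
    phi_star: float = float("nan")
    residuals: tuple = ()
    all_S_roots: tuple = ()
    warnings: tuple = ()

    def as_dict(self) -> dict:
        return {
            "exists": self.exists,
            "L_star": self.L_star,
            "A_star": self.A_star,
            "S_star": self.S_star,
            "R_star": self.R_star,
            "c_star": self.c_star,
            "phi_star": self.phi_star,
            "residuals": list(self.residuals),
            "all_S_roots": list(self.all_S_roots),
            "warnings": list(self.warnings),
        }


def growth_condition_holds(params: ModelParameters) -> bool:
    """Insect-free exponential growth: mu_r mu_s < k_r k_s (1 - e^{-mu_s tau_s})."""
    return params.mu_r * params.mu_s < params.k_r * params.k_s * (
        1.0 - math.exp(-params.mu_s * params.tau_s)
    )


def solve_cstar(params: ModelParameters) -> float:
    """Unique positive root c* of the predation-pressure equation.

    With x = mu_s + c, solves x = (k_r k_s/mu_r)(1 - e^{-x tau_s}) for
    x > mu_s by bracketing and bisection to 1e-12.  Requires the
    insect-free growth condition; otherwise no positive root exists.
    """
    if not growth_condition_holds(params):
        raise ValueError(
            "growth condition mu_r*mu_s < k_r*k_s*(1-exp(-mu_s*tau_s)) fails; "
            "no positive predation pressure c* exists"
        )
    K = params.k_r * params.k_s / params.mu_r

    def fun(c: float) -> float:
        x = params.mu_s + c
        return x - K * (1.0 - math.exp(-x * params.tau_s))

    # fun(0) < 0 by the growth condition; fun -> +inf since the RHS is
    # bounded by K
    hi = max(1.0, 2.0 * K)
    while fun(hi) <= 0:
        hi *= 2.0
    return float(brentq(fun, 0.0, hi, xtol=_BISECT_TOL, rtol=8.9e-16))


def phi_domain_min(params: ModelParameters) -> float:
    """Smallest stem biomass at which phi(S) is defined (Ricker default).

    phi exists iff P e^{-tau_p mu_l(S)} > mu_a, i.e. iff
    mu_l(S) < ln(P/mu_a)/tau_p.  Returns 0 when that holds already at
    S = 0, +inf when it holds nowhere.
    """
    ml_max = math.log(params.P / params.mu_a) / params.tau_p
    if ml_max >= params.mu_l0:
        return 0.0
    if ml_max <= params.m:
        return float("inf")
    return -math.log((ml_max - params.m) / params.k_l)


def phi(S: float, params: ModelParameters, biology: Biology | None = None) -> float | None:
    """Equilibrium adults-per-stem ratio, or None where undefined.

    The positive root of b_p(phi) e^{-tau_p mu_l(S)} = mu_a phi.  For the
    Ricker default this is phi(S) = (1/q) ln(P e^{-tau_p mu_l(S)} / mu_a),
    defined iff the log argument exceeds 1: stems too sparse (mu_l too
    high) cannot sustain any positive adult density.  Increasing in S.
    """
    if S <= 0:
        raise ValueError("phi is defined for S > 0")
    if biology is None:
        ml = params.k_l * math.exp(-S) + params.m
        arg = params.P * math.exp(-params.tau_p * ml) / params.mu_a
        if arg <= 1.0:
            return None
        return math.log(arg) / params.q
    # general closure: root of b_p(x) e^{-tau_p mu_l(S)} - mu_a x on x > 0
    ml = biology.mu_l(S)
    disc = math.exp(-params.tau_p * ml)

    def fun(x: float) -> float:
        return biology.b_p(x) * disc - params.mu_a * x

    # find the upper crossing: scan outward for a sign change from + to -
    if fun(1e-12) <= 0:
        return None
    hi = 1.0
    while fun(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            return None
    return float(brentq(fun, 1e-12, hi, xtol=1e-14, rtol=8.9e-16))


def _phi_and_parts(S: float, params: ModelParameters, c_star: float,
                   biology: Biology):
    """LHS - RHS of the scalar S* equation; None where phi is undefined."""
    p = phi(S, params, None if biology is None else biology)
    if p is None:
        return None
    bio = biology if biology is not None else None
    ml = bio.mu_l(S) if bio else params.k_l * math.exp(-S) + params.m
    bp = bio.b_p(p) if bio else params.P * p * math.exp(-params.q * p)
    es = params.e * params.sigma
    lhs = ml * (1.0 + params.h * es * S) * c_star / es
    rhs = S * bp * (1.0 - math.exp(-params.tau_p * ml))
    return lhs - rhs


def solve_equilibrium(
    params: ModelParameters,
    biology: Biology | None = None,
    S_max: float = 1e8,
    n_grid: int = 2000,
) -> EquilibriumState:
    """Find the coexistence equilibrium, or report non-existence.

    Scans the scalar S* equation on a logarithmic grid over the domain
    where phi is defined, refines every sign change by bisection to
    1e-12 relative, and reconstructs the remaining components.  Multiple
    roots are all reported (``all_S_roots``) with the smallest taken as
    primary.  ``exists=False`` (no sign change anywhere) is the
    large-handling-time regime in which biocontrol cannot pin the stand.

    The scan is restricted to S above the phi-definedness threshold:
    stem levels at which no positive adults-per-stem ratio can sustain
    itself cannot support a positive-insect equilibrium.
    """
    c_star = solve_cstar(params)  # raises if growth condition fails

    S_lo = phi_domain_min(params)
    if not math.isfinite(S_lo):
        return EquilibriumState(
            exists=False, c_star=c_star,
            warnings=("phi(S) is undefined for every S > 0",),
        )
    S_lo = max(S_lo * (1.0 + 1e-9), 1e-12)

    grid = np.geomspace(S_lo, S_max, n_grid)
    vals = np.array(
        [_phi_and_parts(S, params, c_star, biology) or np.nan for S in grid]
    )
    # phi may be undefined at the very first point by rounding; drop NaNs
    ok = np.isfinite(vals)
    grid, vals = grid[ok], vals[ok]

    roots = []
    sign = np.sign(vals)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in flips:
        root = brentq(
            lambda S: _phi_and_parts(S, params, c_star, biology),
            grid[i], grid[i + 1], xtol=1e-300, rtol=_BISECT_TOL,
        )
        roots.append(float(root))
    roots.extend(float(grid[i]) for i in np.nonzero(sign == 0)[0])
    roots.sort()

    if not roots:
        return EquilibriumState(exists=False, c_star=c_star)

    S_star = roots[0]
    bio = biology if biology is not None else ricker_biology(params)
    p_star = phi(S_star, params, biology)
    es = params.e * params.sigma
    A_star = S_star * p_star
    L_star = (1.0 + params.h * es * S_star) * c_star / es
    R_star = params.k_r * S_star / params.mu_r

    residuals = _balance_residuals(
        L_star, A_star, S_star, R_star, params, bio
    )
    warnings = tuple(
        f"multiple equilibria found at S* = {r:.6g}" for r in roots[1:]
    )
    return EquilibriumState(
        exists=True,
        L_star=L_star,
        A_star=A_star,
        S_star=S_star,
        R_star=R_star,
        c_star=c_star,
        phi_star=p_star,
        residuals=residuals,
        all_S_roots=tuple(roots),
        warnings=warnings,
    )


def _balance_residuals(L, A, S, R, params: ModelParameters, bio: Biology):
    """Relative residuals of the four equilibrium balance equations."""
    es = params.e * params.sigma
    c = es * L / (1.0 + params.h * es * S)
    ml = bio.mu_l(S)
    bp = bio.b_p(A / S)

    # stem balance
    lhs1 = (params.mu_s + c) * S
    rhs1 = params.k_s * R * (
        1.0 - math.exp(-params.mu_s * params.tau_s) * math.exp(-params.tau_s * c)
    )
    # rhizome balance
    lhs2, rhs2 = params.k_r * S, params.mu_r * R
    # larval balance
    lhs3 = ml * L
    rhs3 = S * bp * (1.0 - math.exp(-params.tau_p * ml))
    # adult balance
    lhs4 = S * bp * math.exp(-params.tau_p * ml)
    rhs4 = params.mu_a * A

    def rel(a, b):
        return abs(a - b) / max(abs(a), abs(b), 1e-300)

    return (rel(lhs1, rhs1), rel(lhs2, rhs2), rel(lhs3, rhs3), rel(lhs4, rhs4))
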