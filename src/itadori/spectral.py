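"""Characteristic equations and growth/boundedness thresholds.

Three transcendental problems are handled, all for real rates λ (per
day), matching the analytical treatment of the model, which restricts
itself to real roots:

1. *Insect-free*: solutions R(t) ∝ e^{λt} of the stem–rhizome subsystem
   satisfy λ + mu_r = k_r k_s tau_s g(tau_s (λ + mu_s)) with
   g(x) = (1-e^{-x})/x.  Both sides are monotone (LHS up, RHS down), so
   there is a unique real root whose sign decides growth vs decay.

2. *Joint exponential growth with insects*: assuming all four variables
   grow like e^{λt}, the adults-per-stem ratio tends to alpha(λ), the
   positive solution of (λ+mu_a) α = e^{-(λ+m) tau_p} b_p(α), and λ must
   solve a modified insect-free equation in which the stem loss rate is
   augmented by the asymptotic predation pressure
   pi(λ) = b_p(alpha(λ)) tau_p g(tau_p (λ+m)) / h.  The handling-time
   threshold h_crit is where this equation admits λ = 0.

3. *Linearisation about the coexistence equilibrium*: after eliminating
   amplitudes the characteristic equation collapses to the scalar form
   F3(λ) = -F1 F4 F5 / (F2 F5 + F6) in six auxiliary functions of λ;
   only its real roots are scanned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import ModelParameters
from .functions import Biology, ricker_biology, g, g_prime
from .equilibrium import EquilibriumState, growth_condition_holds

__all__ = [
    "SpectralScan",
    "insect_free_dominant_root",
    "classify_insect_free",
    "check_growth_condition",
    "alpha",
    "growth_char_root",
    "h_crit",
    "F_functions",
    "linearised_real_roots",
]


@dataclass
class SpectralScan:
    """Real-root inventory of a named characteristic equation."""

    equation: str
    window: tuple
    n_grid: int
    roots: tuple
    dominant_root: float | None
    denominator_zeros: tuple = ()
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "equation": self.equation,
            "window": list(self.window),
            "n_grid": self.n_grid,
            "roots": list(self.roots),
            "dominant_root": self.dominant_root,
            "denominator_zeros": list(self.denominator_zeros),
            "extras": self.extras,
        }


def _insect_free_fun(lam: float, params: ModelParameters) -> float:
    return lam + params.mu_r - params.k_r * params.k_s * params.tau_s * g(
        params.tau_s * (lam + params.mu_s)
    )


def insect_free_dominant_root(params: ModelParameters) -> float:
    """Unique real root of the insect-free characteristic equation, /day.

    The LHS λ + mu_r increases while the RHS decreases in λ, so a single
    real root exists; it is positive exactly under the growth condition.
    """
    lo, hi = -params.mu_r - 1.0, 1.0
    while _insect_free_fun(lo, params) > 0:
        lo -= 1.0
    while _insect_free_fun(hi, params) < 0:
        hi *= 2.0
    return float(brentq(_insect_free_fun, lo, hi, xtol=1e-14, rtol=8.9e-16,
                        args=(params,)))


def classify_insect_free(params: ModelParameters) -> str:
    """'grows' or 'decays' by the sign of mu_r mu_s vs k_r k_s (1-e^{-mu_s tau_s})."""
    return "grows" if growth_condition_holds(params) else "decays"


def check_growth_condition(params: ModelParameters,
                           biology: Biology | None = None) -> bool:
    """Low-density insect viability: b_p'(0) e^{-m tau_p} > mu_a.

    With unlimited stems and few adults, the adult equation linearises to
    a scalar delay equation that grows iff the discounted per-capita
    recruitment exceeds adult mortality.  Strict inequality required.
    """
    bp0 = biology.b_p_prime(0.0) if biology is not None else params.P
    return bp0 * math.exp(-params.m * params.tau_p) > params.mu_a


def alpha(lam: float, params: ModelParameters,
          biology: Biology | None = None) -> float | None:
    """Asymptotic adults-per-stem ratio alpha(λ) of the joint-growth ansatz.

    Positive solution of (λ+mu_a) α = e^{-(λ+m) tau_p} b_p(α); for the
    Ricker default the closed form
    (1/q) ln(P e^{-(λ+m) tau_p} / (λ+mu_a)).  Returns None where no
    positive solution exists (guaranteed only for small λ ≥ 0).
    Independent of the handling time h.
    """
    disc = math.exp(-(lam + params.m) * params.tau_p)
    if biology is None:
        arg = params.P * disc / (lam + params.mu_a)
        if arg <= 1.0:
            return None
        return math.log(arg) / params.q

    def fun(x: float) -> float:
        return biology.b_p(x) * disc - (lam + params.mu_a) * x

    if fun(1e-12) <= 0:
        return None
    hi = 1.0
    while fun(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            return None
    return float(brentq(fun, 1e-12, hi, xtol=1e-14, rtol=8.9e-16))


def _predation_pressure(lam: float, params: ModelParameters,
                        biology: Biology | None) -> float | None:
    """pi(λ) = b_p(alpha(λ)) tau_p g(tau_p (λ+m)) / h; None if alpha fails."""
    a = alpha(lam, params, biology)
    if a is None:
        return None
    bp = (
        biology.b_p(a)
        if biology is not None
        else params.P * a * math.exp(-params.q * a)
    )
    return bp * params.tau_p * g(params.tau_p * (lam + params.m)) / params.h


def _growth_fun(lam: float, params: ModelParameters,
                biology: Biology | None) -> float | None:
    pi = _predation_pressure(lam, params, biology)
    if pi is None:
        return None
    x = lam + params.mu_s + pi
    return lam + params.mu_r - params.k_r * params.k_s * params.tau_s * g(
        params.tau_s * x
    )


def growth_char_root(
    params: ModelParameters,
    biology: Biology | None = None,
    lam_max: float | None = None,
    n_grid: int = 2000,
) -> float | None:
    """Smallest positive real root of the with-insects growth equation.

    Scans λ in (0, lam_max] (default: the insect-free root, which bounds
    any slowed growth rate from above) for sign changes and refines by
    bisection.  Returns None when no positive root exists on the window
    — the candidate bounded/controlled regime.
    """
    if not growth_condition_holds(params):
        raise ValueError("insect-free growth condition fails; joint growth "
                         "analysis does not apply")
    if not check_growth_condition(params, biology):
        raise ValueError("insect viability condition b_p'(0) e^{-m tau_p} > mu_a fails")
    if lam_max is None:
        lam_max = insect_free_dominant_root(params) * 1.0000001
    grid = np.linspace(lam_max / n_grid, lam_max, n_grid)
    vals = np.array(
        [v if (v := _growth_fun(l, params, biology)) is not None else np.nan
         for l in grid]
    )
    ok = np.isfinite(vals)
    if not ok.any():
        return None
    grid, vals = grid[ok], vals[ok]
    sign = np.sign(vals)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if flips.size == 0:
        if (sign == 0).any():
            return float(grid[np.nonzero(sign == 0)[0][0]])
        return None
    i = flips[0]
    return float(
        brentq(lambda l: _growth_fun(l, params, biology),
               grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16)
    )


def _hcrit_rhs(h: float, params: ModelParameters,
               biology: Biology | None) -> float:
    """RHS of the boundedness-threshold equation at λ = 0, as a function of h."""
    a0 = alpha(0.0, params, biology)
    if a0 is None:
        raise ValueError("alpha(0) does not exist for these parameters")
    bp = (
        biology.b_p(a0)
        if biology is not None
        else params.P * a0 * math.exp(-params.q * a0)
    )
    pi0 = bp * (1.0 - math.exp(-params.m * params.tau_p)) / (params.m * h)
    x = params.mu_s + pi0
    return params.k_r * params.k_s * params.tau_s * g(params.tau_s * x)


def h_crit(params: ModelParameters, biology: Biology | None = None,
           bracket=(1e-6, 1e4)) -> float:
    """Critical handling time: the h at which λ = 0 solves the growth equation.

    Below h_crit the joint-growth equation has no small positive root and
    solutions are conjectured bounded (effective biocontrol).  The RHS of
    the threshold equation increases with h (predation pressure fades),
    so the root is unique; found by bisection on ``bracket``.
    """
    if not growth_condition_holds(params):
        raise ValueError("growth condition fails; h_crit is undefined")

    def fun(h: float) -> float:
        return _hcrit_rhs(h, params, biology) - params.mu_r

    lo, hi = bracket
    flo, fhi = fun(lo), fun(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"h_crit bracket failure: fun({lo})={flo:.3e}, fun({hi})={fhi:.3e}"
        )
    return float(brentq(fun, lo, hi, xtol=1e-12, rtol=8.9e-16))


def _dq(lam: float, tau: float, base: float) -> float:
    """(g(tau*base) - g(tau*(lam+base)))/lam with its λ→0 limit -tau g'(tau base)."""
    if abs(lam) < 1e-7:
        return -tau * g_prime(tau * base)
    return (g(tau * base) - g(tau * (lam + base))) / lam


def F_functions(
    lam: float,
    equilibrium: EquilibriumState,
    params: ModelParameters,
    biology: Biology | None = None,
) -> tuple:
    """The six auxiliary functions of the linearised characteristic equation.

    Evaluated exactly as derived, with the removable λ = 0 singularities
    of the difference quotients replaced by their analytic limits
    (-tau g'(tau·base)).  Returns (F1, ..., F6).
    """
    if not equilibrium.exists:
        raise ValueError("linearisation requires an existing equilibrium")
    bio = biology if biology is not None else ricker_biology(params)
    S = equilibrium.S_star
    c = equilibrium.c_star
    p = equilibrium.phi_star
    ml = bio.mu_l(S)
    mlp = bio.mu_l_prime(S)
    bp = bio.b_p(p)
    bpp = bio.b_p_prime(p)
    tau_p, tau_s = params.tau_p, params.tau_s
    es = params.e * params.sigma
    sat = 1.0 + params.h * es * S
    krks = params.k_r * params.k_s

    g_p = g(tau_p * (lam + ml))
    dq_p = _dq(lam, tau_p, ml)
    dq_s = _dq(lam, tau_s, params.mu_s + c)
    surplus = bp - p * bpp  # b_p(phi*) - phi* b_p'(phi*)

    F1 = bpp * tau_p * g_p
    F2 = surplus * tau_p * g_p - mlp * S * bp * tau_p * dq_p
    F3 = lam + params.mu_a - bpp * math.exp(-tau_p * (lam + ml))
    F4 = (
        math.exp(-tau_p * (lam + ml)) * surplus
        - mlp * S * bp * tau_p * math.exp(-tau_p * ml) * g(tau_p * lam)
    )
    F5 = (krks * S * es * tau_s / (params.mu_r * sat)) * dq_s
    F6 = (
        1.0
        - (krks * tau_s / (lam + params.mu_r)) * g(tau_s * (lam + params.mu_s + c))
        - (krks * S * params.h * es * c * tau_s / (params.mu_r * sat)) * dq_s
    )
    return (F1, F2, F3, F4, F5, F6)


def theorem_hypothesis_warnings(
    equilibrium: EquilibriumState,
    params: ModelParameters,
    biology: Biology | None = None,
) -> tuple:
    """Check the negativity-theorem hypotheses at the equilibrium.

    The real-root negativity argument needs b_p'(phi*) > 0,
    b_p(phi*) - phi* b_p'(phi*) > 0 and
    mu_a > b_p'(phi*) e^{-tau_p mu_l(S*)}.  Violations are reported as
    warnings, not errors: the scan itself remains valid.
    """
    bio = biology if biology is not None else ricker_biology(params)
    p = equilibrium.phi_star
    S = equilibrium.S_star
    bpp = bio.b_p_prime(p)
    bp = bio.b_p(p)
    ml = bio.mu_l(S)
    out = []
    if bpp <= 0:
        out.append("b_p'(phi*) <= 0: equilibrium on the decreasing branch of the birth law")
    if bp - p * bpp <= 0:
        out.append("b_p(phi*) - phi* b_p'(phi*) <= 0")
    if params.mu_a <= bpp * math.exp(-params.tau_p * ml):
        out.append("mu_a <= b_p'(phi*) e^{-tau_p mu_l(S*)}")
    return tuple(out)


def linearised_real_roots(
    params: ModelParameters,
    equilibrium: EquilibriumState,
    window: tuple = (-0.5, 1.0),
    n_grid: int = 2000,
    biology: Biology | None = None,
) -> SpectralScan:
    """Real-root scan of the equilibrium linearisation's characteristic equation.

    Works with the pole-free combination
    H(λ) = (λ + mu_r)·[F3·(F2 F5 + F6) + F1 F4 F5] (the 1/(λ+mu_r) term
    inside F6 is thereby cleared), dense-scans the window for sign
    changes, refines each by bisection, and rejects any candidate at
    which the denominator F2 F5 + F6 itself vanishes — those are reported
    separately, never as roots.  Only real roots are sought; the dominant
    root of the full problem need not be real, so no stability claim is
    attached.
    """
    if not equilibrium.exists:
        raise ValueError("linearisation requires an existing equilibrium")

    def denom(lam: float) -> float:
        F = F_functions(lam, equilibrium, params, biology)
        return F[1] * F[4] + F[5]

    def H(lam: float) -> float:
        F = F_functions(lam, equilibrium, params, biology)
        return (lam + params.mu_r) * (
            F[2] * (F[1] * F[4] + F[5]) + F[0] * F[3] * F[4]
        )

    grid = np.linspace(window[0], window[1], n_grid)
    vals = np.array([H(l) for l in grid])
    sign = np.sign(vals)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]

    roots, den_zeros = [], []
    for i in flips:
        r = float(brentq(H, grid[i], grid[i + 1], xtol=1e-13, rtol=8.9e-16))
        if abs(r + params.mu_r) < 1e-9:
            continue  # artificial zero introduced by pole clearing
        if abs(denom(r)) < 1e-9 * max(1.0, abs(F_functions(r, equilibrium, params, biology)[2])):
            den_zeros.append(r)
        else:
            roots.append(r)

    # denominator zeros elsewhere on the window (diagnostic only)
    dvals = np.array([(grid[i] + params.mu_r) * denom(grid[i]) for i in range(n_grid)])
    dsign = np.sign(dvals)
    for i in np.nonzero(dsign[:-1] * dsign[1:] < 0)[0]:
        r = float(brentq(lambda l: (l + params.mu_r) * denom(l),
                         grid[i], grid[i + 1], xtol=1e-13, rtol=8.9e-16))
        if abs(r + params.mu_r) > 1e-9 and all(abs(r - z) > 1e-9 for z in den_zeros):
            den_zeros.append(r)

    roots.sort()
    return SpectralScan(
        equation="linearised",
        window=tuple(window),
        n_grid=n_grid,
        roots=tuple(roots),
        dominant_root=roots[-1] if roots else None,
        denominator_zeros=tuple(sorted(den_zeros)),
        extras={
            "hypothesis_warnings": list(
                theorem_hypothesis_warnings(equilibrium, params, biology)
            )
        },
    )
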