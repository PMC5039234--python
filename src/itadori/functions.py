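"""Constitutive functions of the knotweed–psyllid model.

The defaults are the forms used throughout the numerical studies: a
Ricker (Nicholson-blowflies) per-stem birth law b_p(x) = P x e^{-qx} and
an exponentially saturating larval mortality mu_l(S) = k_l e^{-S} + m.
Threshold- and equilibrium-level code is written against a small
:class:`Biology` bundle so alternative closures (with their derivatives)
can be plugged in; the shipped tests pin down the defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import ModelParameters


def larval_mortality(S, params: ModelParameters):
    """Per-capita larval mortality mu_l(S) = k_l e^{-S} + m.

    Strictly decreasing in stem biomass S (starvation pressure relaxes as
    sap becomes plentiful), bounded in (m, k_l + m].
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("stem biomass S must be >= 0")
    out = params.k_l * np.exp(-S) + params.m
    return float(out) if out.ndim == 0 else out


def larval_mortality_prime(S, params: ModelParameters):
    """d mu_l / dS for the default exponential form: -k_l e^{-S}."""
    S = np.asarray(S, dtype=float)
    out = -params.k_l * np.exp(-S)
    return float(out) if out.ndim == 0 else out


def birth_per_stem(x, params: ModelParameters):
    """Eggs laid per stem per day, b_p(x) = P x e^{-qx}, x = adults/stem.

    Unimodal with maximum at x = 1/q: egg laying per stem rises nearly
    linearly while stems are uncrowded and collapses when oviposition
    sites run out.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("adults per stem must be >= 0")
    out = params.P * x * np.exp(-params.q * x)
    return float(out) if out.ndim == 0 else out


def birth_per_stem_prime(x, params: ModelParameters):
    """b_p'(x) = P (1 - qx) e^{-qx}."""
    x = np.asarray(x, dtype=float)
    out = params.P * (1.0 - params.q * x) * np.exp(-params.q * x)
    return float(out) if out.ndim == 0 else out


def egg_laying_total(A: float, S: float, params: ModelParameters,
                     biology: "Biology | None" = None) -> float:
    """Stand-wide egg laying rate S·b_p(A/S), eggs per day.

    Continuously extended to 0 at S = 0: no stems means no leaves and no
    oviposition sites.  For the Ricker default this is P·A·e^{-qA/S}.
    """
    if A < 0 or S < 0:
        raise ValueError("A and S must be >= 0")
    if S == 0.0 or A == 0.0:
        return 0.0
    b_p = biology.b_p if biology is not None else (lambda x: birth_per_stem(x, params))
    return S * b_p(A / S)


def functional_response(L: float, S: float, params: ModelParameters) -> float:
    """Holling type II per-unit-biomass predation rate eσL/(1 + heσS).

    Saturates in S: when stems are abundant each larva's sap intake is
    capped by the handling (digestion) time h.  h = 0 recovers the linear
    response eσL.
    """
    es = params.e * params.sigma
    return es * L / (1.0 + params.h * es * S)


def g(x):
    """g(x) = (1 - e^{-x})/x, the mean survival-discount kernel.

    Positive, strictly decreasing and convex on x > 0, with g(0) = 1 by
    continuity.  Appears wherever an exponential mortality discount is
    averaged over a stage duration.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    safe = np.where(small, 1.0, x)
    # -expm1(-x)/x avoids the 1 - e^{-x} cancellation near zero
    out = np.where(small, 1.0 - x / 2.0 + x * x / 6.0, -np.expm1(-safe) / safe)
    return float(out) if out.ndim == 0 else out


def g_prime(x):
    """g'(x) = (e^{-x}(1+x) - 1)/x^2; g'(0) = -1/2."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    safe = np.where(small, 1.0, x)
    out = np.where(
        small,
        -0.5 + x / 3.0 - x * x / 8.0,
        (np.exp(-safe) * (1.0 + safe) - 1.0) / (safe * safe),
    )
    return float(out) if out.ndim == 0 else out


def stem_production(R, params: ModelParameters):
    """New-shoot biomass production b_s(R) = k_s R, biomass/day."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("rhizome biomass R must be >= 0")
    out = params.k_s * R
    return float(out) if out.ndim == 0 else out


def rhizome_production(S, params: ModelParameters):
    """Rhizome biomass production b_r(S) = k_r S, biomass/day."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("stem biomass S must be >= 0")
    out = params.k_r * S
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Biology:
    """Pluggable closures for the birth law and larval mortality.

    Threshold and equilibrium formulas only need the four callables here;
    custom mortality closures must supply their own derivative.
    """

    b_p: Callable[[float], float]
    b_p_prime: Callable[[float], float]
    mu_l: Callable[[float], float]
    mu_l_prime: Callable[[float], float]


def ricker_biology(params: ModelParameters) -> Biology:
    """The default forms bundled for a given parameter set."""
    return Biology(
        b_p=lambda x: float(params.P * x * math.exp(-params.q * x)),
        b_p_prime=lambda x: float(
            params.P * (1.0 - params.q * x) * math.exp(-params.q * x)
        ),
        mu_l=lambda S: float(params.k_l * math.exp(-S) + params.m),
        mu_l_prime=lambda S: float(-params.k_l * math.exp(-S)),
    )
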