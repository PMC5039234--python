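# Methods

## Model

The package simulates and analyses a four-variable delay model of a
single knotweed stand under psyllid predation.  Larvae L and adults A
are insect *numbers*; stems S and rhizome R are *biomass* in an
abstract unit (the model never pins the unit down; all biomass output
is reported in the same unit).  The structure comes from age densities
of larvae and stems: integrating the age-structured balance laws over
the larval stage [0, τ_p] and the stem life-span [0, τ_s] produces
delay equations whose maturation and die-back terms carry
distributed-delay survival factors

    exp(−∫_{t−τ_p}^t μ_l(S(η)) dη)       (larval survival to adulthood)
    e^{−μ_s τ_s} exp(−∫_{t−τ_s}^t f(η) dη)  (stem survival to die-back)

with f = eσL/(1+heσS) the Holling type II per-unit-biomass predation
rate.  Two modelling choices matter and are deliberate:

- **Linear stem/rhizome production** (b_s = k_s R, b_r = k_r S): an
  invasive stand has no effective carrying capacity on the timescale of
  interest, so unbounded exponential growth is a legitimate regime, not
  an artifact.
- **Per-stem crowding in egg laying**: the stand-wide egg rate is
  S·b_p(A/S) with Ricker b_p(x) = P x e^{−qx}, because each stem has
  finite leaf area for oviposition even though the stand as a whole can
  grow without bound.  S·b_p(A/S) is continuously extended to 0 at
  S = 0 (no stems, no oviposition sites).

Default constants (per day unless noted): τ_p = 32.2 d, τ_s = 150 d,
m = 0.0205, k_l = 1 − m (normalising μ_l(0) = 1), P = 16.9867, q = 1,
μ_a = 0.0806, μ_s = μ_r = 0.01, k_s = k_r = 0.1, e = σ = 1.  A second
preset keeps the raw fecundity estimate P = 23.9798; the two are
alternative parameterisations and are not reconciled.  μ_s and μ_r are
used as plain per-capita rates (per day).  The handling time h (days
per biomass unit per larva) is the swept control parameter.

Threshold- and equilibrium-level code takes an optional `Biology`
bundle (b_p, b_p′, μ_l, μ_l′) so other birth/mortality closures can be
analysed; custom mortality closures must supply their own derivative.
The shipped forms are the defaults everywhere and are what the tests
pin down.

## Integrator

**Cumulant channels.** The two running integrals
M_l(t) = ∫_0^t μ_l(S) dη and M_f(t) = ∫_0^t f dη are integrated as
extra state channels, so every survival factor is the exact difference
exp(−(M(t) − M(t−τ))) and nothing is re-quadratured while stepping —
O(1) per step and the survival-factor identity holds to integrator
accuracy.  On the pre-initial interval the cumulants are accumulated
backwards from 0 (trapezoid on the grid; exact for the constant default
histories), which makes cross-boundary survival factors seamless.

**Stepping.** Classical explicit RK4 on a fixed output grid
(default 0.05 d; both delays are then resolved to ≲0.2 %), advanced by
the method of steps: delayed states and cumulants are read from the
stored solution through cubic Hermite interpolation of node values and
node derivatives.  Both delays exceed the step by three orders of
magnitude, so stages only ever read strictly past data.

**Adaptive substepping.** With the default far-from-equilibrium
histories the transient passes through predator–prey relaxation spikes
in which the predation rate f reaches 10³–10⁴/day while stems crash;
an explicit step at 0.05 d is unstable there (stability limit
≈ 2.8/rate).  Each output step is therefore internally subdivided so
that (local rate)·Δt ≤ 0.5, with the local rate bounded by
max(μ_l(0), μ_a, μ_r, μ_s) + eσL/(1+heσS).  Only grid nodes are
stored; the substeps exist for stability and accuracy of the node
values.  Step-halving on the convergent reference scenario moves
terminal states by ~10⁻⁹ relative.  For extreme parameter corners
(h ≫ h_crit with large insect booms) the local rate can reach
10⁶/day and explicit substepping becomes prohibitively expensive;
the integrator raises once the required substep falls below
step/2²⁴ rather than silently stalling.  None of the shipped scenarios
approaches that regime.

**Guards.** Any state beyond 10²⁵⁰ aborts with a diagnostic (the
insect-free stand legitimately reaches ~10³⁸ by t = 900 d, so the guard
is far above every physical regime but well below float overflow).
Relative negativity beyond 10⁻⁶ of a channel's running scale is an
integration failure; sub-tolerance round-off negatives are clipped so
the mortality/birth closures never see negative populations.

## Initial histories

A field release controls two numbers: A⁰ adults and R⁰ rhizome biomass
(defaults 50 and 500).  `make_history` builds constant histories from
them.  The stem level defaults to the insect-free integral-form balance
S_init = k_s R⁰ (1 − e^{−μ_s τ_s})/μ_s (= 3884.3 for the defaults),
and L(0) is set from the larval compatibility constraint evaluated in
closed form over the constant histories.  With insects present the stem
constraint is then not exact; the history records this in flags.
Incompatible non-negative data only perturbs the transient, and the
integral-form consistency check quantifies the effect: recomputing L(t)
and S(t) by Simpson quadrature of their distributed-integral forms
along a stored trajectory agrees with the stepped values to ~2×10⁻⁴
relative on the convergent reference run (10⁻¹² insect-free).

## Equilibrium

At a positive equilibrium the predation pressure
c = eσL*/(1+heσS*) must equal the unique positive root c* of
μ_s + c = (k_r k_s/μ_r)(1 − e^{−(μ_s+c)τ_s}), which exists exactly when
the stand grows insect-free (μ_r μ_s < k_r k_s(1 − e^{−μ_s τ_s})).
The adults-per-stem ratio must equal φ(S), the positive root of
b_p(φ) e^{−τ_p μ_l(S)} = μ_a φ — in closed form for the Ricker default,
φ(S) = (1/q) ln(P e^{−τ_p μ_l(S)}/μ_a), defined only where the log
argument exceeds 1 (S > 1.9057 for the defaults).  Substituting both
reduces the equilibrium system to one scalar equation for S*, scanned
on a 2000-point log grid over [S_min(1+10⁻⁹), 10⁸] and refined by
bisection to 10⁻¹² relative.  Stem levels below S_min cannot support
any positive adults-per-stem ratio and are excluded from the scan: this
is the package's reading of the existence argument, whose global form
assumes φ is defined for all S > 0 — the default parameters violate
that below S_min.  Multiple roots would all be reported with the
smallest primary; the default parameters yield exactly one.  Residuals
of all four balance equations are attached to every returned
equilibrium (~10⁻¹³ in practice).  Existence flips from true to false
once along increasing h (between h ≈ 46 and 48.5 for the defaults).

## Spectral analysis

All root finding is for **real** rates λ, matching the scope of the
analytical treatment; no stability claim is made where the dominant
root could be complex.

- *Insect-free*: λ + μ_r = k_r k_s τ_s g(τ_s(λ+μ_s)) with
  g(x) = (1−e^{−x})/x; LHS increasing, RHS decreasing, hence one real
  root found by bracket expansion + Brent.  Its sign reproduces the
  growth/decay inequality exactly (checked on random parameter draws).
- *Joint growth with insects*: α(λ) solves
  (λ+μ_a)α = e^{−(λ+m)τ_p} b_p(α) (closed form for Ricker; bracketed
  root for general closures; absence is a typed None, not an error).
  The characteristic equation augments the insect-free stem loss by
  π(λ) = b_p(α(λ)) τ_p g(τ_p(λ+m))/h and is scanned on (0, λ_free] —
  any slowed joint growth rate lies below the insect-free rate.
  h_crit is the h at which λ = 0 solves this equation; the relevant
  side is monotone in h, so bisection on [10⁻⁶, 10⁴] suffices.
- *Linearisation about the equilibrium*: the characteristic equation
  collapses to F₃ = −F₁F₄F₅/(F₂F₅+F₆) in six functions of λ built from
  g, μ_l′(S*), b_p′(φ*) and c*.  The removable λ = 0 singularities of
  the difference quotients (g(a) − g(a+τλ))/λ are evaluated by the
  analytic limit −τ g′(a) (threshold |λ| < 10⁻⁷), with g and g′
  computed via expm1/series so no cancellation occurs.  The scan works
  with the pole-free combination (λ+μ_r)[F₃(F₂F₅+F₆) + F₁F₄F₅] on
  [−0.5, 1] (2000 points + Brent refinement); candidates at denominator
  zeros are reported separately, never as roots.  Violations of the
  negativity-theorem hypotheses are attached as warnings, not errors.

F₆(λ) → 1 as λ → ∞ at rate O(1/λ); the tests assert the limit with a
tolerance that scales accordingly (10⁻³ at λ = 10³, 10⁻⁶ at 10⁶).

## Trajectory diagnostics

- **Growth rate**: least-squares slope of log(variable) on a window.
- **Oscillation period**: median spacing of local maxima after a 1-day
  moving average, with peak prominence ≥ 1 % of the windowed amplitude
  so grid-level wiggles never count; fewer than 3 peaks is an error.
- **Regime classification**: the final half of the run is split into
  two windows and the envelopes of S compared.  Mean and envelope both
  growing by > 1.25× → `unbounded`; envelope below 2 % of the local
  mean and not growing → `converged`; a stationary non-vanishing
  envelope → `sustained_oscillation`; anything else is reported
  `inconclusive`, never silently classified.  The thresholds are
  separated by an order of magnitude from the shipped scenarios'
  behaviour (relative late-window amplitudes ~10⁻⁴, ~10, and mean
  growth ~1.0 vs ~1.5 respectively).

**Transient period window.** At h = h_crit + 5 the early transient
(t ≲ 900 d) consists of violent relaxation cycles whose spacing
(14–17 d) reflects the arbitrary initial history; from t ≈ 950 d to
convergence the oscillation is regular with an 11.9–12.0 d cycle,
matching the adult-longevity timescale 1/μ_a = 12.4 d.  The package
measures the period on the regular window [1000, 2000] d.

## Problem sizes

Reference runs use step 0.05 d and horizons chosen per purpose:
4000 d for the convergence scenario (equilibrium agreement to 1 % is
reached well before), 2100–2200 d for the transient-period measurement,
3000 d for the regime gallery, 1000 d insect-free.  These horizons are
the package's defaults for the respective analyses; the scenario
presets carry them.

## What the defaults do and do not show

The default scenarios emulate the standard release configuration
(50 adults on a 500-unit rhizome stand) with constant histories.  Real
releases face seasonality, temperature-dependent rates, overwintering,
spatial spread of the stand and stochasticity in small populations —
none of which is modelled; the adult equilibrium value (~0.4 insects)
is far below the scale at which demographic noise could be ignored in
the field.  Passing tests therefore validate the deterministic model's
internal consistency and its threshold structure in h, not field-level
predictions.  Quantitative transient details (e.g. transient length)
also depend on the unavoidably arbitrary initial history and are
treated as soft, qualitative checks.
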