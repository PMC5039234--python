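"""Integrator and trajectory diagnostics.

The independent oracle for the insect-free reduction is a separately
coded 4th-order Adams–Bashforth integrator of the scalar rhizome
equation R'(t) = -mu_r R + k_r k_s ∫_0^{tau_s} R(t-η) e^{-mu_s η} dη,
with the distributed-delay integral evaluated by Simpson weights on the
same grid — a code path sharing nothing with the production stepper.
"""

import math

import numpy as np
import pytest

from itadori.params import preset
from itadori.simulate import (
    BlowupError,
    make_history,
    integrate,
    integral_consistency_check,
    growth_rate_estimate,
    oscillation_period,
    classify_regime_numeric,
    Trajectory,
)


class TestMakeHistory:
    def test_default_stem_biomass_is_insect_free_compatible(self, eq52):
        hist = make_history(eq52, 50.0, 500.0)
        expect = 0.1 * 500.0 * (1.0 - math.exp(-1.5)) / 0.01
        assert hist.S(0.0) == pytest.approx(expect, rel=1e-12)
        assert hist.S(0.0) == pytest.approx(3884.3, abs=0.05)
        # larval seed from the compatibility quadrature over constant histories
        S0 = hist.S(0.0)
        ml = eq52.k_l * math.exp(-S0) + eq52.m
        birth = eq52.P * 50.0 * math.exp(-eq52.q * 50.0 / S0)
        expect_L = birth * (1.0 - math.exp(-eq52.tau_p * ml)) / ml
        assert hist.L(0.0) == pytest.approx(expect_L, rel=1e-12)
        assert hist.L0_enforced
        assert not hist.S0_enforced  # positive larvae break the stem balance

    def test_no_adults_no_larvae(self, eq52):
        hist = make_history(eq52, 0.0, 500.0)
        assert hist.L(0.0) == 0.0
        assert hist.S0_enforced

    def test_no_rhizome_no_stems(self, eq52):
        hist = make_history(eq52, 10.0, 0.0)
        assert hist.S(0.0) == 0.0
        assert hist.L(0.0) == 0.0

    def test_negative_seed_rejected(self, eq52):
        with pytest.raises(ValueError):
            make_history(eq52, -1.0, 500.0)
        with pytest.raises(ValueError):
            make_history(eq52, 1.0, -5.0)


class TestGrowthRateEstimate:
    def _exp_traj(self, eq52, rate):
        t = np.arange(-150.0 / 0.5, 2001) * 0.5
        v = np.exp(rate * t)
        z = np.zeros_like(t)
        return Trajectory(
            t=t, L=v.copy(), A=v.copy(), S=v.copy(), R=v.copy(),
            M_l=z, M_f=z, step=0.5, i0=300, params=eq52, history=None,
        )

    def test_exact_exponential(self, eq52):
        traj = self._exp_traj(eq52, 0.05)
        assert growth_rate_estimate(traj, "R", (100, 800)) == pytest.approx(0.05, abs=1e-12)

    def test_constant_series(self, eq52):
        traj = self._exp_traj(eq52, 0.0)
        assert growth_rate_estimate(traj, "S", (0, 500)) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_rejected(self, eq52):
        traj = self._exp_traj(eq52, 0.01)
        traj.R[-5] = 0.0
        with pytest.raises(ValueError):
            growth_rate_estimate(traj, "R", (900, 1000))


class TestOscillationPeriod:
    def _osc_traj(self, eq52, fn):
        t = np.arange(0, 12001) * 0.1
        v = fn(t)
        z = np.zeros_like(t)
        return Trajectory(
            t=t, L=v.copy(), A=v.copy(), S=v.copy(), R=v.copy(),
            M_l=z, M_f=z, step=0.1, i0=0, params=eq52, history=None,
        )

    def test_known_period(self, eq52):
        traj = self._osc_traj(eq52, lambda t: 5.0 + np.sin(2 * np.pi * t / 12.0))
        assert oscillation_period(traj, "L", (0, 1200)) == pytest.approx(12.0, abs=0.2)

    def test_constant_has_no_peaks(self, eq52):
        traj = self._osc_traj(eq52, lambda t: np.full_like(t, 3.0))
        with pytest.raises(ValueError):
            oscillation_period(traj, "L", (0, 1200))


class TestRegimeClassification:
    def _traj(self, eq52, v, t):
        z = np.zeros_like(t)
        return Trajectory(
            t=t, L=v.copy(), A=v.copy(), S=v.copy(), R=v.copy(),
            M_l=z, M_f=z, step=t[1] - t[0], i0=0, params=eq52, history=None,
        )

    def test_decaying_oscillation_converges(self, eq52):
        t = np.arange(0, 20000) * 0.1
        v = 10.0 + np.exp(-t / 150.0) * np.sin(2 * np.pi * t / 12.0)
        assert classify_regime_numeric(self._traj(eq52, v, t)) == "converged"

    def test_growing_envelope_is_unbounded(self, eq52):
        t = np.arange(0, 20000) * 0.1
        v = np.exp(0.01 * t) * (2.0 + np.sin(t))
        assert classify_regime_numeric(self._traj(eq52, v, t)) == "unbounded"

    def test_stationary_oscillation_sustained(self, eq52):
        t = np.arange(0, 20000) * 0.1
        v = 10.0 + 3.0 * np.sin(2 * np.pi * t / 12.0)
        assert classify_regime_numeric(self._traj(eq52, v, t)) == "sustained_oscillation"


class TestInsectFreeReduction:
    def test_zero_insects_stay_zero(self, insect_free_traj):
        assert np.all(insect_free_traj.L == 0.0)
        assert np.all(insect_free_traj.A == 0.0)

    def test_matches_scalar_rhizome_oracle(self, eq52, insect_free_traj):
        """Full 4-variable run vs an independent solve of the scalar
        rhizome equation.

        The distributed integral I(t) = ∫_0^{tau_s} R(t-η) e^{-mu_s η} dη
        obeys I' = R - e^{-mu_s tau_s} R(t - tau_s) - mu_s I, which turns
        the scalar equation into a 2-state ODE with one discrete lag,
        advanced interval-by-interval with scipy's adaptive DOP853 and
        dense output for the lagged term.
        """
        from scipy.integrate import solve_ivp

        p = eq52
        t_end = 300.0
        decay = math.exp(-p.mu_s * p.tau_s)
        I0 = 500.0 * (1.0 - decay) / p.mu_s

        sols = []

        def R_lag(t):
            tl = t - p.tau_s
            if tl <= 0.0:
                return 500.0
            for lo, hi, sol in sols:
                if lo - 1e-9 <= tl <= hi + 1e-9:
                    return float(sol.sol(tl)[0])
            raise AssertionError("lagged time not covered")

        def rhs(t, y):
            R, I = y
            return (-p.mu_r * R + p.k_r * p.k_s * I,
                    R - decay * R_lag(t) - p.mu_s * I)

        y0 = (500.0, I0)
        t0 = 0.0
        while t0 < t_end:
            t1 = min(t0 + p.tau_s, t_end)
            sol = solve_ivp(rhs, (t0, t1), y0, method="DOP853",
                            rtol=1e-12, atol=1e-6, dense_output=True)
            assert sol.success
            sols.append((t0, t1, sol))
            y0 = sol.y[:, -1]
            t0 = t1

        tq = np.arange(0.0, t_end + 1e-9, 1.0)
        oracle = np.array([
            next(float(s.sol(t)[0]) for lo, hi, s in sols if lo - 1e-9 <= t <= hi + 1e-9)
            for t in tq
        ])
        i0 = insect_free_traj.i0
        stride = int(round(1.0 / insect_free_traj.step))
        main = insect_free_traj.R[i0 : i0 + stride * (tq.size - 1) + 1 : stride]
        assert np.allclose(main, oracle, rtol=1e-6)

    def test_fitted_rate_matches_characteristic_root(self, insect_free_traj):
        from itadori.spectral import insect_free_dominant_root

        rate = growth_rate_estimate(insect_free_traj, "R", (600, 900))
        root = insect_free_dominant_root(insect_free_traj.params)
        assert rate == pytest.approx(root, rel=1e-3)

    def test_integral_consistency_exact(self, insect_free_traj):
        res = integral_consistency_check(insect_free_traj, [300, 600, 900])
        assert res < 1e-4


class TestTrajectoryInvariants:
    def test_non_negativity(self, fig1_traj):
        for name in ("L", "A", "S", "R"):
            assert np.all(fig1_traj.series(name) >= 0.0)
        assert fig1_traj.diagnostics["worst_negativity"] <= 1e-6

    def test_cumulants_non_decreasing(self, fig1_traj):
        assert np.all(np.diff(fig1_traj.M_l) >= 0)
        assert np.all(np.diff(fig1_traj.M_f) >= -1e-15)

    def test_step_halving_convergence(self, eq52, hc):
        """Terminal states in the convergent regime are step-insensitive."""
        p = eq52.replace(h=hc - 1.0)
        hist = make_history(p, 50.0, 500.0)
        a = integrate(p, hist, t_end=2500.0, step=0.05)
        b = integrate(p, hist, t_end=2500.0, step=0.025)
        for name in ("L", "A", "S", "R"):
            va, vb = a.series(name)[-1], b.series(name)[-1]
            assert va == pytest.approx(vb, rel=1e-4)

    def test_overflow_guard_raises(self, eq52):
        p = eq52.replace(h=1.0)
        hist = make_history(p, 0.0, 500.0)
        with pytest.raises(BlowupError):
            integrate(p, hist, t_end=500.0, overflow=1e6)

    def test_consistency_check_rejects_early_times(self, insect_free_traj):
        with pytest.raises(ValueError):
            integral_consistency_check(insect_free_traj, [10.0])

    def test_insects_only_slow_growth(self, eq52, hc):
        """Stem biomass under heavy-handling predation stays below insect-free."""
        p = eq52.replace(h=10.0 * hc)
        with_insects = integrate(p, make_history(p, 50.0, 500.0), t_end=150.0)
        without = integrate(p, make_history(p, 0.0, 500.0), t_end=150.0)
        sel = with_insects.t >= 0
        assert np.all(with_insects.S[sel] <= without.S[sel] * (1 + 1e-9))


def test_write_csv_roundtrip(tmp_path, insect_free_traj):
    out = tmp_path / "traj.csv"
    insect_free_traj.write_csv(out, every=0.5)
    data = np.loadtxt(out, delimiter=",", skiprows=1)
    assert data.shape[1] == 5
    assert data[0, 0] == pytest.approx(0.0)
    idx = insect_free_traj.i0
    assert data[0, 4] == pytest.approx(insect_free_traj.R[idx])
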