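import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from terlake import (
    InvalidParameterError,
    ModelParams,
    ModelState,
    SteadyState,
    Supply,
    gpp_from_state,
    growth_factors,
    light_limitation,
    monod,
    rhs,
    solve_steady_state,
)


class TestModelParams:
    def test_defaults_valid(self):
        p = ModelParams()
        assert p.mu_max > p.a

    @pytest.mark.parametrize("field", ["mu_max", "a", "m_P", "c_P", "k_A", "z_max"])
    def test_nonpositive_rejected(self, field):
        with pytest.raises(InvalidParameterError):
            ModelParams(**{field: 0.0})
        with pytest.raises(InvalidParameterError):
            ModelParams(**{field: -1.0})

    def test_washout_regime_warns(self):
        with pytest.warns(UserWarning, match="washout"):
            ModelParams(a=1.5, mu_max=1.0)

    def test_consumption_ratio_molar(self):
        # Redfield-proportioned quotas: (0.1084/14.007)/(0.015/30.974)
        assert ModelParams().consumption_ratio_molar == pytest.approx(15.98, abs=0.01)

    def test_supply_positive(self):
        with pytest.raises(InvalidParameterError):
            Supply(N_in=0.0, P_in=30.0)
        with pytest.raises(InvalidParameterError):
            Supply(N_in=700.0, P_in=-5.0)

    def test_state_clips_tiny_negatives(self):
        s = ModelState(A=-1e-13, N=5.0, P=1.0)
        assert s.A == 0.0
        with pytest.raises(InvalidParameterError):
            ModelState(A=-1e-3, N=5.0, P=1.0)


class TestMonod:
    def test_half_saturation(self):
        assert monod(1.5, 1.5) == pytest.approx(0.5)
        assert monod(0.7, 0.7) == pytest.approx(0.5)

    def test_zero_concentration(self):
        assert monod(0.0, 3.0) == 0.0

    def test_invalid_halfsat(self):
        with pytest.raises(InvalidParameterError):
            monod(1.0, 0.0)

    @given(
        conc=st.floats(0.0, 1e6),
        halfsat=st.floats(1e-6, 1e4),
        delta=st.floats(1e-6, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_increasing(self, conc, halfsat, delta):
        f = monod(conc, halfsat)
        assert 0.0 <= f < 1.0
        f2 = monod(conc + delta, halfsat)
        assert f2 >= f
        if conc < 100 * halfsat:  # away from float-precision saturation
            assert f2 > f


class TestLightLimitation:
    def test_no_light_saturation_limit(self):
        # h_I -> 0: the log ratio equals k*z_max exactly, so f_I -> 1.
        p = ModelParams(h_I=1e-12)
        assert light_limitation(500.0, p) == pytest.approx(1.0, abs=1e-6)

    def test_no_attenuation_limit(self):
        # A = 0, k_bg -> 0: depth average collapses to the surface Monod term.
        p = ModelParams(k_bg=1e-9)
        expected = p.I_in / (p.h_I + p.I_in)
        assert light_limitation(0.0, p) == pytest.approx(expected, rel=1e-6)

    def test_quadrature_oracle(self):
        # Closed form must match numerically averaging I(z)/(h+I(z)) in depth.
        p = ModelParams(k_bg=0.2, k_A=0.0008, z_max=2.5, I_in=300.0, h_I=120.0)
        A = 2000.0
        k = p.k_bg + p.k_A * A
        z = np.linspace(0.0, p.z_max, 10_001)
        irradiance = p.I_in * np.exp(-k * z)
        numeric = np.trapezoid(irradiance / (p.h_I + irradiance), z) / p.z_max
        assert light_limitation(A, p) == pytest.approx(numeric, abs=1e-4)

    @given(a1=st.floats(0.0, 5e4), delta=st.floats(1.0, 5e4))
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_biomass(self, a1, delta):
        p = ModelParams()
        f1 = light_limitation(a1, p)
        assert 0.0 < f1 <= 1.0
        assert light_limitation(a1 + delta, p) < f1

    def test_negative_biomass_rejected(self):
        with pytest.raises(InvalidParameterError):
            light_limitation(-1.0, ModelParams())


class TestGrowthFactors:
    def test_symmetric_tie_breaks_to_n(self):
        from scipy.optimize import brentq

        p = ModelParams()
        a_half = brentq(lambda A: light_limitation(A, p) - 0.5, 1.0, 1e5)
        f_N, f_P, f_I, limiter = growth_factors(ModelState(a_half, p.m_N, p.m_P), p)
        assert f_N == pytest.approx(0.5)
        assert f_P == pytest.approx(0.5)
        assert f_I == pytest.approx(0.5, abs=1e-9)
        assert limiter == "N"

    def test_phosphorus_starvation(self):
        p = ModelParams(h_I=1e-12)  # light factor ~1 so nutrients decide
        f_N, f_P, f_I, limiter = growth_factors(ModelState(10.0, 1e6, 0.0), p)
        assert f_P == 0.0
        assert limiter == "P"


class TestRhs:
    def test_no_biomass_pure_dilution(self):
        p = ModelParams()
        supply = Supply(700.0, 30.0)
        dA, dN, dP = rhs(ModelState(0.0, 100.0, 10.0), p, supply)
        assert dA == 0.0
        assert dN == pytest.approx(p.a * (supply.N_in - 100.0))
        assert dP == pytest.approx(p.a * (supply.P_in - 10.0))

    def test_consumption_is_quota_times_production(self):
        p = ModelParams()
        supply = Supply(700.0, 30.0)
        state = ModelState(1.0, supply.N_in, supply.P_in)
        f_N, f_P, f_I, _ = growth_factors(state, p)
        mu = p.mu_max * min(f_N, f_P, f_I)
        _, dN, dP = rhs(state, p, supply)
        assert dN == pytest.approx(-p.c_N * mu * 1.0)
        assert dP == pytest.approx(-p.c_P * mu * 1.0)

    def test_derivatives_vanish_at_steady_state(self):
        p = ModelParams()
        supply = Supply(700.0, 100.0)
        ss = solve_steady_state(p, supply)
        derivs = rhs(ss.state, p, supply)
        for d, x in zip(derivs, (ss.state.A, ss.state.N, ss.state.P)):
            assert abs(d) / (abs(x) + 1e-6) < 1e-6


class TestSolveSteadyState:
    def test_washout_when_dilution_exceeds_growth(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = ModelParams(a=1.2, mu_max=1.0)
        ss = solve_steady_state(p, Supply(700.0, 30.0))
        assert ss.washout
        assert ss.gpp == 0.0
        assert ss.state.N == pytest.approx(700.0, rel=1e-3)
        assert ss.state.P == pytest.approx(30.0, rel=1e-3)

    def test_closed_form_chemostat(self):
        # R* rule + mass balance, with light saturated (h_I -> 0) and N huge.
        p = ModelParams(h_I=1e-9, mu_max=1.0, a=0.1, m_P=1.5, c_P=0.015)
        ss = solve_steady_state(p, Supply(1e6, 100.0))
        p_star = p.m_P * p.a / (p.mu_max - p.a)
        a_star = (100.0 - p_star) / p.c_P
        assert ss.limiter == "P"
        assert ss.state.P == pytest.approx(p_star, rel=1e-3)  # 0.16667
        assert ss.state.A == pytest.approx(a_star, rel=1e-3)  # 6655.6
        assert ss.gpp == pytest.approx(0.1 * a_star * (32.0 / 12.0) / 1000.0, rel=1e-3)

    def test_growth_balances_dilution(self):
        p = ModelParams()
        for supply in (Supply(700.0, 30.0), Supply(700.0, 150.0), Supply(7000.0, 300.0)):
            ss = solve_steady_state(p, supply, tol=1e-6)
            assert ss.converged and not ss.washout
            assert abs(ss.mu - p.a) <= 10 * 1e-6

    def test_mass_balance(self):
        p = ModelParams()
        supply = Supply(500.0, 60.0)
        ss = solve_steady_state(p, supply)
        assert p.a * (supply.N_in - ss.state.N) == pytest.approx(
            p.c_N * ss.mu * ss.state.A, rel=1e-4
        )
        assert p.a * (supply.P_in - ss.state.P) == pytest.approx(
            p.c_P * ss.mu * ss.state.A, rel=1e-4
        )

    def test_solver_setting_validation(self):
        p = ModelParams()
        with pytest.raises(InvalidParameterError):
            solve_steady_state(p, Supply(700.0, 30.0), t_max=100.0)
        with pytest.raises(InvalidParameterError):
            solve_steady_state(p, Supply(700.0, 30.0), tol=0.1)


class TestGpp:
    def _steady(self, mu, A, washout=False):
        return SteadyState(
            state=ModelState(A, 1.0, 1.0),
            f_N=0.5,
            f_P=0.5,
            f_I=0.5,
            limiter="N",
            mu=mu,
            gpp=0.0,
            converged=True,
            washout=washout,
        )

    def test_washout_zero(self):
        assert gpp_from_state(self._steady(0.05, 1e-6, washout=True), ModelParams()) == 0.0

    def test_arithmetic(self):
        ss = self._steady(0.1, 6655.6)
        assert gpp_from_state(ss, ModelParams(o2_per_c=32.0 / 12.0)) == pytest.approx(1.775, abs=1e-3)

    def test_linearity_in_conversion(self):
        ss = self._steady(0.1, 1234.5)
        one = gpp_from_state(ss, ModelParams(o2_per_c=32.0 / 12.0))
        two = gpp_from_state(ss, ModelParams(o2_per_c=64.0 / 12.0))
        assert two == pytest.approx(2 * one)


def test_integration_agrees_with_root_finding_oracle():
    """20 random draws within +/-50% of defaults: 3-significant-figure match."""
    from _semianalytic import steady_state_oracle

    rng = np.random.default_rng(3)
    checked = 0
    for _ in range(20):
        f = lambda: rng.uniform(0.5, 1.5)
        p = ModelParams(
            a=min(0.1 * f(), 0.9),
            m_N=10.8 * f(),
            m_P=1.5 * f(),
            c_N=0.1084 * f(),
            c_P=0.015 * f(),
            k_bg=0.2 * f(),
            k_A=7.3e-4 * f(),
            z_max=2.5 * f(),
            I_in=300.0 * f(),
            h_I=120.0 * f(),
        )
        supply = Supply(rng.uniform(100.0, 2000.0), rng.uniform(10.0, 300.0))
        a_o, n_o, p_o, _ = steady_state_oracle(p, supply)
        ss = solve_steady_state(p, supply)
        for expected, got in ((a_o, ss.state.A), (n_o, ss.state.N), (p_o, ss.state.P)):
            assert got == pytest.approx(expected, rel=1e-3, abs=1e-6)
        checked += 1
    assert checked == 20
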