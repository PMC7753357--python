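"""One-compartment infusion kinetics: closed form vs ODE oracle, invariants."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from teicopk.pk_core import (
    DoseEvent,
    PKParameters,
    Regimen,
    conc_profile,
    steady_state_auc24,
    trough,
)


def ode_oracle(params: PKParameters, regimen: Regimen, times):
    """Stiff numerical integration of dC/dt = R(t)/V - k*C."""

    def rate(t):
        return sum(
            e.amount / e.duration
            for e in regimen
            if e.time <= t < e.time + e.duration
        )

    sol = solve_ivp(
        lambda t, y: [rate(t) / params.v - params.k * y[0]],
        (0.0, max(times) + 1e-9),
        [0.0],
        t_eval=times,
        method="LSODA",
        rtol=1e-10,
        atol=1e-13,
        max_step=0.1,
    )
    return sol.y[0]


def loading_regimen(amount=167.0, duration=0.5):
    return Regimen(tuple(DoseEvent(t, amount, duration) for t in (0.0, 12.0, 24.0)))


class TestConcProfile:
    def test_empty_regimen_is_zero(self):
        p = PKParameters(0.234, 2.43)
        assert np.all(conc_profile(p, Regimen(), [0.0, 1.0, 48.0]) == 0.0)

    def test_superposition_of_two_identical_doses(self):
        p = PKParameters(0.234, 2.43)
        t = np.linspace(0, 48, 97)
        single0 = conc_profile(p, Regimen((DoseEvent(0.0, 167.0, 0.5),)), t)
        single12 = conc_profile(p, Regimen((DoseEvent(12.0, 167.0, 0.5),)), t)
        both = conc_profile(
            p, Regimen((DoseEvent(0.0, 167.0, 0.5), DoseEvent(12.0, 167.0, 0.5))), t
        )
        np.testing.assert_allclose(both, single0 + single12, rtol=0, atol=1e-12)

    def test_dose_linearity_is_exact(self):
        p = PKParameters(0.234, 2.43)
        t = np.linspace(0.1, 60, 50)
        base = conc_profile(p, loading_regimen(100.0), t)
        scaled = conc_profile(p, loading_regimen(250.0), t)
        np.testing.assert_allclose(scaled, 2.5 * base, rtol=1e-13)

    def test_no_contribution_before_dose_start(self):
        p = PKParameters(0.234, 2.43)
        c = conc_profile(p, Regimen((DoseEvent(12.0, 167.0, 0.5),)), [0.0, 6.0, 11.9])
        assert np.all(c == 0.0)

    def test_matches_ode_oracle_single_dose(self):
        p = PKParameters(0.234, 2.43)
        reg = Regimen((DoseEvent(0.0, 167.0, 0.5),))
        t = np.linspace(0.05, 48, 160)
        closed = conc_profile(p, reg, t)
        numeric = ode_oracle(p, reg, t)
        np.testing.assert_allclose(closed, numeric, rtol=1e-3)

    def test_matches_ode_oracle_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(4):
            p = PKParameters(0.234 * rng.lognormal(0, 0.5), 2.43 * rng.lognormal(0, 0.5))
            reg = Regimen(
                tuple(
                    DoseEvent(float(12 * i), float(rng.uniform(50, 400)), 0.5)
                    for i in range(3)
                )
            )
            t = np.linspace(0.1, 48, 120)
            closed = conc_profile(p, reg, t)
            numeric = ode_oracle(p, reg, t)
            mask = closed > 1e-3 * closed.max()
            rel = np.abs(closed[mask] - numeric[mask]) / closed[mask]
            assert rel.max() < 1e-3

    def test_bolus_limit_equals_amount_over_volume(self):
        p = PKParameters(0.234, 2.43)
        reg = Regimen((DoseEvent(0.0, 167.0, 0.0),))
        c = conc_profile(p, reg, [0.0, 5.0])
        assert c[0] == pytest.approx(167.0 / 2.43)
        assert c[1] == pytest.approx(167.0 / 2.43 * np.exp(-p.k * 5.0))

    def test_monotone_washout_after_last_infusion(self):
        p = PKParameters(0.234, 2.43)
        t = np.linspace(24.5, 96, 200)
        c = conc_profile(p, loading_regimen(), t)
        assert np.all(np.diff(c) < 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PKParameters(-1.0, 2.0)
        with pytest.raises(ValueError):
            PKParameters(np.inf, 2.0)

    def test_unsorted_regimen_is_normalized(self):
        p = PKParameters(0.234, 2.43)
        shuffled = Regimen((DoseEvent(24.0, 167.0, 0.5), DoseEvent(0.0, 167.0, 0.5)))
        assert shuffled.events[0].time == 0.0
        ordered = Regimen((DoseEvent(0.0, 167.0, 0.5), DoseEvent(24.0, 167.0, 0.5)))
        t = [30.0, 48.0]
        np.testing.assert_array_equal(
            conc_profile(p, shuffled, t), conc_profile(p, ordered, t)
        )


class TestTrough:
    def test_before_first_dose_is_zero(self):
        p = PKParameters(0.234, 2.43)
        reg = Regimen((DoseEvent(12.0, 167.0, 0.5),))
        assert trough(p, reg, 6.0) == 0.0

    def test_typical_patient_three_loading_doses(self):
        # hand superposition of three decayed end-of-infusion concentrations
        p = PKParameters(0.2338, 2.4325)
        assert trough(p, loading_regimen(), 48.0) == pytest.approx(9.9, abs=0.1)

    def test_doubling_amounts_doubles_trough(self):
        p = PKParameters(0.2338, 2.4325)
        t1 = trough(p, loading_regimen(167.0), 48.0)
        t2 = trough(p, loading_regimen(334.0), 48.0)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_warns_inside_infusion(self):
        p = PKParameters(0.234, 2.43)
        with pytest.warns(UserWarning, match="not a trough"):
            trough(p, loading_regimen(), 12.25)


class TestSteadyStateAUC24:
    def test_zero_dose(self):
        assert steady_state_auc24(0.0, 0.234) == 0.0

    def test_direct_division(self):
        assert steady_state_auc24(240.0, 0.234) == pytest.approx(1025.6, abs=0.1)

    def test_nonpositive_clearance_rejected(self):
        with pytest.raises(ValueError):
            steady_state_auc24(240.0, 0.0)

    def test_consistent_with_trapezoid_at_steady_state(self):
        # day-10 window of q24h dosing vs dose/CL
        p = PKParameters(0.2338, 2.4325)
        reg = Regimen(tuple(DoseEvent(24.0 * i, 167.0, 0.5) for i in range(11)))
        t = np.linspace(216.0, 240.0, 4001)
        auc_trap = np.trapezoid(conc_profile(p, reg, t), t)
        assert auc_trap == pytest.approx(steady_state_auc24(167.0, p.cl), rel=0.01)


class TestPropertyBased:
    from hypothesis import given, settings, strategies as st

    @staticmethod
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        cl=st.floats(0.02, 2.0),
        v=st.floats(0.5, 20.0),
        amounts=st.lists(st.floats(10.0, 500.0), min_size=1, max_size=5),
        scale=st.floats(0.1, 10.0),
    )
    def test_linearity_and_nonnegativity(cl, v, amounts, scale):
        p = PKParameters(cl, v)
        reg = Regimen(
            tuple(DoseEvent(12.0 * i, a, 0.5) for i, a in enumerate(amounts))
        )
        t = np.linspace(0, 12.0 * len(amounts) + 24, 40)
        c = conc_profile(p, reg, t)
        assert np.all(c >= 0)
        np.testing.assert_allclose(
            conc_profile(p, reg.scaled(scale), t), scale * c, rtol=1e-12, atol=1e-12
        )
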