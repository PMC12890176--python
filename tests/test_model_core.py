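"""Auxiliary functions, activation rates and the assembled RHS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rciburn import (
    Exposure,
    InvalidParameterError,
    activation_rates,
    dose_delay_v,
    hill_omega,
    inhibitory_omega,
    rhs,
)
from rciburn.model import IDX, M2_INHIBITION_DOSE_GY, STATE_NAMES

from .conftest import random_states
from .oracles import naive_rhs


class TestInhibitoryOmega:
    @pytest.mark.parametrize(
        "x,pairs,expected",
        [
            (3.0, [], 3.0),                                # empty sum
            (2.0, [(1.0, 1.0)], 1.0),                      # Y == Y_inf halves
            (1.0, [(2.0, 1.0), (3.0, 3.0)], 1.0 / 6.0),    # 1/(1+4+1)
        ],
    )
    def test_values(self, x, pairs, expected):
        assert inhibitory_omega(x, pairs) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_saturation(self):
        with pytest.raises(InvalidParameterError):
            inhibitory_omega(1.0, [(1.0, 0.0)])

    @given(
        x=st.floats(0.0, 10.0),
        y1=st.floats(0.0, 5.0),
        y2=st.floats(0.0, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_decreasing_in_inhibitor(self, x, y1, y2):
        lo, hi = sorted([y1, y2])
        f_lo = inhibitory_omega(x, [(lo, 0.7)])
        f_hi = inhibitory_omega(x, [(hi, 0.7)])
        assert f_lo <= x
        assert f_hi <= f_lo  # non-increasing in the inhibitor level


class TestHillOmega:
    @pytest.mark.parametrize(
        "x,n,xh,expected",
        [
            (0.7, 6, 0.7, 0.5),        # half-saturation
            (0.0, 6, 0.5, 0.0),
            (2.0, 6, 1.0, 64.0 / 65.0),
        ],
    )
    def test_values(self, x, n, xh, expected):
        assert hill_omega(x, n, xh) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_level(self):
        grid = np.linspace(0.0, 3.0, 50)
        values = [hill_omega(x, 6, 0.4) for x in grid]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_rejects_bad_half_saturation(self):
        with pytest.raises(InvalidParameterError):
            hill_omega(1.0, 6, -1.0)


class TestDoseDelay:
    def test_unity_without_dose(self):
        for t in (0.0, 1.0, 500.0):
            assert dose_delay_v(t, 0.0, 0.01) == 1.0

    def test_zero_at_exposure_time(self):
        assert dose_delay_v(0.0, 5.0, 0.01) == 0.0

    def test_half_recovery_at_log2(self):
        gamma, dose = 0.01, 5.0
        t = math.log(2.0) / (gamma * dose)
        assert dose_delay_v(t, dose, gamma) == pytest.approx(0.5, rel=1e-12)

    def test_monotone_saturating(self):
        times = np.linspace(0.0, 2000.0, 40)
        vals = [dose_delay_v(t, 3.0, 0.005) for t in times]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0 and vals[-1] > 0.99

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            dose_delay_v(-1.0, 1.0, 0.01)


class TestActivationRates:
    def test_quiet_wound_gives_zero_cell_rates(self, baseline):
        state = np.zeros(len(STATE_NAMES))
        state[IDX["M_st_ud"]] = 1.0  # resident pool present but no signals
        rates = activation_rates(state, baseline, 0.0)
        assert rates.Rm1 == rates.Rm2 == rates.Rl1 == rates.Rl2 == 0.0

    def test_neutrophil_rate_formula(self, baseline, rng):
        # Deb = P = 0, N > 0: Rn = knn*N / (1 + (M2/M2inf)^2 + (L2/L21inf)^2)
        state = np.zeros(len(STATE_NAMES))
        state[IDX["N_tb"]] = 0.8
        state[IDX["M2_tb"]] = 0.3
        state[IDX["L2_tb"]] = 0.2
        p = baseline
        expected = p.knn * 0.8 / (1 + (0.3 / p.M2_inf) ** 2 + (0.2 / p.L21_inf) ** 2)
        assert activation_rates(state, p, 0.0).Rn == pytest.approx(expected, rel=1e-12)

    def test_rates_nonnegative_on_random_states(self, baseline, rng):
        for state in random_states(rng, 20):
            rates = activation_rates(state, baseline, 3.0)
            assert min(rates.Rn, rates.Rm1, rates.Rm2, rates.Rl1, rates.Rl2) >= 0


class TestRhs:
    def test_matches_naive_oracle_on_random_states(self, baseline, rng):
        """Production RHS equals the hand-coded term-by-term oracle."""
        pdict = baseline.to_dict()
        for dose in (0.0, 1.9, 2.0, 7.0):
            exposure = Exposure(fluence=0.0, dose_gy=dose)
            for state in random_states(rng, 30):
                t = float(rng.uniform(0.0, 300.0))
                got = rhs(t, state, baseline, exposure)
                expected = naive_rhs(t, dict(zip(STATE_NAMES, state)), pdict, dose)
                for i, name in enumerate(STATE_NAMES):
                    assert got[i] == pytest.approx(expected[name], rel=1e-12, abs=1e-15)

    def test_pathogen_axis_invariant(self, baseline, rng):
        """Every pathogen flux carries P: dP/dt = 0 whenever P = 0."""
        for state in random_states(rng, 10):
            state[IDX["P_tb"]] = 0.0
            out = rhs(10.0, state, baseline, Exposure(0.0, 5.0))
            assert out[IDX["P_tb"]] == 0.0

    def test_clean_tissue_generates_no_damage(self, baseline):
        """No damage/debris production when the wound is empty and the
        surrounding tissue is at rest."""
        state = np.zeros(len(STATE_NAMES))
        state[IDX["M_st_ud"]] = 1.0
        state[IDX["L_st_ud"]] = 1.0
        state[IDX["F_st_ud"]] = 0.4
        out = rhs(0.0, state, baseline, Exposure(0.0, 0.0))
        assert out[IDX["Dam_tb"]] == 0.0
        assert out[IDX["Deb_tb"]] == 0.0

    def test_dose_switch_changes_only_m2_fluxes(self, baseline, rng):
        """Crossing 2 Gy at fixed state alters exactly the three components
        carrying the M2-activation flux."""
        state = random_states(rng, 1)[0]
        state[IDX["M_st_d"]] = 0.6  # damaged monocytes present
        below = rhs(24.0, state, baseline, Exposure(0.0, M2_INHIBITION_DOSE_GY - 0.1))
        above = rhs(24.0, state, baseline, Exposure(0.0, M2_INHIBITION_DOSE_GY))
        changed = {
            name
            for i, name in enumerate(STATE_NAMES)
            if not np.isclose(below[i], above[i], rtol=1e-9, atol=1e-13)
        }
        # v(t, DR) also shifts slightly with dose; isolate by matching gammas
        # to a dose-free comparison: only M2-flux carriers may differ beyond
        # the influx terms.
        influx_states = {"N_st_ud", "L_st_ud", "F_st_ud"}
        assert changed - influx_states <= {"M_st_ud", "M_st_d", "M2_tb"}
        assert "M2_tb" in changed

    def test_dose_switch_exact_inhibition_factor(self, baseline):
        """At the switch the M2 flux is scaled by exactly
        1/(1 + (M_st_d/omega_m2)^2)."""
        state = np.zeros(len(STATE_NAMES))
        state[IDX["M_st_ud"]] = 0.5
        state[IDX["M_st_d"]] = 0.4
        state[IDX["M1_tb"]] = 0.3  # drives Rm2 via km2m1
        p = baseline
        below = rhs(0.0, state, p, Exposure(0.0, 1.9))
        above = rhs(0.0, state, p, Exposure(0.0, 2.0))
        factor = 1.0 / (1.0 + (0.4 / p.omega_m2) ** 2)
        # at t = 0 the influx terms vanish for DR > 0 in both cases
        flux_below = below[IDX["M2_tb"]]
        flux_above = above[IDX["M2_tb"]]
        assert flux_above == pytest.approx(flux_below * factor, rel=1e-12)

    def test_inhibition_monotonicity_by_finite_differences(self, baseline, rng):
        """Raising an inhibitor never raises the flux it gates: the M2 and
        L2 levels gate neutrophil activation (Rn * N_st_ud term)."""
        for state in random_states(rng, 10):
            state[IDX["N_st_ud"]] = 0.5
            base = rhs(10.0, state, baseline, Exposure(0.0, 0.0))
            for inhibitor in ("M2_tb", "L2_tb"):
                bumped = state.copy()
                bumped[IDX[inhibitor]] += 0.25
                out = rhs(10.0, bumped, baseline, Exposure(0.0, 0.0))
                # neutrophil activation flux appears with + sign in dN_tb
                # and - sign in dN_st_ud; bumping the inhibitor weakens it
                assert out[IDX["N_st_ud"]] >= base[IDX["N_st_ud"]] - 1e-12
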