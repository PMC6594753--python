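"""Kinetic scheme right-hand sides, integration, and steady-state theory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cftrpot import (
    DrugProtocol,
    GatingParams,
    Scheme,
    derived_affinities,
    integrate_protocol,
    midpoint_hill_slope,
    normalized_current,
    rhs,
    steady_state_concentrations,
    steady_state_response,
)
from cftrpot.schemes import _RHS, initial_state

from conftest import fast_params

ALL_SCHEMES = list(Scheme)


def params_for(scheme: Scheme, c_t: float = 1.66e-6, **over) -> GatingParams:
    kwargs = dict(k_in=4034.0, k_out=0.06446, k_on=870.3, k_off=0.007451,
                  po_ratio=3.935, c_t=c_t)
    if scheme.two_compartment:
        kwargs["k_flip"] = 0.04408
    kwargs.update(over)
    return GatingParams(**kwargs)


class TestRhs:
    @pytest.mark.parametrize("scheme", ALL_SCHEMES)
    def test_unliganded_no_drug_is_fixed_point(self, scheme):
        p = params_for(scheme)
        dx = rhs(scheme, p, initial_state(scheme, p), v_c=0.0)
        assert np.allclose(dx, 0.0, atol=1e-25)

    def test_drug_entry_flux_arithmetic(self, wt_params):
        # at drug-free state the only nonzero term is the entry flux k_in*V_c
        x0 = initial_state(Scheme.TWO_SITE, wt_params)
        dx = rhs(Scheme.TWO_SITE, wt_params, x0, v_c=62e-9)
        assert dx[0] == pytest.approx(4034.0 * 62e-9, rel=1e-12)
        assert dx[0] == pytest.approx(2.50e-4, rel=1e-2)

    def test_dimension_mismatch_rejected(self, wt_params):
        with pytest.raises(ValueError, match="length"):
            rhs(Scheme.TWO_SITE, wt_params, [0.0, 0.0], v_c=0.0)

    def test_negative_state_rejected(self, wt_params):
        with pytest.raises(ValueError, match="non-negative"):
            rhs(Scheme.TWO_SITE, wt_params, [-1e-9, 0.0, 0.0], v_c=0.0)

    def test_flip_rate_required_and_forbidden(self):
        with pytest.raises(ValueError, match="requires k_flip"):
            rhs(Scheme.ONE_SITE_FLIP, params_for(Scheme.ONE_SITE),
                [0.0, 0.0, 1e-6], 0.0)
        with pytest.raises(ValueError, match="does not take"):
            rhs(Scheme.ONE_SITE, params_for(Scheme.ONE_SITE_FLIP),
                [0.0, 1e-6], 0.0)


class TestNormalizedCurrent:
    def test_all_non_potentiated_gives_one(self, wt_params):
        ct = wt_params.c_t
        assert normalized_current(
            Scheme.TWO_SITE, wt_params, [0.0, 0.3 * ct, 0.7 * ct]
        ) == pytest.approx(1.0)

    def test_all_diliganded_gives_po_ratio(self, wt_params):
        assert normalized_current(
            Scheme.TWO_SITE, wt_params, [0.0, 0.0, 0.0]
        ) == pytest.approx(wt_params.po_ratio)

    def test_half_potentiated_interpolates(self, wt_params):
        ct = wt_params.c_t
        val = normalized_current(Scheme.TWO_SITE, wt_params,
                                 [0.0, 0.25 * ct, 0.25 * ct])
        assert val == pytest.approx(0.5 + 0.5 * 3.935, rel=1e-12)
        assert val == pytest.approx(2.4675, rel=1e-12)


class TestIntegration:
    def test_no_drug_stays_at_unity(self, wt_params):
        sim = integrate_protocol(
            Scheme.TWO_SITE, wt_params, DrugProtocol([(60.0, 0.0)]), dt=0.05
        )
        assert np.allclose(sim.i_norm, 1.0, atol=1e-12)

    @pytest.mark.parametrize("scheme", ALL_SCHEMES)
    def test_long_integration_reaches_closed_form_steady_state(self, scheme):
        p = fast_params(scheme, 1.66e-6)
        v_c = 1e-9
        horizon = 50.0 / min(p.k_out, p.k_off)
        sim = integrate_protocol(scheme, p, DrugProtocol([(horizon, v_c)]),
                                 dt=0.1, record_every=100)
        assert sim.i_norm[-1] == pytest.approx(
            steady_state_response(scheme, p, v_c), rel=1e-4
        )
        conc = steady_state_concentrations(scheme, p, v_c)
        if scheme.two_compartment:
            assert sim.states is None
            sim2 = integrate_protocol(scheme, p, DrugProtocol([(horizon, v_c)]),
                                      dt=0.1, record_every=100, keep_states=True)
            assert sim2.states[-1][0] == pytest.approx(conc[0], rel=1e-4)
            assert sim2.states[-1][1] == pytest.approx(conc[1], rel=1e-4)
        else:
            sim2 = integrate_protocol(scheme, p, DrugProtocol([(horizon, v_c)]),
                                      dt=0.1, record_every=100, keep_states=True)
            assert sim2.states[-1][0] == pytest.approx(conc, rel=1e-4)

    def test_terminal_on_value_matches_steady_state(self, wt_params,
                                                    saturated_on_off):
        sim = integrate_protocol(Scheme.TWO_SITE, wt_params, saturated_on_off,
                                 dt=0.05)
        i_on_end = sim.i_norm[np.searchsorted(sim.t, 600.0)]
        assert i_on_end == pytest.approx(
            steady_state_response(Scheme.TWO_SITE, wt_params, 62e-9), rel=1e-4
        )

    def test_step_refinement_converges(self, wt_params, saturated_on_off):
        coarse = integrate_protocol(Scheme.TWO_SITE, wt_params,
                                    saturated_on_off, dt=0.01, record_every=100)
        fine = integrate_protocol(Scheme.TWO_SITE, wt_params,
                                  saturated_on_off, dt=0.005, record_every=200)
        on_common = np.interp(coarse.t, fine.t, fine.i_norm)
        assert np.max(np.abs(coarse.i_norm - on_common) / on_common) < 1e-4

    def test_channel_mass_stays_bounded(self, wt_params, saturated_on_off):
        sim = integrate_protocol(Scheme.TWO_SITE, wt_params, saturated_on_off,
                                 dt=0.05, keep_states=True)
        ct = wt_params.c_t
        channel_total = sim.states[:, 1] + sim.states[:, 2]
        assert np.all(channel_total <= ct * (1.0 + 1e-9))
        assert np.all(sim.states >= 0.0)

    def test_washout_returns_to_baseline(self, c_t_membrane):
        p = fast_params(Scheme.TWO_SITE, c_t_membrane)
        horizon = 50.0 / p.k_off
        proto = DrugProtocol([(200.0, 1e-9), (horizon, 0.0)])
        sim = integrate_protocol(Scheme.TWO_SITE, p, proto, dt=0.1,
                                 record_every=50)
        assert abs(sim.i_norm[-1] - 1.0) < 1e-3

    @pytest.mark.parametrize("scheme", ALL_SCHEMES)
    def test_specialized_stepper_matches_generic_heun(self, scheme):
        """The scalar-unrolled segment steppers must agree with a direct
        Heun step built on the public rhs to round-off."""
        p = fast_params(scheme, 1.66e-6)
        proto = DrugProtocol.on_off(1e-9, 10.0, 10.0)
        sim = integrate_protocol(scheme, p, proto, dt=0.05, keep_states=True)
        f = _RHS[scheme]
        kf = p.k_flip if p.k_flip is not None else 0.0
        n = scheme.n_states
        x = tuple(initial_state(scheme, p))
        traj = [x]
        for dur, vc in proto.segments:
            n_steps = math.ceil(dur / 0.05)
            h = dur / n_steps
            for _ in range(n_steps):
                k1 = f(x, vc, p.k_in, p.k_out, p.k_on, p.k_off, kf, p.c_t)
                xp = tuple(x[i] + h * k1[i] for i in range(n))
                k2 = f(xp, vc, p.k_in, p.k_out, p.k_on, p.k_off, kf, p.c_t)
                x = tuple(x[i] + 0.5 * h * (k1[i] + k2[i]) for i in range(n))
                traj.append(x)
        assert np.allclose(sim.states, np.array(traj), rtol=0, atol=1e-18)

    def test_bad_dt_rejected(self, wt_params, saturated_on_off):
        with pytest.raises(ValueError):
            integrate_protocol(Scheme.TWO_SITE, wt_params, saturated_on_off,
                               dt=-1.0)


class TestSteadyStateTheory:
    def test_zero_drug_zero_membrane(self, wt_params):
        assert steady_state_concentrations(Scheme.TWO_SITE, wt_params, 0.0) == 0.0

    def test_membrane_accumulation_value(self, wt_params):
        v_m = steady_state_concentrations(Scheme.TWO_SITE, wt_params, 62e-9)
        assert v_m == pytest.approx(62e-9 * 4034.0 / (2 * 0.06446), rel=1e-12)
        assert v_m == pytest.approx(1.94e-3, rel=1e-2)

    def test_fast_flip_approaches_single_compartment_form(self):
        p = params_for(Scheme.TWO_SITE_FLIP, k_flip=1e4)
        _, v_me = steady_state_concentrations(Scheme.TWO_SITE_FLIP, p, 62e-9)
        one_comp = 62e-9 * p.k_in / p.k_out / 2.0
        assert v_me == pytest.approx(one_comp, rel=1e-3)

    def test_response_limits(self, wt_params):
        assert steady_state_response(Scheme.TWO_SITE, wt_params, 0.0) == 1.0
        assert steady_state_response(Scheme.TWO_SITE, wt_params, 1.0) \
            == pytest.approx(wt_params.po_ratio, rel=1e-6)

    def test_response_at_membrane_kd(self, wt_params):
        # V_inf = Kd => Y2 = 1/4
        kd = wt_params.k_off / wt_params.k_on
        v_c = kd / (wt_params.k_in / (2 * wt_params.k_out))
        expect = 1.0 + (wt_params.po_ratio - 1.0) * 0.25
        assert steady_state_response(Scheme.TWO_SITE, wt_params, v_c) \
            == pytest.approx(expect, rel=1e-12)

    def test_saturated_stimulation_close_to_fourfold(self, wt_params):
        assert steady_state_response(Scheme.TWO_SITE, wt_params, 62e-9) \
            == pytest.approx(3.9, abs=0.05)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=-12, max_value=-6))
    def test_response_monotone_in_concentration(self, wt_params, log_vc):
        v1, v2 = 10.0**log_vc, 10.0 ** (log_vc + 0.5)
        assert steady_state_response(Scheme.TWO_SITE, wt_params, v2) >= \
            steady_state_response(Scheme.TWO_SITE, wt_params, v1)

    def test_derived_affinity_formulas(self):
        p = params_for(Scheme.TWO_SITE, k_off=0.01, k_on=1000.0)
        kd, k05m, _ = derived_affinities(Scheme.TWO_SITE, p)
        assert kd == pytest.approx(10e-6, rel=1e-12)
        assert k05m == pytest.approx(24.14e-6, rel=1e-3)
        p1 = params_for(Scheme.ONE_SITE, k_off=0.01, k_on=1000.0)
        kd1, k05m1, _ = derived_affinities(Scheme.ONE_SITE, p1)
        assert k05m1 == kd1

    def test_aqueous_affinity_subnanomolar(self, wt_params):
        _, _, k05aq = derived_affinities(Scheme.TWO_SITE, wt_params)
        expect = (1 + math.sqrt(2)) * (0.007451 / 870.3) / (4034.0 / (2 * 0.06446))
        assert k05aq == pytest.approx(expect, rel=1e-12)
        assert k05aq * 1e9 == pytest.approx(0.66, abs=0.02)

    def test_half_maximal_at_derived_k05(self, wt_params):
        """K_0.5;aq really is the aqueous concentration giving half-maximal
        fractional response."""
        _, _, k05aq = derived_affinities(Scheme.TWO_SITE, wt_params)
        resp = steady_state_response(Scheme.TWO_SITE, wt_params, k05aq)
        frac = (resp - 1.0) / (wt_params.po_ratio - 1.0)
        assert frac == pytest.approx(0.5, rel=1e-9)


class TestHillSlope:
    def test_one_site_slope_is_unity(self):
        assert midpoint_hill_slope(Scheme.ONE_SITE) == 1.0
        assert midpoint_hill_slope(Scheme.ONE_SITE_FLIP) == 1.0

    def test_two_site_slope_value(self):
        expect = 2.0 * (2.0 - math.sqrt(2.0))
        assert midpoint_hill_slope(Scheme.TWO_SITE) == pytest.approx(expect)
        assert midpoint_hill_slope(Scheme.TWO_SITE) == pytest.approx(1.1716,
                                                                     abs=5e-4)
        assert midpoint_hill_slope(Scheme.TWO_SITE_FLIP) == \
            midpoint_hill_slope(Scheme.TWO_SITE)

    def test_matches_numeric_logit_slope_at_midpoint(self, wt_params):
        _, _, k05aq = derived_affinities(Scheme.TWO_SITE, wt_params)

        def logit_frac(v):
            y = (steady_state_response(Scheme.TWO_SITE, wt_params, v) - 1.0) \
                / (wt_params.po_ratio - 1.0)
            return math.log(y / (1.0 - y))

        eps = 1e-5
        slope = (logit_frac(k05aq * math.exp(eps))
                 - logit_frac(k05aq * math.exp(-eps))) / (2 * eps)
        assert slope == pytest.approx(midpoint_hill_slope(Scheme.TWO_SITE),
                                      abs=1e-3)


class TestValidation:
    def test_positive_rates_enforced(self):
        with pytest.raises(ValueError):
            GatingParams(k_in=-1, k_out=0.1, k_on=1e3, k_off=0.01,
                         po_ratio=4, c_t=1e-6)
        with pytest.raises(ValueError):
            GatingParams(k_in=1, k_out=0.1, k_on=1e3, k_off=0.01,
                         po_ratio=0.5, c_t=1e-6)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            DrugProtocol([])
        with pytest.raises(ValueError):
            DrugProtocol([(0.0, 1e-9)])
        with pytest.raises(ValueError):
            DrugProtocol([(10.0, -1e-9)])

    def test_saturation_calibration(self):
        from cftrpot import saturated_conc

        assert saturated_conc(1.0) == pytest.approx(62e-9)
        assert saturated_conc(0.01) == pytest.approx(0.62e-9)
        assert saturated_conc(0.5, calibration=50e-9) == pytest.approx(25e-9)

    def test_protocol_json_round_trip(self):
        proto = DrugProtocol.on_off(62e-9, 600.0, 420.0)
        assert DrugProtocol.from_json_obj(proto.to_json_obj()) == proto
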