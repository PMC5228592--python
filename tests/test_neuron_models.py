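"""Unit tests of the hybrid point-neuron families."""

import numpy as np
import pytest

from bgnet import neuron_models as nm


def state(V, u=0.0):
    return nm.NeuronState(np.array([float(V)]), np.array([float(u)]))


class TestQifDerivatives:
    def test_fixed_point_at_rest(self, neuron_params):
        p = neuron_params["MSN_D2"]
        dV, du = nm.qif_derivatives(state(p.v_r), p, I=0.0)
        assert dV[0] == pytest.approx(0.0)
        assert du[0] == pytest.approx(0.0)

    def test_msn_d1_hand_value(self, neuron_params):
        # independent hand evaluation of the quadratic form for the D1
        # parameter set at V=-60 mV, u=0, I=100 pA
        p = neuron_params["MSN_D1"]
        dV, _ = nm.qif_derivatives(state(-60.0), p, I=100.0)
        assert dV[0] == pytest.approx(-29.701315789473696, rel=1e-12)

    def test_rejects_non_finite_state(self, neuron_params):
        p = neuron_params["MSN_D1"]
        with pytest.raises(ValueError):
            nm.qif_derivatives(state(np.nan), p, I=0.0)


class TestFsnRecovery:
    def test_vanishes_at_kink(self, neuron_params):
        p = neuron_params["FSN"]
        du = nm.fsn_recovery_derivative(state(p.v_b, u=0.0), p)
        assert du[0] == pytest.approx(0.0)

    def test_upper_branch_pure_decay(self, neuron_params):
        p = neuron_params["FSN"]
        du = nm.fsn_recovery_derivative(state(p.v_b + 10.0, u=7.0), p)
        assert du[0] == pytest.approx(-p.a * 7.0)

    def test_cubic_branch_hand_value(self, neuron_params):
        # 0.2 * (0.025*(-5)^3 - 5) = -1.625 pA/ms at V=-60, u=5
        p = neuron_params["FSN"]
        du = nm.fsn_recovery_derivative(state(-60.0, u=5.0), p)
        assert du[0] == pytest.approx(-1.625, rel=1e-12)

    def test_requires_fsn_variant(self, neuron_params):
        with pytest.raises(ValueError):
            nm.fsn_recovery_derivative(state(-60.0), neuron_params["MSN_D1"])


class TestAdexDerivatives:
    def test_algebraic_balance(self, neuron_params):
        p = neuron_params["GPe_TI"]
        I = 5.0
        w = p.g_L * p.Delta_T * np.exp((p.E_L - p.V_T) / p.Delta_T) + I
        dV, _ = nm.adex_derivatives(state(p.E_L, u=w), p, I=I)
        assert dV[0] == pytest.approx(0.0, abs=1e-12)

    def test_gpe_ti_hand_value(self, neuron_params):
        p = neuron_params["GPe_TI"]
        dV, _ = nm.adex_derivatives(state(-60.0), p, I=12.0)
        assert dV[0] == pytest.approx(0.4243811005737167, rel=1e-12)

    def test_stn_adaptation_gated_above_minus70(self, neuron_params):
        p = neuron_params["STN"]
        _, dw = nm.adex_derivatives(state(-60.0, u=10.0), p, I=0.0)
        assert dw[0] == pytest.approx(-10.0 / 333.0)
        # below the gate the subthreshold conductance acts
        _, dw = nm.adex_derivatives(state(-75.0, u=0.0), p, I=0.0)
        assert dw[0] == pytest.approx(0.3 * (-75.0 + 80.2) / 333.0)


class TestSpikeReset:
    def test_msn_d2_reset_and_increment(self, neuron_params):
        p = neuron_params["MSN_D2"]
        s = state(41.0, u=3.0)
        nm.apply_spike_reset(s, p)
        assert s.V[0] == pytest.approx(-60.0)
        assert s.u_or_w[0] == pytest.approx(3.0 + 91.0)

    def test_gpe_ta_spike_adaptation(self, neuron_params):
        p = neuron_params["GPe_TA"]
        s = state(p.t_f, u=0.0)
        nm.apply_spike_reset(s, p)
        assert s.V[0] == pytest.approx(p.V_r)
        assert s.u_or_w[0] == pytest.approx(105.0)

    def test_stn_depolarized_reset_when_w_negative(self, neuron_params):
        # literal printed rule: V_r + max(w-15, 20) = -70 + 20 = -50
        p = neuron_params["STN"]
        s = state(p.t_f, u=-30.0)
        nm.apply_spike_reset(s, p)
        assert s.V[0] == pytest.approx(-50.0)
        # with w >= 0 the ordinary reset applies
        s = state(p.t_f, u=5.0)
        nm.apply_spike_reset(s, p)
        assert s.V[0] == pytest.approx(p.V_r)


class TestHeterogeneity:
    def test_degenerate_spread_copies_base(self, neuron_params):
        p = neuron_params["MSN_D1"]
        C, thr = nm.sample_heterogeneity(
            p, nm.HeterogeneitySpec(C_cv=0.0, Vth_sd=0.0, seed=1), 5)
        assert np.allclose(C, p.C)
        assert np.allclose(thr, p.v_th)

    def test_moments_match_spec(self, neuron_params):
        p = neuron_params["MSN_D1"]
        C, thr = nm.sample_heterogeneity(
            p, nm.HeterogeneitySpec(seed=7), 10_000)
        assert np.mean(C) == pytest.approx(15.2, rel=0.01)
        assert np.std(C) == pytest.approx(1.52, rel=0.05)
        assert np.std(thr) == pytest.approx(1.0, rel=0.05)
        assert np.all(C > 0)

    def test_same_seed_reproduces(self, neuron_params):
        p = neuron_params["GPe_TI"]
        spec = nm.HeterogeneitySpec(seed=3)
        a = nm.sample_heterogeneity(p, spec, 100)
        b = nm.sample_heterogeneity(p, spec, 100)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_rejects_empty_sample(self, neuron_params):
        with pytest.raises(ValueError):
            nm.sample_heterogeneity(neuron_params["FSN"],
                                    nm.HeterogeneitySpec(), 0)


class TestFiCurve:
    def test_gpe_tonic_rates(self, neuron_params):
        # pallidal pacemaker anchors: TI ~18 Hz at 12 pA, TA ~8 Hz at 1 pA
        ti = nm.fi_curve(neuron_params["GPe_TI"], [12.0], duration=6000.0)
        ta = nm.fi_curve(neuron_params["GPe_TA"], [1.0], duration=6000.0)
        assert ti[0] == pytest.approx(18.0, abs=1.0)
        assert ta[0] == pytest.approx(8.0, abs=1.0)

    def test_subthreshold_current_is_silent(self, neuron_params):
        rates = nm.fi_curve(neuron_params["MSN_D1"], [-50.0, 0.0, 100.0])
        assert np.all(rates == 0.0)

    def test_ta_slope_shallower_than_ti(self, neuron_params):
        I = [0.0, 50.0, 100.0]
        ta = nm.fi_curve(neuron_params["GPe_TA"], I, duration=3000.0)
        ti = nm.fi_curve(neuron_params["GPe_TI"], I, duration=3000.0)
        assert ta[-1] - ta[0] < ti[-1] - ti[0]
        assert np.all(np.diff(ta) >= 0) and np.all(np.diff(ti) >= 0)

    def test_rejects_bad_dt(self, neuron_params):
        with pytest.raises(ValueError):
            nm.fi_curve(neuron_params["FSN"], [10.0], dt=0.0)


class TestIntegrationProperties:
    def test_pacemaker_isi_regular(self, neuron_params):
        spikes = nm.simulate_single(neuron_params["GPe_TI"], duration=6000.0,
                                    V0=-50.0)
        isi = np.diff(spikes[spikes > 2000.0])
        assert isi.size > 10
        assert np.std(isi) / np.mean(isi) < 0.01

    @pytest.mark.parametrize("pop,I", [
        ("GPe_TI", 12.0), ("GPe_TA", 1.0), ("SNr", 15.0), ("STN", 5.0),
        ("FSN", 150.0),
    ])
    def test_dt_refinement_within_two_percent(self, neuron_params, pop, I):
        # ISI-based steady rate at the tonic operating input, dt 0.1 vs a
        # 10x finer reference
        p = neuron_params[pop]
        rates = []
        for dt in (0.1, 0.01):
            s = nm.simulate_single(p, I=I, duration=8000.0, dt=dt,
                                   V0=p.threshold + 5.0, include_bias=False)
            s = s[s > 2000.0]
            rates.append(1000.0 * (s.size - 1) / (s[-1] - s[0]))
        assert rates[0] == pytest.approx(rates[1], rel=0.02)

    def test_msn_tonic_drive_subthreshold_at_any_dt(self, neuron_params):
        # the striatal operating point is fluctuation-driven; the mean
        # drive sits below rheobase, where both step sizes agree exactly
        p = neuron_params["MSN_D1"]
        for dt in (0.1, 0.01):
            s = nm.simulate_single(p, I=150.0, duration=3000.0, dt=dt)
            assert s.size == 0

    def test_stn_rebound_burst_after_hyperpolarization(self, neuron_params):
        from dataclasses import replace
        p = neuron_params["STN"]
        # 500 ms of strong hyperpolarization (below E_L so w goes negative),
        # then release; the rebound variant bursts
        def release_spikes(params):
            s = nm.NeuronState(np.array([params.E_L]), np.array([0.0]))
            dt = 0.1
            spikes = []
            for i in range(int(1000 / dt)):
                t = (i + 1) * dt
                I = params.I_e + (-450.0 if t <= 500.0 else 0.0)
                spiked = nm._step(s, params, I, dt)
                if spiked[0]:
                    spikes.append(t)
                    nm.apply_spike_reset(s, params)
            return [t for t in spikes if 500.0 < t <= 600.0]

        with_rebound = release_spikes(p)
        without = release_spikes(replace(p, stn_rebound=False))
        assert len(with_rebound) >= 2
        assert len(without) < len(with_rebound)

    def test_invariant_membrane_capped_at_cutoff(self, neuron_params):
        p = neuron_params["STN"]
        _, trace = nm.simulate_single(p, I=200.0, duration=500.0,
                                      record=True)
        assert np.all(trace[:, 1] <= p.t_f + 1e-9)
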