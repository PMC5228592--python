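"""Unit and property tests of the synapse models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgnet import synapse_models as sm


def make_state(dynamic=False, n=1):
    return sm.SynapseState(n=n, dynamic=dynamic)


class TestStaticSynapse:
    def test_decay_one_time_constant(self):
        p = sm.StaticSynapseParams("s", g0=1.0, tau_syn=12.0, E_rev=0.0,
                                   delay=1.0)
        s = make_state()
        s.g[:] = p.g0
        sm.static_decay(s, p, dt=12.0)
        assert s.g[0] == pytest.approx(p.g0 / np.e)

    def test_zero_stays_zero(self):
        p = sm.StaticSynapseParams("s", g0=0.5, tau_syn=5.0, E_rev=0.0,
                                   delay=1.0)
        s = make_state()
        sm.static_decay(s, p, dt=3.0)
        assert s.g[0] == 0.0

    def test_decay_closed_form(self):
        p = sm.StaticSynapseParams("s", g0=2.0, tau_syn=12.0, E_rev=0.0,
                                   delay=1.0)
        s = make_state()
        s.g[:] = 2.0
        sm.static_decay(s, p, dt=4.0)
        assert s.g[0] == pytest.approx(1.4330626211475785, rel=1e-12)

    def test_on_spike_superposition(self, synapse_catalog):
        p = synapse_catalog["drives"]["CTX->MSN_D1"][0]  # AMPA, 0.5 nS
        assert p.g0 == 0.5
        s = make_state()
        sm.static_on_spike(s, p)
        assert s.g[0] == pytest.approx(0.5)
        sm.static_on_spike(s, p)
        assert s.g[0] == pytest.approx(1.0)

    def test_impulse_response_peak_and_area(self):
        # event-driven exact decay: peak g0, area g0*tau within 0.1%
        p = sm.StaticSynapseParams("s", g0=1.5, tau_syn=8.0, E_rev=0.0,
                                   delay=1.0)
        s = make_state()
        sm.static_on_spike(s, p)
        dt = 0.01
        area = 0.0
        peak = s.g[0]
        for _ in range(int(200.0 / dt)):
            area += s.g[0] * dt
            sm.static_decay(s, p, dt)
        assert peak == pytest.approx(p.g0)
        assert area == pytest.approx(p.g0 * p.tau_syn, rel=1e-3)


class TestMgBlock:
    def test_no_magnesium_no_block(self):
        p = sm.NmdaBlockParams(mg_mM=0.0)
        for V in (-100.0, -50.0, 0.0, 40.0):
            assert sm.mg_block_factor(V, p) == pytest.approx(1.0)

    def test_limits(self):
        p = sm.NmdaBlockParams(mg_mM=1.0)
        assert sm.mg_block_factor(200.0, p) == pytest.approx(1.0, abs=1e-5)
        assert sm.mg_block_factor(-300.0, p) == pytest.approx(0.0, abs=1e-5)

    def test_hand_value_at_minus_80(self):
        # 1/(1 + exp(0.062*80)/3.57) evaluated by hand
        p = sm.NmdaBlockParams(mg_mM=1.0)
        assert sm.mg_block_factor(-80.0, p) == pytest.approx(
            0.024424653027730656, rel=1e-12)

    def test_monotone_on_1mV_grid(self):
        p = sm.NmdaBlockParams(mg_mM=1.0)
        V = np.arange(-100.0, 41.0, 1.0)
        B = sm.mg_block_factor(V, p)
        assert np.all(np.diff(B) > 0)
        assert np.all((B > 0) & (B <= 1))


class TestTsodyks:
    def tsodyks(self, name="MSN_D2->GPe_TI", **kw):
        base = dict(U=0.24, tau_rec=11.0, tau_fac=73.0, tau_syn=6.0,
                    g0=2.0, E_rev=-65.0, delay=7.0)
        base.update(kw)
        return sm.TsodyksParams(name, **base)

    def test_first_release_from_rest_is_U(self, synapse_catalog):
        # the indirect-pathway dynamic synapse releases U = 0.24 from rest
        p = synapse_catalog["connections"]["MSN_D2->GPe_TI"]
        assert p.U == 0.24
        s = make_state(dynamic=True)
        _, r = sm.tsodyks_on_spike(s, p)
        assert r[0] == pytest.approx(0.24)

    def test_depleted_pool_releases_nothing(self):
        p = self.tsodyks()
        s = make_state(dynamic=True)
        s.z[:] = 1.0  # x = 0
        _, r = sm.tsodyks_on_spike(s, p)
        assert r[0] == pytest.approx(0.0)

    def test_rest_state_recovered_at_long_times(self):
        p = self.tsodyks()
        s = make_state(dynamic=True)
        sm.tsodyks_on_spike(s, p)
        sm.tsodyks_evolve(s, p, dt=1e6)
        assert s.u[0] == pytest.approx(0.0, abs=1e-12)
        assert s.x[0] == pytest.approx(1.0, abs=1e-9)

    def test_single_decay_of_active_pool(self):
        p = self.tsodyks(tau_syn=5.0)
        s = make_state(dynamic=True)
        s.y[:] = 0.2
        sm.tsodyks_evolve(s, p, dt=5.0)
        assert s.y[0] == pytest.approx(0.2 / np.e)

    def test_evolution_matches_fine_step_integration(self, synapse_catalog):
        # closed-form jump over 10 ms vs explicit Euler at 1e-4 ms
        p = synapse_catalog["connections"]["MSN_D1->SNr"]
        s = make_state(dynamic=True)
        s.u[:], s.y[:], s.z[:] = 0.3, 0.25, 0.35
        u, y, z = 0.3, 0.25, 0.35
        h = 1e-4
        for _ in range(int(10.0 / h)):
            u += h * (-u / p.tau_fac)
            dy = -y / p.tau_syn
            dz = y / p.tau_syn - z / p.tau_rec
            y += h * dy
            z += h * dz
        sm.tsodyks_evolve(s, p, dt=10.0)
        assert s.u[0] == pytest.approx(u, abs=1e-6)
        assert s.y[0] == pytest.approx(y, abs=1e-6)
        assert s.z[0] == pytest.approx(z, abs=1e-6)

    def test_steady_state_matches_recurrence_oracle(self, synapse_catalog):
        # periodic 10 Hz train on the depressing pallidonigral synapse:
        # compare against an independently coded linear-map fixed point
        p = synapse_catalog["connections"]["GPe_TI->SNr"]
        assert (p.U, p.tau_rec, p.tau_fac) == (0.196, 969.0, 0.0)
        T = 100.0
        # oracle: iterate the exact interval map written from scratch
        import math
        ey, ez = math.exp(-T / p.tau_syn), math.exp(-T / p.tau_rec)
        c_fac = p.tau_rec / (p.tau_syn - p.tau_rec)
        y, z = 0.0, 0.0
        for _ in range(10_000):
            r = p.U * (1.0 - y - z)       # u = U (no facilitation)
            y += r
            zc = c_fac * y
            z = (z - zc) * ez + zc * ey
            y *= ey
        r_oracle = p.U * (1.0 - y - z)
        s = make_state(dynamic=True)
        r_imp = None
        for _ in range(10_000):
            _, r_imp = sm.tsodyks_on_spike(s, p)
            sm.tsodyks_evolve(s, p, dt=T)
        assert r_imp[0] == pytest.approx(r_oracle, rel=1e-9)

    def test_facilitating_vs_depressing_train(self, synapse_catalog):
        # 20-Hz train: striatonigral releases strictly increase over the
        # first five spikes, pallidonigral strictly decrease
        fac = synapse_catalog["connections"]["MSN_D1->SNr"]
        dep = synapse_catalog["connections"]["GPe_TI->SNr"]
        for p, increasing in ((fac, True), (dep, False)):
            s = make_state(dynamic=True)
            rel = []
            for _ in range(5):
                _, r = sm.tsodyks_on_spike(s, p)
                rel.append(r[0])
                sm.tsodyks_evolve(s, p, dt=50.0)
            diffs = np.diff(rel)
            assert np.all(diffs > 0) if increasing else np.all(diffs < 0)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.1, max_value=200.0),
                    min_size=1, max_size=200),
           st.sampled_from(["MSN_D1->SNr", "GPe_TI->SNr", "FSN->MSN_D1",
                            "MSN_D2->GPe_TI"]))
    def test_resource_conservation(self, intervals, name):
        from bgnet.catalog import load_synapse_catalog
        p = load_synapse_catalog()[0][name]
        s = make_state(dynamic=True)
        for dt in intervals:
            sm.tsodyks_on_spike(s, p)
            sm.tsodyks_evolve(s, p, dt=dt)
            total = s.x[0] + s.y[0] + s.z[0]
            assert abs(total - 1.0) < 1e-9
            assert 0.0 <= s.u[0] <= 1.0
            assert s.x[0] >= -1e-12 and s.y[0] >= -1e-12 and s.z[0] >= -1e-12


class TestConductanceBookkeeping:
    def test_unitary_conductance_from_epsc(self):
        # 90 pA at -80 mV holding with a 0 mV reversal -> ~1.1 nS
        g = 90.0 / (0.0 - (-80.0))
        assert round(g, 1) == 1.1

    def test_nmda_peak_from_ampa_size_ratio(self, synapse_catalog):
        # conductance size (g0*tau) ratio AMPA:NMDA of 2:1 fixes the MSN D2
        # NMDA peak at 0.019 nS, and the D1 value is 6x that
        ampa = synapse_catalog["drives"]["CTX->MSN_D2"][0]
        nmda = synapse_catalog["drives"]["CTX->MSN_D2"][1]
        size_ampa = ampa.g0 * ampa.tau_syn            # 0.5 * 12 = 6
        g_nmda = (size_ampa / 2.0) / nmda.tau_syn     # 3 / 160
        assert round(g_nmda, 3) == 0.019
        assert g_nmda == pytest.approx(nmda.g0, abs=5e-4)
        d1 = synapse_catalog["drives"]["CTX->MSN_D1"][1]
        assert d1.g0 == pytest.approx(6 * 0.019, abs=0.01)
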