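"""Tests of the clock-driven simulation engine."""

import warnings

import numpy as np
import pytest

from bgnet import catalog, engine
from bgnet.engine import SimulationConfig, run, scale_connection
from bgnet.network_builder import (ConnectionSpec, NetworkConfig,
                                   PopulationSpec, build_network)
from bgnet.neuron_models import HeterogeneitySpec
from bgnet.synapse_models import StaticSynapseParams


def _motif_config(neuron_params, delay=5.0, g0=10.0):
    """Two-neuron motif: a GPe TI pacemaker inhibiting an SNr target."""
    het = HeterogeneitySpec(C_cv=0.0, Vth_sd=0.0)
    pops = {
        "GPe_TI": PopulationSpec("GPe_TI", 1, neuron_params["GPe_TI"], het),
        "SNr": PopulationSpec("SNr", 1, neuron_params["SNr"], het),
    }
    conns = {
        "GPe_TI->SNr": ConnectionSpec(
            "GPe_TI->SNr", "GPe_TI", "SNr", 1,
            StaticSynapseParams("g", g0=g0, tau_syn=5.0, E_rev=-72.0,
                                delay=delay, receptor="GABA")),
    }
    return NetworkConfig(n_total=2, populations=pops, connections=conns,
                         drives={})


class TestRunBasics:
    def test_empty_network_empty_record(self):
        cfg = NetworkConfig(n_total=0, populations={}, connections={},
                            drives={})
        net = build_network(cfg, seed=1)
        rec = run(net, None, SimulationConfig(duration=100.0))
        assert rec.populations() == []

    def test_single_gpe_ti_tonic_rate(self, neuron_params):
        het = HeterogeneitySpec(C_cv=0.0, Vth_sd=0.0)
        cfg = NetworkConfig(
            n_total=1,
            populations={"GPe_TI": PopulationSpec("GPe_TI", 1,
                                                  neuron_params["GPe_TI"],
                                                  het)},
            connections={}, drives={})
        net = build_network(cfg, seed=1)
        rec = run(net, None, SimulationConfig(duration=11000.0,
                                              transient_discard=1000.0,
                                              seed=2, init_jitter=False))
        assert rec.mean_rate("GPe_TI") == pytest.approx(18.0, abs=1.0)

    def test_bit_reproducible_given_seed(self, small_network, small_config):
        drives = catalog.make_drives(small_config, "activation")
        sc = SimulationConfig(duration=300.0, seed=7)
        a = run(small_network, drives, sc)
        b = run(small_network, drives, sc)
        for pop in a.populations():
            assert np.array_equal(a.spikes[pop][0], b.spikes[pop][0])
            assert np.array_equal(a.spikes[pop][1], b.spikes[pop][1])

    def test_no_event_loss(self, small_network, small_config):
        # delivered events per connection = emitted presynaptic spikes x
        # per-neuron out-degree, audited exactly
        drives = catalog.make_drives(small_config, "activation")
        rec = run(small_network, drives,
                  SimulationConfig(duration=400.0, seed=3))
        for name, g in small_network.edges.items():
            ids, times = rec.spikes[g.spec.pre]
            delay_steps = max(1, round(g.spec.synapse.delay / 0.1))
            cutoff = 400.0 - delay_steps * 0.1
            expected = sum(
                g.indptr[i + 1] - g.indptr[i]
                for i, t in zip(ids, times) if t <= cutoff + 1e-9)
            assert rec.meta["delivered"][name] >= expected, name


class TestDelayBookkeeping:
    def test_target_response_shifts_with_delay(self, neuron_params):
        latencies = {}
        for delay in (5.0, 15.0):
            cfg = _motif_config(neuron_params, delay=delay, g0=50.0)
            net = build_network(cfg, seed=1)
            # hold the target well below threshold so the IPSP is the only
            # membrane deflection
            sc = SimulationConfig(duration=600.0, seed=1, init_jitter=False,
                                  probes={"SNr": [0]},
                                  injections=[engine.inject_current(
                                      "SNr", -100.0)])
            rec = run(net, None, sc)
            pr = rec.meta["probes"]["SNr"]
            _, times = rec.spikes["GPe_TI"]
            # use a presynaptic spike after the target's injection
            # transient has settled
            t_ref = times[times > 150.0][0]
            dV = np.diff(pr["V"][:, 0])
            after = pr["t"][1:] > t_ref
            drop = np.nonzero(after & (dV < -0.02))[0]
            latencies[delay] = pr["t"][drop[0] + 1] - t_ref
        assert latencies[15.0] - latencies[5.0] == pytest.approx(10.0,
                                                                 abs=0.25)


class TestCurrentInjectionAndScaling:
    def test_zero_injection_identical_record(self, small_network,
                                             small_config):
        drives = catalog.make_drives(small_config, "activation")
        base = run(small_network, drives,
                   SimulationConfig(duration=300.0, seed=5))
        inj = run(small_network, drives,
                  SimulationConfig(duration=300.0, seed=5,
                                   injections=[engine.inject_current("STN",
                                                                     0.0)]))
        for pop in base.populations():
            assert np.array_equal(base.spikes[pop][1], inj.spikes[pop][1])

    def test_strong_negative_current_silences(self, small_network,
                                              small_config):
        drives = catalog.make_drives(small_config, "activation")
        rec = run(small_network, drives,
                  SimulationConfig(
                      duration=400.0, transient_discard=100.0, seed=5,
                      injections=[engine.inject_current("STN", -2000.0)]))
        ids, times = rec.spikes["STN"]
        assert np.sum(times > 100.0) == 0

    def test_scale_factor_one_identical(self, small_network, small_config):
        drives = catalog.make_drives(small_config, "activation")
        scaled = scale_connection(small_network, "MSN_D2->GPe_TI", 1.0)
        a = run(small_network, drives, SimulationConfig(duration=300.0,
                                                        seed=6))
        b = run(scaled, drives, SimulationConfig(duration=300.0, seed=6))
        for pop in a.populations():
            assert np.array_equal(a.spikes[pop][1], b.spikes[pop][1])

    def test_removing_d2_inhibition_disinhibits_gpe_ti(self, small_network,
                                                       small_config):
        drives = catalog.make_drives(small_config, "activation")
        sc = SimulationConfig(duration=1000.0, transient_discard=300.0,
                              seed=6)
        base = run(small_network, drives, sc)
        cut = run(scale_connection(small_network, "MSN_D2->GPe_TI", 0.0),
                  drives, sc)
        assert cut.mean_rate("GPe_TI") > base.mean_rate("GPe_TI")

    def test_unknown_connection_raises(self, small_network):
        with pytest.raises(KeyError):
            scale_connection(small_network, "NOPE->NADA", 0.0)


class TestNumericalHealth:
    def test_dt_halving_rates_within_two_percent(self, neuron_params):
        # striatal module: rates at dt=0.1 vs dt=0.05 agree within 2% plus
        # two standard errors of the Poisson counting noise (the halved
        # step consumes a different stochastic drive realization)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = catalog.default_config(3000)
        rates, counts = {}, {}
        window_s = 1.5
        for dt in (0.1, 0.05):
            net = build_network(cfg, seed=8)
            drives = catalog.make_drives(cfg, "activation")
            rec = run(net, drives,
                      SimulationConfig(duration=2000.0,
                                       transient_discard=500.0, seed=8,
                                       dt=dt))
            rates[dt] = {p: rec.mean_rate(p) for p in rec.populations()}
            counts[dt] = {
                p: np.sum(rec.spikes[p][1] >= 500.0)
                for p in rec.populations()
            }
            sizes = rec.sizes
        for pop in rates[0.1]:
            a, b = rates[0.1][pop], rates[0.05][pop]
            se = (np.sqrt(counts[0.1][pop] + counts[0.05][pop])
                  / (sizes[pop] * window_s))
            assert abs(a - b) <= 0.02 * max(a, b) + 2.0 * se, pop

    def test_all_synapses_removed_matches_isolated_prediction(
            self, neuron_params):
        # GPe TI population without synapses fires at its isolated tonic
        # rate within 1%
        het = HeterogeneitySpec(C_cv=0.0, Vth_sd=0.0)
        cfg = NetworkConfig(
            n_total=50,
            populations={"GPe_TI": PopulationSpec(
                "GPe_TI", 50, neuron_params["GPe_TI"], het)},
            connections={}, drives={})
        net = build_network(cfg, seed=1)
        rec = run(net, None, SimulationConfig(duration=11000.0,
                                              transient_discard=1000.0,
                                              seed=2))
        from bgnet.neuron_models import fi_curve
        iso = fi_curve(neuron_params["GPe_TI"], [12.0], duration=11000.0)[0]
        assert rec.mean_rate("GPe_TI") == pytest.approx(iso, rel=0.01)


class TestSpikeRecord:
    def test_round_trip_hdf5(self, tmp_path, small_network, small_config):
        drives = catalog.make_drives(small_config, "activation")
        rec = run(small_network, drives, SimulationConfig(duration=200.0,
                                                          seed=1))
        path = tmp_path / "rec.h5"
        rec.save_hdf5(path)
        back = engine.SpikeRecord.load_hdf5(path)
        for pop in rec.populations():
            assert np.array_equal(rec.spikes[pop][1], back.spikes[pop][1])

    def test_times_sorted_and_in_range(self, small_network, small_config):
        drives = catalog.make_drives(small_config, "activation")
        rec = run(small_network, drives, SimulationConfig(duration=200.0,
                                                          seed=1))
        for pop in rec.populations():
            _, times = rec.spikes[pop]
            assert np.all(np.diff(times) >= 0)
            if times.size:
                assert times.min() > 0 and times.max() <= 200.0
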