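"""Scripted in-silico experiments at configurable scale.

Each experiment builds control and/or dopamine-depleted networks from the
parameter catalogue, drives them with the appropriate cortical regime, and
reduces the spike records to the dynamics metrics (rates, interspike CV,
Fano factor, oscillation index, coherence, phase relations) or to
action-selection outcome grids.  All functions return tidy pandas
DataFrames and accept a scale/duration so the same protocol runs at desk
scale in tests and at larger scale from the command line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import analysis, catalog, engine
from .network_builder import (ActionChannelSpec, Network, build_network,
                              carve_nonconnected_clusters)
from .stimuli import Episode, TrialSchedule, build_selection_trials
from .synapse_models import StaticSynapseParams

__all__ = [
    "ExperimentSpec",
    "simulate_condition",
    "population_metrics",
    "pair_metrics",
    "run_dynamics_validation",
    "run_inhibition_sweep",
    "run_nonconnected_cluster_contrast",
    "run_selection_grid",
    "run_restoration_sweep",
    "run_perturbation_screen",
    "run_robustness_checks",
    "RESTORATION_GROUPS",
]

PAIRS = (("STN", "GPe_TI"), ("STN", "GPe_TA"), ("GPe_TI", "GPe_TA"),
         ("GPe_TI", "GPe_TI"))

# Restoration-sweep groups: one experimental perturbation may span several
# catalogue entries (e.g. the four MSN collateral conductances).
RESTORATION_GROUPS = {
    "CTX->MSN_D1 NMDA": ["drive:CTX->MSN_D1:NMDA:g0"],
    "CTX->MSN_D2 AMPA": ["drive:CTX->MSN_D2:AMPA:g0"],
    "CTX->STN": ["drive:CTX->STN:AMPA:g0", "drive:CTX->STN:NMDA:g0"],
    "MSN collaterals": [
        "synapse:MSN_D1->MSN_D1:g0", "synapse:MSN_D1->MSN_D2:g0",
        "synapse:MSN_D2->MSN_D1:g0", "synapse:MSN_D2->MSN_D2:g0",
        "fan_in:MSN_D1->MSN_D1", "fan_in:MSN_D1->MSN_D2",
        "fan_in:MSN_D2->MSN_D1", "fan_in:MSN_D2->MSN_D2",
    ],
    "MSN_D2->GPe_TI": ["synapse:MSN_D2->GPe_TI:g0"],
    "GPe excitability": ["neuron:GPe_TA:E_L", "neuron:GPe_TI:E_L"],
    "GPe collaterals": [
        "synapse:GPe_TA->GPe_TA:g0", "synapse:GPe_TA->GPe_TI:g0",
        "synapse:GPe_TI->GPe_TA:g0", "synapse:GPe_TI->GPe_TI:g0",
    ],
    "MSN_D1->SNr": ["synapse:MSN_D1->SNr:g0"],
    "FSN->MSN_D2 fan-in": ["fan_in:FSN->MSN_D2"],
}


@dataclass
class ExperimentSpec:
    """Shared experiment settings: scale, conditions and replicates."""

    name: str = "experiment"
    n_total: int = 10000
    condition: str = "activation"
    alpha_control: float = 0.8
    alpha_lesioned: float = 0.0
    duration: float = 3000.0
    transient: float = 500.0
    seeds: tuple = (1, 2, 3, 4, 5)
    action_channels: ActionChannelSpec | None = None

    def __post_init__(self) -> None:
        if len(self.seeds) < 1:
            raise ValueError("need at least one replicate seed")


def _build_config(spec: ExperimentSpec, alpha: float, restore=(),
                  action_channels=None):
    channels = action_channels or spec.action_channels
    if alpha < spec.alpha_control:
        return catalog.lesioned_config(spec.n_total, alpha=alpha,
                                       restore=tuple(restore),
                                       action_channels=channels)
    return catalog.default_config(spec.n_total, action_channels=channels)


def simulate_condition(spec: ExperimentSpec, alpha: float, seed: int,
                       restore=(), connection_scales=None, injections=(),
                       drive_factors=None, drive_episodes=None,
                       config_hook=None, duration=None, net_out=None):
    """Build and run one network condition; returns the SpikeRecord.

    ``connection_scales`` maps connection name to a conductance factor,
    ``drive_factors`` maps drive name to a base-rate factor,
    ``drive_episodes`` maps drive name to a list of Episodes (masks may be
    callables receiving the built network), and ``config_hook`` may edit
    the NetworkConfig in place before building.
    """
    cfg = _build_config(spec, alpha, restore=restore)
    if config_hook is not None:
        config_hook(cfg)
    net = build_network(cfg, seed=seed)
    if connection_scales:
        for name, factor in connection_scales.items():
            net = engine.scale_connection(net, name, factor)
    drives = catalog.make_drives(cfg, spec.condition)
    if drive_factors:
        for name, f in drive_factors.items():
            drives[name] = replace(drives[name],
                                   base_rate=drives[name].base_rate * f)
    if drive_episodes:
        for name, eps in drive_episodes.items():
            for ep in eps:
                mask = ep.mask(net) if callable(ep.mask) else ep.mask
                drives[name] = drives[name].with_episode(replace(ep, mask=mask))
    sc = engine.SimulationConfig(
        duration=duration if duration is not None else spec.duration,
        transient_discard=spec.transient, seed=seed,
        injections=list(injections))
    rec = engine.run(net, drives, sc)
    if net_out is not None:
        net_out.append(net)
    return rec


def population_metrics(rec: engine.SpikeRecord, populations=None,
                       band=analysis.BETA_BAND) -> pd.DataFrame:
    """Rate, interspike CV, Fano factor and oscillation index per
    population."""
    rows = []
    t0, t1 = rec.transient_discard, rec.duration
    for pop in (populations or rec.populations()):
        ids, times = rec.spikes[pop]
        keep = (times >= t0) & (times < t1)
        counts = analysis.bin_spike_times(times[keep], t0, t1)
        try:
            ff = analysis.fano_factor(counts)
        except ValueError:
            ff = math.nan
        try:
            oi = analysis.oscillation_index(rec.spike_trains(pop), t0, t1,
                                            band=band)
        except ValueError:
            oi = math.nan
        rows.append({
            "population": pop,
            "rate_hz": rec.mean_rate(pop),
            "isi_cv": rec.isi_cv(pop),
            "fano_factor": ff,
            "oscillation_index": oi,
        })
    return pd.DataFrame(rows)


def pair_metrics(rec: engine.SpikeRecord, pairs=PAIRS, n_pairs: int = 20,
                 band=analysis.BETA_BAND, window: int = 256,
                 seed: int = 0) -> pd.DataFrame:
    """Population-pair phase relation (circular mean of the instantaneous
    phase difference) and unit-pair beta-band coherence summary."""
    rows = []
    t0, t1 = rec.transient_discard, rec.duration
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        ph = analysis.phase_relation(rec.spikes[a][1], rec.spikes[b][1],
                                     t0, t1, band=band)
        tra, trb = rec.spike_trains(a), rec.spike_trains(b)
        vals, above, tot = [], 0, 0
        for _ in range(n_pairs):
            i = int(rng.integers(len(tra)))
            j = int(rng.integers(len(trb)))
            if a == b and i == j:
                continue
            try:
                c = analysis.coherence(tra[i], trb[j], t0, t1, window=window)
            except ValueError:
                continue
            sel = (c.freqs >= band[0]) & (c.freqs <= band[1])
            peak = float(c.coherence[sel].max())
            vals.append(peak)
            above += int(peak > c.significance)
            tot += 1
        rows.append({
            "pair": f"{a}-{b}",
            "phase_circ_mean": ph.circ_mean,
            "beta_coherence_mean": float(np.mean(vals)) if vals else math.nan,
            "frac_pairs_significant": above / tot if tot else math.nan,
            "n_unit_pairs": tot,
        })
    return pd.DataFrame(rows)


def run_dynamics_validation(spec: ExperimentSpec) -> pd.DataFrame:
    """Control vs lesioned dynamics metrics per population and pair, per
    replicate seed."""
    frames = []
    for seed in spec.seeds:
        for label, alpha in (("control", spec.alpha_control),
                             ("lesioned", spec.alpha_lesioned)):
            rec = simulate_condition(spec, alpha, seed)
            pm = population_metrics(rec)
            pm["kind"] = "population"
            qm = pair_metrics(rec, seed=seed)
            qm["kind"] = "pair"
            df = pd.concat([pm, qm], ignore_index=True)
            df["condition"] = label
            df["seed"] = seed
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


_INHIBITION_ARMS = {
    "all": {},
    "msn_only": {"FSN->MSN_D1": 0.0, "FSN->MSN_D2": 0.0,
                 "GPe_TA->MSN_D1": 0.0, "GPe_TA->MSN_D2": 0.0},
    "fsn_only": {"MSN_D1->MSN_D1": 0.0, "MSN_D1->MSN_D2": 0.0,
                 "MSN_D2->MSN_D1": 0.0, "MSN_D2->MSN_D2": 0.0,
                 "GPe_TA->MSN_D1": 0.0, "GPe_TA->MSN_D2": 0.0},
    "fsn_static": {"MSN_D1->MSN_D1": 0.0, "MSN_D1->MSN_D2": 0.0,
                   "MSN_D2->MSN_D1": 0.0, "MSN_D2->MSN_D2": 0.0,
                   "GPe_TA->MSN_D1": 0.0, "GPe_TA->MSN_D2": 0.0},
    "ta_only": {"MSN_D1->MSN_D1": 0.0, "MSN_D1->MSN_D2": 0.0,
                "MSN_D2->MSN_D1": 0.0, "MSN_D2->MSN_D2": 0.0,
                "FSN->MSN_D1": 0.0, "FSN->MSN_D2": 0.0},
    "none": {"MSN_D1->MSN_D1": 0.0, "MSN_D1->MSN_D2": 0.0,
             "MSN_D2->MSN_D1": 0.0, "MSN_D2->MSN_D2": 0.0,
             "FSN->MSN_D1": 0.0, "FSN->MSN_D2": 0.0,
             "GPe_TA->MSN_D1": 0.0, "GPe_TA->MSN_D2": 0.0},
}


def _staticize_fsn_msn(cfg) -> None:
    """Replace the dynamic FSN->MSN synapses by amplitude-matched static
    ones (first-event conductance U*g0)."""
    for name in ("FSN->MSN_D1", "FSN->MSN_D2"):
        syn = cfg.connections[name].synapse
        cfg.connections[name].synapse = StaticSynapseParams(
            name=syn.name + ":static", g0=syn.U * syn.g0,
            tau_syn=syn.tau_syn, E_rev=syn.E_rev, delay=syn.delay,
            receptor=syn.receptor)


def run_inhibition_sweep(spec: ExperimentSpec,
                         factors=(0.8, 1.0, 1.2, 1.5),
                         arms=("all", "msn_only", "fsn_only", "fsn_static",
                               "ta_only", "none")) -> pd.DataFrame:
    """MSN firing rate versus cortical input factor for each striatal
    inhibition arm (all / collaterals only / FSN only / static-FSN only /
    GPe TA only / none)."""
    if not factors:
        return pd.DataFrame(
            columns=["arm", "factor", "population", "rate_hz", "seed"])
    rows = []
    for seed in spec.seeds:
        for arm in arms:
            scales = _INHIBITION_ARMS[arm]
            hook = _staticize_fsn_msn if arm == "fsn_static" else None
            for f in factors:
                rec = simulate_condition(
                    spec, spec.alpha_control, seed,
                    connection_scales=scales,
                    drive_factors={d: f for d in
                                   ("CTX->MSN_D1", "CTX->MSN_D2",
                                    "CTX->FSN", "CTX->STN")},
                    config_hook=hook)
                for pop in ("MSN_D1", "MSN_D2"):
                    rows.append({"arm": arm, "factor": f, "population": pop,
                                 "rate_hz": rec.mean_rate(pop), "seed": seed})
    return pd.DataFrame(rows)


def run_nonconnected_cluster_contrast(spec: ExperimentSpec,
                                      fractions=(0.1,),
                                      burst_factor: float = 2.0
                                      ) -> pd.DataFrame:
    """Firing-rate contrast between activating a nonconnected MSN cluster
    and an equally sized random MSN subset (100-ms burst)."""
    rows = []
    onset, dur = spec.transient + 500.0, 100.0
    for seed in spec.seeds:
        for frac in fractions:
            for mode in ("nonconnected", "random"):
                cfg = _build_config(spec, spec.alpha_control)
                net = build_network(cfg, seed=seed)
                n1 = net.populations["MSN_D1"].size
                n2 = net.populations["MSN_D2"].size
                if mode == "nonconnected":
                    net = carve_nonconnected_clusters(
                        net, cluster_fraction=frac, seed=seed)
                    m1 = net.labels["cluster:MSN_D1"]
                    m2 = net.labels["cluster:MSN_D2"]
                else:
                    rng = np.random.default_rng(seed + 17)
                    m1 = np.zeros(n1, bool)
                    m1[rng.choice(n1, int(round(frac * n1)), replace=False)] = True
                    m2 = np.zeros(n2, bool)
                    m2[rng.choice(n2, int(round(frac * n2)), replace=False)] = True
                drives = catalog.make_drives(cfg, spec.condition)
                drives["CTX->MSN_D1"] = drives["CTX->MSN_D1"].with_episode(
                    Episode(onset, dur, factor=burst_factor, mask=m1))
                drives["CTX->MSN_D2"] = drives["CTX->MSN_D2"].with_episode(
                    Episode(onset, dur, factor=burst_factor, mask=m2))
                sc = engine.SimulationConfig(
                    duration=onset + dur + 100.0,
                    transient_discard=spec.transient, seed=seed)
                rec = engine.run(net, drives, sc)
                for pop, mask in (("MSN_D1", m1), ("MSN_D2", m2)):
                    ids, times = rec.spikes[pop]
                    in_burst = (times >= onset) & (times < onset + dur)
                    sel = np.isin(ids, np.nonzero(mask)[0])
                    rate = (np.sum(in_burst & sel)
                            / (mask.sum() * dur / 1000.0))
                    rows.append({"mode": mode, "fraction": frac,
                                 "population": pop, "burst_rate_hz": rate,
                                 "seed": seed})
    return pd.DataFrame(rows)


_SELECTION_ARMS = {
    "direct_only": {"indirect": False},
    "direct_indirect": {"indirect": True},
    "no_collaterals": {"indirect": True,
                       "scales": {"MSN_D1->MSN_D1": 0.0, "MSN_D1->MSN_D2": 0.0,
                                  "MSN_D2->MSN_D1": 0.0, "MSN_D2->MSN_D2": 0.0}},
    "no_fsn_msn": {"indirect": True,
                   "scales": {"FSN->MSN_D1": 0.0, "FSN->MSN_D2": 0.0}},
    "stn_pulse": {"indirect": True, "stn_pulse": 3.0},
    "stn_pulse_no_ta_msn": {"indirect": True, "stn_pulse": 3.0,
                            "scales": {"GPe_TA->MSN_D1": 0.0,
                                       "GPe_TA->MSN_D2": 0.0}},
    "lesioned": {"indirect": True, "alpha": 0.0},
}


def run_selection_grid(spec: ExperimentSpec, factors=(1.0, 2.0, 3.0),
                       trials_per_cell: int = 5,
                       arms=("direct_only", "direct_indirect"),
                       pool_fraction: float = 0.2,
                       fsn_burst: bool = True) -> pd.DataFrame:
    """Action-selection outcome proportions over a burst-factor grid for
    the configured pathway/ablation arms.

    Each trial is a 100-ms co-burst on the two action channels followed by
    900 ms of rest; an action is selected when its SNr pool drops below
    half the control baseline.  The hyperdirect "stn_pulse" arms add a
    co-timed 100-ms pulse on the STN drive.
    """
    schedule = build_selection_trials(factors, trials_per_cell=1,
                                      settle=spec.transient + 500.0)
    rows = []
    for arm in arms:
        opts = _SELECTION_ARMS[arm]
        alpha = opts.get("alpha", spec.alpha_control)
        channels = ActionChannelSpec(pool_fraction=pool_fraction,
                                     include_indirect=opts.get("indirect", True))
        for rep in range(trials_per_cell):
            for seed_base in spec.seeds[:1]:
                seed = seed_base + 1000 * rep
                baseline = None
                if alpha < spec.alpha_control:
                    baseline = control_baseline(spec, seed, channels)
                outcomes = _run_selection_pass(
                    spec, alpha, seed, schedule, channels,
                    scales=opts.get("scales"),
                    stn_pulse=opts.get("stn_pulse"),
                    fsn_burst=fsn_burst, baseline=baseline)
                for cell, out in outcomes.items():
                    rows.append({"arm": arm, "cell": cell,
                                 "outcome": out.outcome,
                                 "rate1": out.rates[0], "rate2": out.rates[1],
                                 "baseline": out.baseline, "seed": seed})
    return pd.DataFrame(rows)


def control_baseline(spec: ExperimentSpec, seed: int, channels,
                     settle: float = 1500.0) -> float:
    """Mean SNr rate of the control network in a settle-only run (the
    reference for the selection threshold in depleted arms)."""
    cfg = _build_config(spec, spec.alpha_control, action_channels=channels)
    net = build_network(cfg, seed=seed)
    drives = catalog.make_drives(cfg, spec.condition)
    sc = engine.SimulationConfig(duration=settle,
                                 transient_discard=spec.transient,
                                 seed=seed, record_spikes=("SNr",))
    rec = engine.run(net, drives, sc)
    return rec.mean_rate("SNr")


def _run_selection_pass(spec, alpha, seed, schedule: TrialSchedule, channels,
                        scales=None, stn_pulse=None, fsn_burst=True,
                        baseline=None):
    """One pass over the factor grid (one trial per cell) in a single
    continuous simulation; returns cell -> SelectionOutcome.

    ``baseline`` overrides the settle-window SNr rate used by the
    threshold rule (the depleted network is classified against the
    *control* model's baseline).
    """
    cfg = _build_config(spec, alpha, action_channels=channels)
    net = build_network(cfg, seed=seed)
    if scales:
        for name, f in scales.items():
            net = engine.scale_connection(net, name, f)
    drives = catalog.make_drives(cfg, spec.condition)
    lab1 = net.labels["MSN_D1"]
    lab2 = net.labels.get("MSN_D2")
    for idx, (f1, f2), onset in schedule.trials:
        for a, f in ((0, f1), (1, f2)):
            if f > 1.0:
                drives["CTX->MSN_D1"] = drives["CTX->MSN_D1"].with_episode(
                    Episode(onset, 100.0, factor=f, mask=(lab1 == a)))
                if lab2 is not None:
                    drives["CTX->MSN_D2"] = drives["CTX->MSN_D2"].with_episode(
                        Episode(onset, 100.0, factor=f, mask=(lab2 == a)))
        if fsn_burst:
            fm = 0.5 * (f1 + f2)
            drives["CTX->FSN"] = drives["CTX->FSN"].with_episode(
                Episode(onset, 100.0, factor=fm))
        if stn_pulse:
            drives["CTX->STN"] = drives["CTX->STN"].with_episode(
                Episode(onset, 100.0, factor=stn_pulse))
    sc = engine.SimulationConfig(duration=schedule.total_duration,
                                 transient_discard=spec.transient, seed=seed,
                                 record_spikes=("SNr",))
    rec = engine.run(net, drives, sc)
    labS = net.labels["SNr"]
    ids, times = rec.spikes["SNr"]
    pools = [np.nonzero(labS == a)[0] for a in (0, 1)]
    masks = [np.isin(ids, p) for p in pools]
    # baseline: pool rates during the settle window (unless overridden
    # with the control model's baseline)
    t0, t1 = spec.transient, schedule.settle
    base = baseline if baseline is not None else float(np.mean([
        np.sum(m & (times >= t0) & (times < t1)) / (p.size * (t1 - t0) / 1e3)
        for m, p in zip(masks, pools)
    ]))
    outcomes = {}
    for idx, cell, onset in schedule.trials:
        rates = tuple(
            np.sum(m & (times >= onset) & (times < onset + 100.0))
            / (p.size * 0.1)
            for m, p in zip(masks, pools)
        )
        outcomes[cell] = analysis.classify_selection(rates, base)
    return outcomes


def run_restoration_sweep(spec: ExperimentSpec,
                          groups=None) -> pd.DataFrame:
    """Per-parameter restoration in the lesioned network: change in Fano
    factor and oscillation index per population relative to the fully
    lesioned baseline, per replicate seed."""
    groups = dict(groups or RESTORATION_GROUPS)
    rows = []
    for seed in spec.seeds:
        base = population_metrics(
            simulate_condition(spec, spec.alpha_lesioned, seed))
        base = base.set_index("population")
        for label, targets in groups.items():
            rec = simulate_condition(spec, spec.alpha_lesioned, seed,
                                     restore=tuple(targets))
            pm = population_metrics(rec).set_index("population")
            for pop in pm.index:
                rows.append({
                    "restored": label, "population": pop, "seed": seed,
                    "delta_fano": pm.loc[pop, "fano_factor"]
                                  - base.loc[pop, "fano_factor"],
                    "delta_oi": pm.loc[pop, "oscillation_index"]
                                - base.loc[pop, "oscillation_index"],
                    "delta_rate": pm.loc[pop, "rate_hz"]
                                  - base.loc[pop, "rate_hz"],
                })
    return pd.DataFrame(rows)


def run_perturbation_screen(spec: ExperimentSpec,
                            connection_arms=(("GPe_TA->MSN_D2", 0.0),
                                             ("GPe_TA->MSN_D2", 5.0),
                                             ("MSN_D2->GPe_TI", 0.0)),
                            nucleus_arms=("STN",)) -> pd.DataFrame:
    """Connection-scaling (x0 / x5) and nucleus-silencing screen on the
    lesioned network: synchrony/oscillation deltas per population."""
    rows = []
    for seed in spec.seeds:
        base = population_metrics(
            simulate_condition(spec, spec.alpha_lesioned, seed))
        base = base.set_index("population")

        def add(arm_label, rec):
            pm = population_metrics(rec).set_index("population")
            for pop in pm.index:
                rows.append({
                    "arm": arm_label, "population": pop, "seed": seed,
                    "delta_fano": pm.loc[pop, "fano_factor"]
                                  - base.loc[pop, "fano_factor"],
                    "delta_oi": pm.loc[pop, "oscillation_index"]
                                - base.loc[pop, "oscillation_index"],
                    "rate_hz": pm.loc[pop, "rate_hz"],
                })

        for name, factor in connection_arms:
            rec = simulate_condition(spec, spec.alpha_lesioned, seed,
                                     connection_scales={name: factor})
            add(f"{name} x{factor:g}", rec)
        for nucleus in nucleus_arms:
            rec = simulate_condition(
                spec, spec.alpha_lesioned, seed,
                injections=[engine.inject_current(nucleus, -2000.0)])
            add(f"{nucleus} silenced", rec)
    return pd.DataFrame(rows)


def run_robustness_checks(spec: ExperimentSpec,
                          ta_msn_tau_factors=(1.0, 0.25, 0.1),
                          msn_ta_fan_ins=(),
                          ctx_delays=()) -> pd.DataFrame:
    """Parameter-perturbation sweeps: TA->MSN synaptic decay (oscillation
    onset in the control striatum), optional MSN->TA fan-in (TI-TA phase)
    and cortical delay sweeps (STN-TI phase)."""
    rows = []
    for seed in spec.seeds:
        for f in ta_msn_tau_factors:
            def hook(cfg, f=f):
                for name in ("GPe_TA->MSN_D1", "GPe_TA->MSN_D2"):
                    syn = cfg.connections[name].synapse
                    cfg.connections[name].synapse = replace(
                        syn, tau_syn=syn.tau_syn * f)
            rec = simulate_condition(spec, spec.alpha_control, seed,
                                     config_hook=hook)
            for pop in ("MSN_D1", "MSN_D2"):
                try:
                    oi = analysis.oscillation_index(
                        rec.spike_trains(pop), rec.transient_discard,
                        rec.duration)
                except ValueError:
                    oi = math.nan
                rows.append({"sweep": "ta_msn_tau", "value": f,
                             "population": pop, "metric": "oscillation_index",
                             "result": oi, "seed": seed})
        for fan in msn_ta_fan_ins:
            def hook(cfg, fan=fan):
                src = cfg.connections["MSN_D2->GPe_TI"]
                cfg.connections["MSN_D2->GPe_TA"] = replace(
                    src, name="MSN_D2->GPe_TA", post="GPe_TA", fan_in=fan)
            rec = simulate_condition(spec, spec.alpha_lesioned, seed,
                                     config_hook=hook)
            ph = analysis.phase_relation(
                rec.spikes["GPe_TI"][1], rec.spikes["GPe_TA"][1],
                rec.transient_discard, rec.duration)
            rows.append({"sweep": "msn_ta_fan_in", "value": fan,
                         "population": "GPe_TI-GPe_TA", "metric": "phase",
                         "result": ph.circ_mean, "seed": seed})
        for delay in ctx_delays:
            def hook(cfg, delay=delay):
                for name in ("CTX->MSN_D1", "CTX->MSN_D2"):
                    cfg.drives[name].phase_offset = delay
            rec = simulate_condition(spec, spec.alpha_lesioned, seed,
                                     config_hook=hook)
            ph = analysis.phase_relation(
                rec.spikes["STN"][1], rec.spikes["GPe_TI"][1],
                rec.transient_discard, rec.duration)
            rows.append({"sweep": "ctx_striatum_delay", "value": delay,
                         "population": "STN-GPe_TI", "metric": "phase",
                         "result": ph.circ_mean, "seed": seed})
    return pd.DataFrame(rows)
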