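"""Clock-driven network simulation.

Forward-Euler integration at a fixed step (default 0.1 ms); spikes are
detected at step end, delivered after their connection delay through
per-connection ring buffers, and accumulated as exponentially decaying
conductances per (postsynaptic population, receptor channel).  Each
population's channels live in one matrix, decayed with a single
elementwise product per step, and the per-neuron update (current
summation with the NMDA magnesium block, Euler step, threshold
detection, reset) runs in a compiled kernel.  Short-term plastic
synapses keep per-edge Tsodyks state, updated lazily at event times with
the closed-form inter-spike relaxation.  All randomness is drawn from
named streams derived from the master seed, so adding probes or drives
never perturbs unrelated dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from . import neuron_models as nm
from .synapse_models import NmdaBlockParams, TsodyksParams
from .network_builder import Network, _stream_seed
from .stimuli import DriveSpec, rate_at

__all__ = [
    "SimulationConfig",
    "CurrentInjection",
    "SpikeRecord",
    "run",
    "inject_current",
    "scale_connection",
    "find_silencing_current",
]


@dataclass
class CurrentInjection:
    """Constant current (pA) added to every member of a population during
    [t0, t1)."""

    population: str
    amplitude: float
    t0: float = 0.0
    t1: float = math.inf


@dataclass
class SimulationConfig:
    duration: float                 # ms
    dt: float = 0.1                 # ms
    transient_discard: float = 0.0  # ms, excluded by rate helpers
    seed: int = 0
    record_spikes: tuple | None = None   # population names; None = all
    probes: dict = field(default_factory=dict)   # pop -> neuron id list
    injections: list = field(default_factory=list)
    mg_mM: float = 1.0
    init_jitter: bool = True        # randomize initial membrane potentials

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


class SpikeRecord:
    """Per-population spike times with bookkeeping metadata."""

    def __init__(self, spikes: dict, duration: float, dt: float,
                 transient_discard: float = 0.0, seed: int = 0,
                 sizes: dict | None = None, meta: dict | None = None):
        self.spikes = spikes            # pop -> (ids int64, times float64)
        self.duration = duration
        self.dt = dt
        self.transient_discard = transient_discard
        self.seed = seed
        self.sizes = sizes or {}
        self.meta = meta or {}

    def populations(self):
        return list(self.spikes)

    def spike_trains(self, pop: str, t0: float | None = None,
                     t1: float | None = None) -> list[np.ndarray]:
        """Per-neuron spike-time arrays (ms) within [t0, t1)."""
        ids, times = self.spikes[pop]
        t0 = self.transient_discard if t0 is None else t0
        t1 = self.duration if t1 is None else t1
        keep = (times >= t0) & (times < t1)
        ids, times = ids[keep], times[keep]
        n = self.sizes.get(pop, ids.max() + 1 if ids.size else 0)
        order = np.argsort(ids, kind="stable")
        ids, times = ids[order], times[order]
        bounds = np.searchsorted(ids, np.arange(n + 1))
        return [np.sort(times[bounds[i]:bounds[i + 1]]) for i in range(n)]

    def mean_rate(self, pop: str, t0: float | None = None,
                  t1: float | None = None) -> float:
        """Population mean firing rate in Hz over [t0, t1)."""
        ids, times = self.spikes[pop]
        t0 = self.transient_discard if t0 is None else t0
        t1 = self.duration if t1 is None else t1
        n = self.sizes[pop]
        count = int(np.sum((times >= t0) & (times < t1)))
        return 1000.0 * count / (n * (t1 - t0))

    def per_neuron_rates(self, pop: str, t0: float | None = None,
                         t1: float | None = None) -> np.ndarray:
        ids, times = self.spikes[pop]
        t0 = self.transient_discard if t0 is None else t0
        t1 = self.duration if t1 is None else t1
        keep = (times >= t0) & (times < t1)
        n = self.sizes[pop]
        return 1000.0 * np.bincount(ids[keep], minlength=n) / (t1 - t0)

    def isi_cv(self, pop: str, t0: float | None = None,
               t1: float | None = None) -> float:
        """Mean coefficient of variation of interspike intervals over
        neurons with at least three spikes."""
        cvs = []
        for tr in self.spike_trains(pop, t0, t1):
            if tr.size >= 3:
                isi = np.diff(tr)
                cvs.append(np.std(isi) / np.mean(isi))
        return float(np.mean(cvs)) if cvs else math.nan

    def to_dataframe(self):
        import pandas as pd
        frames = [
            pd.DataFrame({"population": pop, "neuron": ids, "time_ms": times})
            for pop, (ids, times) in self.spikes.items()
        ]
        return (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=["population", "neuron", "time_ms"]))

    def save_text(self, directory) -> None:
        """Two-column (neuron id, time ms) delimited text per population."""
        import pathlib
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for pop, (ids, times) in self.spikes.items():
            np.savetxt(d / f"spikes_{pop}.txt",
                       np.column_stack([ids, times]), fmt="%d %.3f")

    def save_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as fh:
            fh.attrs["duration"] = self.duration
            fh.attrs["dt"] = self.dt
            fh.attrs["seed"] = self.seed
            for pop, (ids, times) in self.spikes.items():
                grp = fh.create_group(pop)
                grp.create_dataset("ids", data=ids)
                grp.create_dataset("times", data=times)
                grp.attrs["size"] = self.sizes.get(pop, 0)

    @classmethod
    def load_hdf5(cls, path) -> "SpikeRecord":
        import h5py
        spikes, sizes = {}, {}
        with h5py.File(path, "r") as fh:
            duration = float(fh.attrs["duration"])
            dt = float(fh.attrs["dt"])
            seed = int(fh.attrs["seed"])
            for pop in fh:
                spikes[pop] = (fh[pop]["ids"][:], fh[pop]["times"][:])
                sizes[pop] = int(fh[pop].attrs["size"])
        return cls(spikes, duration, dt, seed=seed, sizes=sizes)


class _PopRuntime:
    """Per-population simulation state: neuron arrays plus the stacked
    conductance-channel matrix."""

    def __init__(self, pop, rng, jitter: bool, dt: float):
        self.name = pop.name
        self.size = pop.size
        self.params = pop.params
        self.C = np.ascontiguousarray(pop.C, dtype=np.float64)
        self.thr = np.ascontiguousarray(pop.threshold, dtype=np.float64)
        self.dt = dt
        p = pop.params
        self.qif = isinstance(p, nm.QifAdaptParams)
        rest = p.rest
        if jitter:
            lo = min(rest, p.c if self.qif else p.V_r)
            hi = max(rest, float(self.thr.mean()))
            self.V = lo + (hi - lo) * rng.random(pop.size)
        else:
            self.V = np.full(pop.size, float(rest))
        self.w = np.zeros(pop.size)
        self.I_e = float(getattr(p, "I_e", 0.0))
        self._chan = []          # (decay, E_rev, nmda) descriptors
        self.G = None
        self.out_groups: list = []
        self.injections: list = []
        self.spike_steps: list = []
        self.spike_ids: list = []
        self.spike_buf = np.empty(pop.size, dtype=np.int64)
        self.emitted = 0

    def add_channel(self, tau: float, E_rev: float, nmda: bool) -> int:
        self._chan.append((math.exp(-self.dt / tau), E_rev, nmda))
        return len(self._chan) - 1

    def finalize(self) -> None:
        n_ch = len(self._chan)
        self.G = np.zeros((max(n_ch, 1), self.size))
        if n_ch:
            self.decay_col = np.array([c[0] for c in self._chan])[:, None]
        else:
            self.decay_col = np.ones((1, 1))
        self.E_rev = np.array([c[1] for c in self._chan] or [0.0])
        self.nmda = np.array([c[2] for c in self._chan] or [False],
                             dtype=np.bool_)
        self.n_ch = n_ch

    def bias_at(self, t: float) -> float:
        I = self.I_e
        for inj in self.injections:
            if inj.t0 <= t < inj.t1:
                I += inj.amplitude
        return I

    def step(self, t: float, mg_c: float, mg_k: float) -> np.ndarray:
        p = self.params
        if self.qif:
            count = _kernels.qif_step(
                self.V, self.w, self.G, self.E_rev, self.nmda, mg_c, mg_k,
                self.C, self.thr, self.bias_at(t), p.k, p.v_r, p.a, p.b,
                self.dt, p.is_fsn_variant,
                p.v_b if p.v_b is not None else 0.0,
                p.v_peak, p.c, p.d, self.spike_buf)
        else:
            count = _kernels.adex_step(
                self.V, self.w, self.G, self.E_rev, self.nmda, mg_c, mg_k,
                self.C, self.thr, self.bias_at(t), p.g_L, p.E_L, p.Delta_T,
                p.a_sub, p.tau_w, p.b_spike, p.V_r, p.t_f, self.dt,
                p.adaptation_gate_mV is not None,
                (p.adaptation_gate_mV if p.adaptation_gate_mV is not None
                 else 0.0),
                p.stn_rebound, p.stn_reset_offset, p.stn_reset_cap,
                p.stn_reset_mode == "max", self.spike_buf)
        return self.spike_buf[:count]


class _GroupRuntime:
    """Per-connection runtime: delay ring buffer, the target channel row,
    and (for dynamic synapses) per-edge Tsodyks state."""

    def __init__(self, group, post_rt: _PopRuntime, row: int, dt: float):
        self.group = group
        self.post_rt = post_rt
        self.row = row
        syn = group.spec.synapse
        self.g0 = syn.g0
        self.dynamic = syn.is_dynamic
        self.delay_steps = max(1, int(round(syn.delay / dt)))
        self.buffer = [[] for _ in range(self.delay_steps + 1)]
        self.delivered = 0
        if self.dynamic:
            n = group.n_edges
            self.syn: TsodyksParams = syn
            self.u = np.zeros(n)
            self.y = np.zeros(n)
            self.z = np.zeros(n)
            self.tlast = np.zeros(n)

    def deliver(self, pre_spikes: np.ndarray, t: float) -> None:
        g = self.group
        edges = g.out_edges(pre_spikes)
        if edges.size == 0:
            return
        posts = g.post_ids[edges]
        target = self.post_rt.G[self.row]
        if not self.dynamic:
            _kernels.scatter_add(target, posts, self.g0)
        else:
            syn = self.syn
            _kernels.tsodyks_deliver(target, posts, edges, self.u, self.y,
                                     self.z, self.tlast, t, syn.U,
                                     syn.tau_fac, syn.tau_syn, syn.tau_rec,
                                     self.g0)
        self.delivered += edges.size


class _DriveRuntime:
    """Poisson event generation for one drive.  Outside episodes and away
    from square-wave edges the per-step counts are drawn in blocks (same
    stream, fewer generator calls)."""

    _BLOCK = 64

    def __init__(self, spec: DriveSpec, pop: _PopRuntime, rng, dt: float):
        self.spec = spec
        self.pop = pop
        self.rng = rng
        self.dt = dt
        self.rows = [pop.add_channel(c.tau_syn, c.E_rev,
                                     c.receptor == "NMDA")
                     for c in spec.components]
        self.g0s = [c.g0 for c in spec.components]
        self._buf = None
        self._bi = 0

    def _steps_to_boundary(self, t: float) -> float:
        """Steps until the square-wave rate or an episode boundary."""
        horizon = math.inf
        if self.spec.mod_freq > 0 and self.spec.mod_amplitude > 0:
            half = 1000.0 / self.spec.mod_freq / 2.0
            te = t - self.spec.phase_offset
            edge = (math.floor(te / half + 1e-9) + 1) * half \
                + self.spec.phase_offset
            horizon = min(horizon, edge - t)
        for ep in self.spec.episodes:
            if ep.onset > t:
                horizon = min(horizon, ep.onset - t)
        if not math.isfinite(horizon):
            return math.inf
        return max(1, int(round(horizon / self.dt)))

    def step(self, t: float) -> None:
        episodes = [ep for ep in self.spec.episodes if ep.active(t)]
        lam = rate_at(self.spec, t) / 1000.0 * self.dt
        if episodes:
            self._buf = None
            lam_arr = np.full(self.pop.size, lam)
            for ep in episodes:
                mod = lam * ep.factor + ep.rate_add / 1000.0 * self.dt
                if ep.mask is None:
                    lam_arr[:] = mod
                else:
                    lam_arr[ep.mask] = mod
            counts = self.rng.poisson(lam_arr)
        else:
            if self._buf is None or self._bi >= self._buf.shape[0]:
                b = min(self._BLOCK, self._steps_to_boundary(t))
                b = int(b) if math.isfinite(b) else self._BLOCK
                self._buf = self.rng.poisson(lam, (b, self.pop.size))
                self._bi = 0
            counts = self._buf[self._bi]
            self._bi += 1
        if counts.any():
            for row, g0 in zip(self.rows, self.g0s):
                self.pop.G[row] += g0 * counts


class EngineError(RuntimeError):
    pass


def run(network: Network, drives: dict | list | None,
        config: SimulationConfig) -> SpikeRecord:
    """Simulate the network and return the spike record.

    Total synaptic current into neuron i is the sum over channels of
    g*(E_rev - V_i), with NMDA channels additionally weighted by the
    magnesium-block factor B(V_i), plus the tonic bias I_e and any
    configured current injections.  Deterministic given config.seed.
    """
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    mg = NmdaBlockParams(mg_mM=config.mg_mM)
    mg_c = mg.mg_mM / mg.k_conc
    mg_k = mg.k_volt
    seed = config.seed

    pops: dict[str, _PopRuntime] = {}
    for name, pop in network.populations.items():
        rng = np.random.default_rng(_stream_seed(seed, f"init:{name}"))
        pops[name] = _PopRuntime(pop, rng, config.init_jitter, dt)

    groups: list[_GroupRuntime] = []
    for name, g in network.edges.items():
        syn = g.spec.synapse
        if syn.delay < dt:
            raise ValueError(f"{name}: delay {syn.delay} below dt {dt}")
        post = pops[g.spec.post]
        row = post.add_channel(syn.tau_syn, syn.E_rev,
                               syn.receptor == "NMDA")
        grt = _GroupRuntime(g, post, row, dt)
        groups.append(grt)
        pops[g.spec.pre].out_groups.append(grt)

    drive_rts: list[_DriveRuntime] = []
    if drives:
        items = drives.values() if isinstance(drives, dict) else drives
        for spec in items:
            rng = np.random.default_rng(
                _stream_seed(seed, f"drive:{spec.name}"))
            drive_rts.append(_DriveRuntime(spec, pops[spec.target], rng, dt))

    for prt in pops.values():
        prt.finalize()
    for inj in config.injections:
        pops[inj.population].injections.append(inj)

    record_pops = (set(config.record_spikes)
                   if config.record_spikes is not None else set(pops))
    probe_data = {
        pop: {"ids": np.asarray(ids, dtype=int), "t": [], "V": [], "w": []}
        for pop, ids in config.probes.items()
    }

    pop_list = list(pops.values())
    for step in range(n_steps):
        t = step * dt
        t_end = (step + 1) * dt
        # conductance decay (one elementwise product per population)
        for prt in pop_list:
            if prt.n_ch:
                prt.G *= prt.decay_col
        # external drive events
        for drt in drive_rts:
            drt.step(t)
        # delayed spike delivery (batched per connection)
        for grt in groups:
            slot = step % len(grt.buffer)
            pending = grt.buffer[slot]
            if pending:
                grt.buffer[slot] = []
                pres = (pending[0] if len(pending) == 1
                        else np.concatenate(pending))
                grt.deliver(pres, t)
        # neuron update
        for prt in pop_list:
            ids = prt.step(t, mg_c, mg_k)
            if ids.size:
                prt.emitted += ids.size
                ids = ids.copy()
                if prt.name in record_pops:
                    prt.spike_steps.append(t_end)
                    prt.spike_ids.append(ids)
                for grt in prt.out_groups:
                    L = len(grt.buffer)
                    grt.buffer[(step + grt.delay_steps) % L].append(ids)
        # probes
        for pop, pd in probe_data.items():
            prt = pops[pop]
            pd["t"].append(t_end)
            pd["V"].append(prt.V[pd["ids"]].copy())
            pd["w"].append(prt.w[pd["ids"]].copy())
        # health check
        if step % 2000 == 1999:
            for prt in pop_list:
                if not np.all(np.isfinite(prt.V)):
                    bad = int(np.nonzero(~np.isfinite(prt.V))[0][0])
                    raise EngineError(
                        f"non-finite membrane potential in {prt.name} "
                        f"neuron {bad} at t={t_end:.1f} ms")

    spikes = {}
    for name, prt in pops.items():
        if name not in record_pops:
            continue
        if prt.spike_ids:
            times = np.concatenate([
                np.full(ids.size, ts)
                for ts, ids in zip(prt.spike_steps, prt.spike_ids)
            ])
            ids = np.concatenate(prt.spike_ids)
        else:
            times = np.empty(0)
            ids = np.empty(0, dtype=np.int64)
        spikes[name] = (ids, times)

    meta = {
        "emitted": {name: prt.emitted for name, prt in pops.items()},
        "delivered": {grt.group.name: grt.delivered for grt in groups},
        "n_edges": {grt.group.name: grt.group.n_edges for grt in groups},
    }
    if probe_data:
        meta["probes"] = {
            pop: {
                "ids": pd["ids"],
                "t": np.asarray(pd["t"]),
                "V": np.asarray(pd["V"]),
                "w": np.asarray(pd["w"]),
            }
            for pop, pd in probe_data.items()
        }
    return SpikeRecord(spikes, config.duration, dt,
                       transient_discard=config.transient_discard,
                       seed=seed,
                       sizes={n: p.size for n, p in pops.items()},
                       meta=meta)


def inject_current(population: str, amplitude: float, t0: float = 0.0,
                   t1: float = math.inf) -> CurrentInjection:
    """Config modifier: constant current into every member of a population
    during [t0, t1)."""
    return CurrentInjection(population=population, amplitude=amplitude,
                            t0=t0, t1=t1)


def scale_connection(network: Network, name: str, factor: float) -> Network:
    """Copy of the network with one connection's peak conductance scaled
    (0 removes the influence, leaving the edges in place)."""
    if name not in network.edges:
        raise KeyError(f"unknown connection {name!r}")
    net = network.copy()
    g = net.edges[name]
    syn = replace(g.spec.synapse, g0=g.spec.synapse.g0 * factor)
    g.spec = replace(g.spec, synapse=syn)
    return net


def find_silencing_current(network: Network, drives, config: SimulationConfig,
                           population: str, max_amplitude: float = 2000.0,
                           tol: float = 25.0) -> float:
    """Smallest-magnitude hyperpolarizing current that silences a
    population in a probe run (bisection on the amplitude)."""
    def spikes_at(amp: float) -> int:
        cfg = replace(config,
                      injections=list(config.injections)
                      + [inject_current(population, -amp)])
        rec = run(network, drives, cfg)
        ids, times = rec.spikes[population]
        return int(np.sum(times >= config.transient_discard))

    lo, hi = 0.0, max_amplitude
    if spikes_at(hi) > 0:
        raise EngineError(f"{population}: not silenced even at -{hi} pA")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid) == 0:
            hi = mid
        else:
            lo = mid
    return -hi
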