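"""Population sizing and fan-in connectivity of the basal ganglia circuit.

Populations are sized by fixed fractions (anchored at the 80,000-neuron
reference network); connectivity is specified as an exact in-degree per
postsynaptic neuron.  Striatal collateral and feed-forward connections are
spatially restricted: neurons live on a 1-D index ring and presynaptic
partners are drawn from a window of the stated axonal/dendritic-field size.
Scaled-down networks keep absolute fan-ins (firing rates depend on
in-degree, not connection probability).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from .neuron_models import HeterogeneitySpec, sample_heterogeneity
from .synapse_models import StaticSynapseParams, TsodyksParams

__all__ = [
    "PopulationSpec",
    "ConnectionSpec",
    "ActionChannelSpec",
    "NetworkConfig",
    "Network",
    "population_sizes",
    "derived_fan_in",
    "sample_in_edges",
    "build_network",
    "carve_nonconnected_clusters",
    "embed_action_channels",
]

POPULATION_NAMES = ("MSN_D1", "MSN_D2", "FSN", "STN", "GPe_TA", "GPe_TI", "SNr")

# Reference-scale sizes; fractions of the total are fixed.
REFERENCE_SIZES = {
    "MSN_D1": 37971, "MSN_D2": 37971, "FSN": 1599, "STN": 388,
    "GPe_TA": 329, "GPe_TI": 988, "SNr": 754,
}
REFERENCE_TOTAL = 80000
_REFERENCE_MSN_TOTAL = REFERENCE_SIZES["MSN_D1"] + REFERENCE_SIZES["MSN_D2"]


@dataclass
class PopulationSpec:
    name: str
    size: int
    neuron_params: object          # QifAdaptParams | AdexParams
    heterogeneity: HeterogeneitySpec = field(default_factory=HeterogeneitySpec)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"population {self.name}: size must be >= 1")


@dataclass
class ConnectionSpec:
    """Fan-in connection: every postsynaptic neuron receives exactly
    ``fan_in`` distinct presynaptic partners.

    ``spatial_window`` is the axonal/dendritic-field size in MSN-count
    equivalents at the reference scale (None = no restriction);
    ``pre_subpopulation`` restricts the presynaptic pool to a leading
    fraction (e.g. the striatum-projecting tenth of GPe TI).
    """

    name: str
    pre: str
    post: str
    fan_in: int
    synapse: StaticSynapseParams | TsodyksParams
    spatial_window: int | None = None
    pre_subpopulation: float | None = None

    def __post_init__(self) -> None:
        if self.fan_in < 0:
            raise ValueError(f"{self.name}: fan_in must be non-negative")


@dataclass
class ActionChannelSpec:
    """Embedding of competing action channels (Go/NoGo pools).

    Each action i claims a ``pool_fraction`` of one half of MSN D1 (the Go
    pool) and, when ``include_indirect`` is set, of MSN D2 (the NoGo pool).
    SNr is partitioned into one pool per action; a ``ti_pool_fraction`` of
    GPe TI is claimed per action.  Mapping: Go_i inhibits SNr pool i;
    NoGo_i inhibits TI pool i, which in turn inhibits the other action's
    SNr pool (disinhibition of the competing action's output).

    ``channel_share`` is the fraction of a mapped post neuron's afferents
    drawn from its pool (learned corticostriatal convergence concentrates
    a pool's output onto its mapping); the remainder comes from unassigned
    neurons, and the share is capped by pool availability.
    """

    n_actions: int = 2
    pool_fraction: float = 0.2
    include_indirect: bool = True
    ti_pool_fraction: float = 0.5
    channel_share: float = 0.75

    def __post_init__(self) -> None:
        if self.n_actions < 1:
            raise ValueError("need at least one action")
        if not (0 < self.pool_fraction <= 1.0):
            raise ValueError("pool_fraction must lie in (0, 1]")
        if not (0.0 <= self.channel_share <= 1.0):
            raise ValueError("channel_share must lie in [0, 1]")


@dataclass
class DriveConfig:
    """External Poisson drive onto one population: per-neuron base rates for
    the two cortical regimes, square-wave modulation amplitude, and the
    receptor components each event activates."""

    name: str
    target: str
    rate_slow_wave: float
    rate_activation: float
    amp_slow_wave: float
    amp_activation: float
    components: list  # list[StaticSynapseParams]
    phase_offset: float = 0.0   # ms lag of the rate modulation


@dataclass
class NetworkConfig:
    """Declarative network description, consumed by build_network()."""

    n_total: int
    populations: dict
    connections: dict
    drives: dict
    alpha: float = 0.8
    action_channels: ActionChannelSpec | None = None

    def copy(self) -> "NetworkConfig":
        return copy.deepcopy(self)

    def validate(self) -> None:
        names = [p.name for p in self.populations.values()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for c in self.connections.values():
            if c.pre not in self.populations or c.post not in self.populations:
                raise ValueError(f"connection {c.name}: unknown population")


def population_sizes(n_total: int) -> dict:
    """Population sizes at a given network size, by the fixed nucleus
    fractions.  Exact at the reference scale; rounding keeps the total
    within a few neurons otherwise."""
    if n_total < 100:
        raise ValueError("network size must be at least 100")
    return {
        name: int(round(size * n_total / REFERENCE_TOTAL))
        for name, size in REFERENCE_SIZES.items()
    }


def derived_fan_in(neighborhood: int, probability: float) -> int:
    """In-degree from a neighborhood size and a pairwise connection
    probability: round(neighborhood * probability)."""
    if not (0.0 <= probability <= 1.0):
        raise ValueError("probability must lie in [0, 1]")
    return int(round(neighborhood * probability))


def _window_pre_count(spec: ConnectionSpec, pre_size: int, msn_total: int) -> int:
    """Convert an MSN-equivalent field size into an eligible presynaptic
    count on the index ring (capped at the population size)."""
    if spec.spatial_window is None:
        return pre_size
    w = int(round(spec.spatial_window * pre_size / msn_total))
    return min(max(w, 1), pre_size)


def sample_in_edges(spec: ConnectionSpec, pre_size: int, post_size: int,
                    rng, msn_total: int | None = None,
                    forbidden_pre=None,
                    strict: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Draw the presynaptic partners of every postsynaptic neuron.

    Returns (pre_ids, post_ids) with exactly ``fan_in`` distinct partners
    per post neuron, drawn uniformly without replacement from the post
    neuron's ring window (or the whole presynaptic pool), never including
    the neuron itself for recurrent connections.  ``forbidden_pre`` maps a
    post id to a boolean mask of excluded presynaptic neurons.
    """
    fan_in = spec.fan_in
    if fan_in == 0 or post_size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    if msn_total is None:
        msn_total = _REFERENCE_MSN_TOTAL

    pool_size = pre_size
    if spec.pre_subpopulation is not None:
        pool_size = max(1, int(round(spec.pre_subpopulation * pre_size)))

    w = min(_window_pre_count(spec, pool_size, msn_total), pool_size)
    recurrent = spec.pre == spec.post
    avail = w - (1 if recurrent else 0)
    eff_fan_in = fan_in
    if avail < fan_in:
        if strict:
            raise ValueError(
                f"{spec.name}: fan_in {fan_in} exceeds available "
                f"presynaptic pool {avail}")
        warnings.warn(
            f"{spec.name}: fan_in {fan_in} capped at available pool {avail} "
            "(scaled-down network)", stacklevel=2)
        eff_fan_in = avail
        if eff_fan_in <= 0:
            raise ValueError(f"{spec.name}: empty presynaptic window")

    pre_ids = np.empty(post_size * eff_fan_in, dtype=np.int64)
    post_ids = np.repeat(np.arange(post_size, dtype=np.int64), eff_fan_in)
    windowed = w < pool_size
    offsets = (np.arange(w) - w // 2) if windowed else None
    for j in range(post_size):
        if windowed:
            center = int(j * pool_size / post_size)
            candidates = (center + offsets) % pool_size
        else:
            candidates = None
        keys = rng.random(w if windowed else pool_size)
        if recurrent:
            if windowed:
                self_hit = np.nonzero(candidates == j)[0]
                keys[self_hit] = np.inf
            elif j < pool_size:
                keys[j] = np.inf
        if forbidden_pre is not None:
            mask = forbidden_pre(j)
            if mask is not None:
                if windowed:
                    keys[mask[candidates]] = np.inf
                else:
                    keys[mask] = np.inf
        k = eff_fan_in
        picked = np.argpartition(keys, k - 1)[:k]
        if not np.all(np.isfinite(keys[picked])):
            raise ValueError(
                f"{spec.name}: cannot draw {k} partners for post {j} "
                "after exclusions")
        chosen = candidates[picked] if windowed else picked
        pre_ids[j * k:(j + 1) * k] = chosen
    return pre_ids, post_ids


class EdgeGroup:
    """Compiled edge list of one ConnectionSpec, CSR-indexed by presynaptic
    neuron for fast fan-out lookup during simulation."""

    def __init__(self, spec: ConnectionSpec, pre_ids: np.ndarray,
                 post_ids: np.ndarray, pre_size: int):
        self.spec = spec
        self.name = spec.name
        order = np.argsort(pre_ids, kind="stable")
        self.pre_ids = np.ascontiguousarray(pre_ids[order])
        self.post_ids = np.ascontiguousarray(post_ids[order])
        counts = np.bincount(self.pre_ids, minlength=pre_size)
        self.indptr = np.concatenate(([0], np.cumsum(counts)))
        self.pre_size = pre_size

    @property
    def n_edges(self) -> int:
        return self.pre_ids.size

    def out_edges(self, pre_neurons: np.ndarray) -> np.ndarray:
        """Edge indices originating from the given presynaptic neurons."""
        if len(pre_neurons) == 1:
            return np.arange(self.indptr[pre_neurons[0]],
                             self.indptr[pre_neurons[0] + 1])
        starts = self.indptr[pre_neurons]
        lens = self.indptr[pre_neurons + 1] - starts
        total = int(lens.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64)
        nz = lens > 0
        starts, lens = starts[nz], lens[nz]
        # vectorized concatenation of the [start_i, start_i + len_i) ranges
        steps = np.ones(total, dtype=np.int64)
        steps[0] = starts[0]
        pos = np.cumsum(lens)[:-1]
        steps[pos] = starts[1:] - (starts[:-1] + lens[:-1] - 1)
        return np.cumsum(steps)

    def rebuild(self, pre_ids: np.ndarray, post_ids: np.ndarray) -> None:
        order = np.argsort(pre_ids, kind="stable")
        self.pre_ids = np.ascontiguousarray(pre_ids[order])
        self.post_ids = np.ascontiguousarray(post_ids[order])
        counts = np.bincount(self.pre_ids, minlength=self.pre_size)
        self.indptr = np.concatenate(([0], np.cumsum(counts)))


class Population:
    """Compiled population: shared parameters plus per-neuron heterogeneous
    capacitance and spike threshold."""

    def __init__(self, spec: PopulationSpec):
        self.name = spec.name
        self.size = spec.size
        self.params = spec.neuron_params
        self.C, self.threshold = sample_heterogeneity(
            spec.neuron_params, spec.heterogeneity, spec.size)


class Network:
    """Compiled network: populations, edge groups and channel labels."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.populations: dict[str, Population] = {}
        self.edges: dict[str, EdgeGroup] = {}
        self.labels: dict[str, np.ndarray] = {}
        self.action_spec: ActionChannelSpec | None = None

    def msn_total(self) -> int:
        tot = sum(p.size for n, p in self.populations.items()
                  if n.startswith("MSN"))
        return tot or max(1, sum(p.size for p in self.populations.values()))

    def in_degrees(self, name: str) -> np.ndarray:
        g = self.edges[name]
        post_size = self.populations[g.spec.post].size
        return np.bincount(g.post_ids, minlength=post_size)

    def copy(self) -> "Network":
        return copy.deepcopy(self)

    def save_hdf5(self, path) -> None:
        """Dump the compiled network (heterogeneous parameters, edge lists,
        labels) to a hierarchical binary container."""
        import h5py
        with h5py.File(path, "w") as fh:
            fh.attrs["seed"] = self.seed
            gp = fh.create_group("populations")
            for name, pop in self.populations.items():
                g = gp.create_group(name)
                g.attrs["size"] = pop.size
                g.create_dataset("C", data=pop.C)
                g.create_dataset("threshold", data=pop.threshold)
            ge = fh.create_group("edges")
            for name, grp in self.edges.items():
                g = ge.create_group(name)
                g.create_dataset("pre_ids", data=grp.pre_ids)
                g.create_dataset("post_ids", data=grp.post_ids)
            gl = fh.create_group("labels")
            for name, lab in self.labels.items():
                gl.create_dataset(name, data=lab)

    @classmethod
    def load_hdf5(cls, config: "NetworkConfig", path) -> "Network":
        """Reattach a dumped network to its configuration (which supplies
        the neuron and synapse parameter objects)."""
        import h5py
        net = cls(config)
        with h5py.File(path, "r") as fh:
            net.seed = int(fh.attrs["seed"])
            for name, pspec in config.populations.items():
                g = fh["populations"][name]
                pop = Population.__new__(Population)
                pop.name = name
                pop.size = int(g.attrs["size"])
                pop.params = pspec.neuron_params
                pop.C = g["C"][:]
                pop.threshold = g["threshold"][:]
                net.populations[name] = pop
            for name, cspec in config.connections.items():
                g = fh["edges"][name]
                net.edges[name] = EdgeGroup(
                    cspec, g["pre_ids"][:], g["post_ids"][:],
                    net.populations[cspec.pre].size)
            for name in fh["labels"]:
                net.labels[name] = fh["labels"][name][:]
        return net


def build_network(config: NetworkConfig, seed: int = 0) -> Network:
    """Compile a NetworkConfig into populations and edge lists.

    Reproducible given the seed; per-connection RNG streams are derived
    from it by name, so adding or removing one connection never perturbs
    the others.
    """
    config.validate()
    net = Network(config, seed)
    for name, pspec in config.populations.items():
        pspec = copy.copy(pspec)
        pspec.heterogeneity = HeterogeneitySpec(
            C_cv=pspec.heterogeneity.C_cv, Vth_sd=pspec.heterogeneity.Vth_sd,
            seed=_stream_seed(seed, f"het:{name}"))
        net.populations[name] = Population(pspec)
    msn_total = net.msn_total()
    for name, cspec in config.connections.items():
        rng = np.random.default_rng(_stream_seed(seed, f"edges:{name}"))
        pre_size = net.populations[cspec.pre].size
        post_size = net.populations[cspec.post].size
        pre_ids, post_ids = sample_in_edges(cspec, pre_size, post_size, rng,
                                            msn_total=msn_total, strict=False)
        net.edges[name] = EdgeGroup(cspec, pre_ids, post_ids, pre_size)
    if config.action_channels is not None:
        embed_action_channels(net, config.action_channels,
                              _stream_seed(seed, "channels"))
    return net


def _stream_seed(master: int, name: str) -> int:
    """Stable named sub-seed below 2^31."""
    h = np.uint64(1469598103934665603)
    for b in f"{master}:{name}".encode():
        h = np.uint64((int(h) ^ b) * 1099511628211 % (1 << 64))
    return int(h % np.uint64(2**31 - 1))


def carve_nonconnected_clusters(net: Network, populations=("MSN_D1", "MSN_D2"),
                                cluster_fraction: float = 0.1,
                                seed: int = 0) -> Network:
    """Remove collateral edges between designated cluster members (the
    low-index fraction of each MSN population) and re-draw them from
    outside the cluster, preserving every in-degree.

    Returns a modified copy; cluster membership is recorded in
    ``net.labels['cluster:<pop>']``.
    """
    if not (0 < cluster_fraction <= 0.5):
        raise ValueError("cluster_fraction must lie in (0, 0.5]")
    net = net.copy()
    members = {}
    for pop in populations:
        n = net.populations[pop].size
        mask = np.zeros(n, dtype=bool)
        mask[: int(round(cluster_fraction * n))] = True
        members[pop] = mask
        net.labels[f"cluster:{pop}"] = mask
    for name, g in net.edges.items():
        spec = g.spec
        if spec.pre not in members or spec.post not in members:
            continue
        pre_mask, post_mask = members[spec.pre], members[spec.post]
        bad = pre_mask[g.pre_ids] & post_mask[g.post_ids]
        if not bad.any():
            continue
        rng = np.random.default_rng(_stream_seed(seed, f"carve:{name}"))
        pre_ids = g.pre_ids.copy()
        post_ids = g.post_ids
        by_post = np.argsort(post_ids, kind="stable")
        post_size = net.populations[spec.post].size
        pptr = np.concatenate(
            ([0], np.cumsum(np.bincount(post_ids, minlength=post_size))))
        outside = np.nonzero(~pre_mask)[0]
        for j in np.unique(post_ids[bad]):
            edges_j = by_post[pptr[j]:pptr[j + 1]]
            keep = pre_ids[edges_j[~bad[edges_j]]]
            n_new = int(bad[edges_j].sum())
            allowed = np.setdiff1d(outside, keep, assume_unique=False)
            if spec.pre == spec.post:
                allowed = allowed[allowed != j]
            if allowed.size < n_new:
                raise ValueError(
                    f"{name}: cannot re-balance {n_new} edges for post {j}")
            pre_ids[edges_j[bad[edges_j]]] = rng.choice(
                allowed, size=n_new, replace=False)
        g.rebuild(pre_ids, post_ids)
    return net


def _pool_slices(size: int, n_actions: int, fraction: float):
    """Disjoint index pools: action i claims the leading ``fraction`` of the
    i-th equal segment."""
    seg = size // n_actions
    pools = []
    for i in range(n_actions):
        start = i * seg
        pools.append(np.arange(start, start + max(1, int(round(fraction * seg)))))
    return pools


def embed_action_channels(net: Network, spec: ActionChannelSpec,
                          seed: int = 0) -> Network:
    """Label action pools and rewire the pathway-specific projections.

    Direct: the SNr pool of action i draws its MSN D1 afferents from the
    Go_i pool plus unassigned D1 neurons.  Indirect (optional): the GPe TI
    pool of action i draws its MSN D2 afferents from NoGo_i plus
    unassigned D2, and the SNr pool of action j draws its TI afferents
    avoiding TI pools of actions other than i = (j+1) mod n.  In-degrees
    are preserved exactly.  Mutates and returns ``net``.
    """
    n_act = spec.n_actions
    pops = net.populations
    go = _pool_slices(pops["MSN_D1"].size, n_act, spec.pool_fraction)
    snr = _pool_slices(pops["SNr"].size, n_act, 1.0)

    def label_array(size, pools):
        lab = np.full(size, -1, dtype=np.int64)
        for i, idx in enumerate(pools):
            if lab[idx].max(initial=-1) >= 0:
                raise ValueError("overlapping action pools")
            lab[idx] = i
        return lab

    net.labels["MSN_D1"] = label_array(pops["MSN_D1"].size, go)
    net.labels["SNr"] = label_array(pops["SNr"].size, snr)

    rng = np.random.default_rng(_stream_seed(seed, "rewire"))
    _rewire_by_post_pool(net, "MSN_D1->SNr", net.labels["SNr"],
                         net.labels["MSN_D1"], same_action=True, rng=rng,
                         share=spec.channel_share)

    if spec.include_indirect:
        # The NoGo pool of action i occupies the ring segment of action
        # (i+1) mod n in MSN D2: in striatal space the indirect pool of one
        # action overlies the competing action's direct pool, so its
        # windowed collateral field suppresses the competitor rather than
        # its own channel.
        seg_pools = _pool_slices(pops["MSN_D2"].size, n_act,
                                 spec.pool_fraction)
        nogo = [seg_pools[(i + 1) % n_act] for i in range(n_act)]
        ti = _pool_slices(pops["GPe_TI"].size, n_act, spec.ti_pool_fraction)
        net.labels["MSN_D2"] = label_array(pops["MSN_D2"].size, nogo)
        net.labels["GPe_TI"] = label_array(pops["GPe_TI"].size, ti)
        _rewire_by_post_pool(net, "MSN_D2->GPe_TI", net.labels["GPe_TI"],
                             net.labels["MSN_D2"], same_action=True, rng=rng,
                             share=spec.channel_share)
        # TI pool of action i projects to the next action's SNr pool
        snr_to_ti = {j: (j - 1) % n_act for j in range(n_act)}
        _rewire_by_post_pool(net, "GPe_TI->SNr", net.labels["SNr"],
                             net.labels["GPe_TI"], same_action=False,
                             action_map=snr_to_ti, rng=rng,
                             share=spec.channel_share)
    net.action_spec = spec
    return net


def _rewire_by_post_pool(net: Network, conn: str, post_labels, pre_labels,
                         same_action: bool, rng, action_map=None,
                         share: float = 0.75) -> None:
    """Redraw the presynaptic partners of labelled post neurons: a
    ``share`` fraction of the in-degree from the mapped action's pre pool
    (capped by its size), the rest from unassigned pre neurons.  In-degree
    is preserved whenever the combined pools allow it."""
    g = net.edges[conn]
    pre_ids = g.pre_ids.copy()
    post_ids = g.post_ids
    post_size = net.populations[g.spec.post].size
    by_post = np.argsort(post_ids, kind="stable")
    pptr = np.concatenate(
        ([0], np.cumsum(np.bincount(post_ids, minlength=post_size))))
    drop = np.zeros(pre_ids.size, dtype=bool)
    capped = 0
    unassigned = np.nonzero(pre_labels < 0)[0]
    pools = {a: np.nonzero(pre_labels == a)[0]
             for a in np.unique(pre_labels) if a >= 0}
    for j in range(post_size):
        a = post_labels[j]
        if a < 0:
            continue
        want = a if same_action else action_map[a]
        pool = pools.get(want, np.empty(0, dtype=np.int64))
        rest = unassigned
        if g.spec.pre == g.spec.post:
            pool = pool[pool != j]
            rest = rest[rest != j]
        edges_j = by_post[pptr[j]:pptr[j + 1]]
        k = edges_j.size
        k_pool = min(int(round(share * k)), pool.size)
        k_rest = min(k - k_pool, rest.size)
        # backfill from the pool if unassigned neurons run out
        k_pool = min(k - k_rest, pool.size)
        chosen = np.concatenate([
            rng.choice(pool, size=k_pool, replace=False),
            rng.choice(rest, size=k_rest, replace=False),
        ])
        if chosen.size < k:
            capped += 1
            drop[edges_j[chosen.size:]] = True
        pre_ids[edges_j[:chosen.size]] = chosen
    if capped:
        warnings.warn(
            f"{conn}: in-degree capped at the eligible pool size for "
            f"{capped} postsynaptic neurons", stacklevel=2)
    g.rebuild(pre_ids[~drop], post_ids[~drop])
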