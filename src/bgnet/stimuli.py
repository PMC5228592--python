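"""Extrinsic inputs: square-wave-modulated Poisson drives and protocols.

Background cortical/thalamic input is an independent Poisson process per
target neuron whose rate alternates between v(1+a) and v(1-a) every half
cycle of the modulation frequency (1 Hz slow-wave; 20 Hz beta, used in the
dopamine-depleted activation state).  Action-selection protocols
superimpose 100-ms rate bursts on the channelized striatal pools, and the
hyperdirect stop signal is a 100-ms additive rate pulse on the STN drive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DriveSpec",
    "Episode",
    "BurstProtocol",
    "TrialSchedule",
    "modulated_poisson",
    "rate_at",
    "build_selection_trials",
    "stn_stop_pulse",
    "stepwise_input_sweep",
]


@dataclass
class Episode:
    """A transient drive modifier on a subset of target neurons:
    rate -> rate * factor + rate_add over [onset, onset + duration)."""

    onset: float            # ms
    duration: float         # ms
    factor: float = 1.0     # multiplier on the momentary rate
    rate_add: float = 0.0   # Hz, additive
    mask: np.ndarray | None = None   # bool over target neurons; None = all

    def active(self, t: float) -> bool:
        return self.onset <= t < self.onset + self.duration


@dataclass
class DriveSpec:
    """Poisson drive on one population.

    ``base_rate`` v (Hz per target neuron), square-wave modulation amplitude
    ``mod_amplitude`` a (fraction of v) at ``mod_freq`` (Hz; 0 = none).
    ``components`` lists the receptor conductances each event activates.
    """

    name: str
    target: str
    base_rate: float
    mod_amplitude: float = 0.0
    mod_freq: float = 0.0
    components: list = field(default_factory=list)
    episodes: list = field(default_factory=list)
    phase_offset: float = 0.0   # ms; models the source->target axonal delay
                                # as a lag of the rate modulation

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError(f"{self.name}: rate must be non-negative")
        if not (0.0 <= self.mod_amplitude < 1.0):
            raise ValueError(
                f"{self.name}: modulation amplitude must lie in [0, 1)")

    def with_episode(self, ep: Episode) -> "DriveSpec":
        d = replace(self, episodes=list(self.episodes) + [ep])
        return d


def rate_at(spec: DriveSpec, t: float) -> float:
    """Momentary square-wave rate v(1 +/- a) at time t (ms), before
    episode modifiers."""
    if spec.mod_freq <= 0 or spec.mod_amplitude == 0:
        return spec.base_rate
    t = t - spec.phase_offset
    half_period = 1000.0 / spec.mod_freq / 2.0
    up = (int(t // half_period) % 2) == 0
    return spec.base_rate * (1.0 + (spec.mod_amplitude if up
                                    else -spec.mod_amplitude))


def modulated_poisson(spec: DriveSpec, duration: float, n_targets: int,
                      seed: int = 0, dt: float = 0.1):
    """Generate event times per target neuron over ``duration`` ms.

    Piecewise-homogeneous Poisson: within each half cycle events are drawn
    at the momentary rate, independently per target.  Returns a list of
    time arrays (ms), one per target.  The long-run mean rate equals the
    base rate by the symmetry of the square wave.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    # segment boundaries at half-cycle edges
    if spec.mod_freq > 0 and spec.mod_amplitude > 0:
        half = 1000.0 / spec.mod_freq / 2.0
        edges = np.arange(0.0, duration, half)
    else:
        edges = np.array([0.0])
    edges = np.append(edges, duration)
    events = [[] for _ in range(n_targets)]
    for k in range(len(edges) - 1):
        t0, t1 = edges[k], edges[k + 1]
        r = rate_at(spec, t0) / 1000.0  # events per ms
        lam = r * (t1 - t0)
        counts = rng.poisson(lam, n_targets)
        for i in range(n_targets):
            if counts[i]:
                events[i].append(t0 + (t1 - t0) * np.sort(rng.random(counts[i])))
    return [np.concatenate(e) if e else np.empty(0) for e in events]


@dataclass
class BurstProtocol:
    """Selection-phase burst: 100 ms of elevated cortical drive on an
    action pool, followed by a rest phase on background drive alone."""

    target_pool: str            # label, e.g. "action:0"
    onset: float                # ms
    duration: float = 100.0
    burst_factor: float | None = 2.0   # multiplier on the base rate
    burst_rate: float | None = None    # absolute rate, Hz (overrides factor)
    rest_duration: float = 900.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("burst duration must be positive")


@dataclass
class TrialSchedule:
    """Full factorial selection protocol: per grid cell (factor_1,
    factor_2), ``trials_per_cell`` repeated 1-s trials."""

    trials: list                # (trial_index, (f1, f2), onset_ms)
    grid: list                  # [(f1, f2), ...]
    trials_per_cell: int
    trial_length: float = 1000.0
    settle: float = 1000.0

    @property
    def total_duration(self) -> float:
        return self.settle + len(self.trials) * self.trial_length


def build_selection_trials(factors_1, factors_2=None, trials_per_cell: int = 80,
                           burst_duration: float = 100.0,
                           rest_duration: float = 900.0,
                           settle: float = 1000.0) -> TrialSchedule:
    """Build the trial schedule of a selection experiment.

    The grid is the cross product of the two factor lists (the second
    defaults to the first); each cell is visited ``trials_per_cell`` times.
    Each trial is a ``burst_duration`` burst followed by ``rest_duration``
    of background drive.
    """
    factors_1 = list(factors_1)
    factors_2 = factors_1 if factors_2 is None else list(factors_2)
    if not factors_1 or not factors_2:
        raise ValueError("empty factor grid")
    if min(factors_1 + factors_2) < 1.0:
        raise ValueError("burst factors must be >= 1")
    grid = list(itertools.product(factors_1, factors_2))
    trials = []
    idx = 0
    for rep in range(trials_per_cell):
        for cell in grid:
            onset = settle + idx * (burst_duration + rest_duration)
            trials.append((idx, cell, onset))
            idx += 1
    return TrialSchedule(trials=trials, grid=grid,
                         trials_per_cell=trials_per_cell,
                         trial_length=burst_duration + rest_duration,
                         settle=settle)


def stn_stop_pulse(onset: float, duration: float = 100.0,
                   rate_add: float = 0.0, factor: float = 1.0) -> Episode:
    """Hyperdirect stop signal: transient extra drive on STN co-timed with
    the striatal selection burst."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return Episode(onset=onset, duration=duration, factor=factor,
                   rate_add=rate_add)


def stepwise_input_sweep(drives: dict, factors,
                         targets=("CTX->MSN_D1", "CTX->MSN_D2", "CTX->FSN",
                                  "CTX->STN")) -> list:
    """One drive set per factor, scaling the cortical inputs to MSN, FSN
    and STN while leaving the pallidal/nigral background untouched."""
    factors = list(factors)
    if any(f <= 0 for f in factors):
        raise ValueError("factors must be positive")
    out = []
    for f in factors:
        dset = {}
        for name, d in drives.items():
            if name in targets:
                dset[name] = replace(d, base_rate=d.base_rate * f)
            else:
                dset[name] = replace(d)
        out.append((f, dset))
    return out
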