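"""Conductance-based synapse models.

Static synapses are single-exponential conductances: a presynaptic spike
increments the conductance by the peak value ``g0`` and between events the
conductance decays with ``tau_syn``; the postsynaptic current is
``g (E_rev - V)``, multiplied for NMDA receptors by the magnesium-block
factor B(V).  Short-term facilitation/depression uses the Tsodyks-Markram
resource formalism with recovered (x), active (y) and inactive (z) resource
fractions and the running utilization u.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StaticSynapseParams",
    "NmdaBlockParams",
    "TsodyksParams",
    "SynapseState",
    "static_decay",
    "static_on_spike",
    "mg_block_factor",
    "tsodyks_on_spike",
    "tsodyks_evolve",
]

RECEPTORS = ("AMPA", "NMDA", "GABA")


@dataclass
class StaticSynapseParams:
    name: str
    g0: float           # peak conductance, nS
    tau_syn: float      # decay time constant, ms
    E_rev: float        # reversal potential, mV
    delay: float        # axonal + synaptic delay, ms
    receptor: str = "AMPA"

    def __post_init__(self) -> None:
        if self.g0 < 0:
            raise ValueError(f"{self.name}: g0 must be non-negative")
        if self.tau_syn <= 0 or self.delay <= 0:
            raise ValueError(f"{self.name}: tau_syn and delay must be positive")
        if self.receptor not in RECEPTORS:
            raise ValueError(f"{self.name}: unknown receptor {self.receptor!r}")

    @property
    def is_dynamic(self) -> bool:
        return False


@dataclass
class NmdaBlockParams:
    """Magnesium block of the NMDA receptor (Jahr-Stevens form):

    B(V) = 1 / (1 + [Mg2+]/k_conc * exp(-k_volt * V)),  V in mV.

    With the classic constants k_conc = 3.57 mM and k_volt = 0.062/mV the
    block relieves smoothly with depolarization (e-fold per ~16 mV).
    """

    mg_mM: float = 1.0
    k_conc: float = 3.57    # mM
    k_volt: float = 0.062   # 1/mV

    def __post_init__(self) -> None:
        if self.mg_mM < 0:
            raise ValueError("magnesium concentration must be non-negative")


@dataclass
class TsodyksParams:
    """Tsodyks-Markram facilitating/depressing synapse.

    du/dt = -u/tau_fac + U (1-u) at spikes; release r = u*x moves resources
    from recovered (x) to active (y); y decays into the inactive pool z with
    tau_syn, and z recovers to x with tau_rec.  tau_fac = 0 denotes the
    no-facilitation limit: u is pinned to U at every spike.
    """

    name: str
    U: float
    tau_rec: float      # ms
    tau_fac: float      # ms; 0 = instantaneous decay (no facilitation)
    tau_syn: float      # ms
    g0: float           # nS
    E_rev: float        # mV
    delay: float        # ms
    receptor: str = "GABA"

    def __post_init__(self) -> None:
        if not (0 < self.U <= 1):
            raise ValueError(f"{self.name}: U must lie in (0, 1]")
        if self.tau_rec <= 0 or self.tau_fac < 0:
            raise ValueError(f"{self.name}: bad recovery/facilitation constants")
        if self.tau_syn <= 0 or self.delay <= 0:
            raise ValueError(f"{self.name}: tau_syn and delay must be positive")
        if self.g0 < 0:
            raise ValueError(f"{self.name}: g0 must be non-negative")
        if self.receptor not in RECEPTORS:
            raise ValueError(f"{self.name}: unknown receptor {self.receptor!r}")

    @property
    def is_dynamic(self) -> bool:
        return True


class SynapseState:
    """State of one synapse (or a vector of synapses).

    Static: conductance g (nS).  Tsodyks: utilization u and resource
    fractions (x, y, z) with x + y + z = 1.
    """

    def __init__(self, n: int = 1, dynamic: bool = False):
        self.dynamic = dynamic
        if dynamic:
            self.u = np.zeros(n)
            self.y = np.zeros(n)
            self.z = np.zeros(n)
        else:
            self.g = np.zeros(n)

    @property
    def x(self) -> np.ndarray:
        return 1.0 - self.y - self.z


def static_decay(state: SynapseState, p: StaticSynapseParams, dt: float) -> SynapseState:
    """Exact exponential decay of the conductance over dt ms."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.g *= np.exp(-dt / p.tau_syn)
    return state


def static_on_spike(state: SynapseState, p: StaticSynapseParams) -> SynapseState:
    """Additive conductance increment on a presynaptic spike (linear
    superposition of events)."""
    state.g += p.g0
    return state


def mg_block_factor(V, p: NmdaBlockParams):
    """Voltage-dependent relief of the NMDA magnesium block, in (0, 1]."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    return 1.0 / (1.0 + (p.mg_mM / p.k_conc) * np.exp(-p.k_volt * V))


def tsodyks_on_spike(state: SynapseState, p: TsodyksParams):
    """Process one presynaptic spike: facilitate, then release.

    u <- u + U(1-u) (u <- U when tau_fac = 0); the released fraction
    r = u*x moves from the recovered to the active pool.  Returns
    (state, r); the conductance jump is g0 * r.
    """
    if p.tau_fac > 0:
        state.u += p.U * (1.0 - state.u)
    else:
        state.u = np.full_like(np.asarray(state.u, dtype=float), p.U)
    r = state.u * state.x
    state.y += r
    return state, r


def tsodyks_evolve(state: SynapseState, p: TsodyksParams, dt: float) -> SynapseState:
    """Closed-form relaxation of (u, y, z) over a spike-free interval dt.

    u decays toward 0 with tau_fac; y decays into z with tau_syn; z drains
    into x with tau_rec.  x + y + z is conserved exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if p.tau_fac > 0:
        state.u = state.u * np.exp(-dt / p.tau_fac)
    else:
        state.u = np.zeros_like(np.asarray(state.u, dtype=float))
    ey = np.exp(-dt / p.tau_syn)
    ez = np.exp(-dt / p.tau_rec)
    y0, z0 = state.y, state.z
    if abs(p.tau_syn - p.tau_rec) < 1e-12:
        # degenerate equal-rate case: forcing resonates with its own decay
        state.z = (z0 + y0 * dt / p.tau_syn) * ez
    else:
        c = y0 * p.tau_rec / (p.tau_syn - p.tau_rec)
        state.z = (z0 - c) * ez + c * ey
    state.y = y0 * ey
    return state
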