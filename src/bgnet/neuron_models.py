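"""Hybrid point-neuron models of the basal ganglia populations.

Two model families are used throughout the circuit:

* a quadratic integrate-and-fire model with a slow recovery current
  (Izhikevich-type) for the striatal projection neurons (MSN D1/D2) and the
  fast-spiking interneurons (FSN, with a cubic recovery nonlinearity below a
  kink voltage ``v_b``), and
* the adaptive exponential integrate-and-fire (AdEx) model for STN, GPe
  (arkypallidal TA / prototypical TI) and SNr neurons.

Units are mV, ms, pF, nS and pA throughout (nS*mV = pA, pF*mV/ms = pA).
The QIF recovery rate ``a`` is stored per millisecond.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "QifAdaptParams",
    "AdexParams",
    "NeuronState",
    "HeterogeneitySpec",
    "qif_derivatives",
    "fsn_recovery_derivative",
    "adex_derivatives",
    "apply_spike_reset",
    "sample_heterogeneity",
    "fi_curve",
    "simulate_single",
]

# AdEx exponential argument beyond which the membrane is declared spiking
# instead of evaluating exp() (overflow guard).
_EXP_ARG_MAX = 30.0


@dataclass
class QifAdaptParams:
    """Quadratic integrate-and-fire neuron with adaptation.

    dV/dt = [k (V - v_r)(V - v_th) - u + I] / C
    du/dt = a [b (V - v_r) - u]              (MSN form)
    du/dt = a [b (V - v_b)^3 - u] if V <= v_b else -a u   (FSN form)

    On V > v_peak: V <- c, u <- u + d.
    """

    name: str
    C: float            # pF
    k: float            # steady-state I-V coefficient
    v_r: float          # mV
    v_th: float         # mV
    v_peak: float       # mV
    c: float            # spike reset, mV
    a: float            # recovery rate, 1/ms
    b: float            # recovery voltage dependence
    d: float            # spike-triggered recovery increment, pA
    v_b: float | None = None   # recovery kink voltage (FSN only), mV
    is_fsn_variant: bool = False

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"{self.name}: capacitance must be positive")
        if not (self.v_r < self.v_th < self.v_peak):
            raise ValueError(f"{self.name}: require v_r < v_th < v_peak")
        if self.c >= self.v_peak:
            raise ValueError(f"{self.name}: reset c must lie below v_peak")
        if self.a <= 0:
            raise ValueError(f"{self.name}: recovery rate a must be positive")
        if self.is_fsn_variant and self.v_b is None:
            raise ValueError(f"{self.name}: FSN variant requires v_b")

    @property
    def threshold(self) -> float:
        return self.v_th

    @property
    def cutoff(self) -> float:
        return self.v_peak

    @property
    def rest(self) -> float:
        return self.v_r


@dataclass
class AdexParams:
    """Adaptive exponential integrate-and-fire neuron.

    C dV/dt = -g_L (V - E_L) + g_L Delta_T exp((V - V_T)/Delta_T) - w + I
    tau_w dw/dt = a_sub (V - E_L) - w

    On V > t_f: V <- V_r, w <- w + b_spike.  The STN variant additionally
    uses a depolarized reset V_r + max(w - stn_reset_offset, stn_reset_cap)
    when w < 0 at spike time (hyperpolarization-induced rebound burst), and
    gates the subthreshold adaptation conductance to zero above
    ``adaptation_gate_mV``.
    """

    name: str
    C: float            # pF
    g_L: float          # nS
    E_L: float          # mV
    V_T: float          # mV
    Delta_T: float      # mV
    a_sub: float        # nS
    tau_w: float        # ms
    b_spike: float      # pA
    V_r: float          # mV
    t_f: float          # spike cutoff, mV
    I_e: float = 0.0    # tonic bias, pA
    stn_rebound: bool = False
    stn_reset_offset: float = 15.0  # mV
    stn_reset_cap: float = 20.0     # mV
    stn_reset_mode: str = "max"     # literal printed rule; "min" available
    adaptation_gate_mV: float | None = None

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g_L <= 0:
            raise ValueError(f"{self.name}: C and g_L must be positive")
        if self.Delta_T <= 0 or self.tau_w <= 0:
            raise ValueError(f"{self.name}: Delta_T and tau_w must be positive")
        if self.V_r >= self.t_f:
            raise ValueError(f"{self.name}: reset V_r must lie below cutoff t_f")
        if self.stn_reset_mode not in ("max", "min"):
            raise ValueError(f"{self.name}: stn_reset_mode must be 'max' or 'min'")

    @property
    def threshold(self) -> float:
        return self.V_T

    @property
    def cutoff(self) -> float:
        return self.t_f

    @property
    def rest(self) -> float:
        return self.E_L


@dataclass
class NeuronState:
    """State of one neuron (or a vector of neurons): membrane potential V and
    the slow recovery/adaptation current u (QIF) or w (AdEx), both in pA."""

    V: np.ndarray
    u_or_w: np.ndarray

    def __init__(self, V, u_or_w):
        self.V = np.atleast_1d(np.asarray(V, dtype=float)).copy()
        self.u_or_w = np.atleast_1d(np.asarray(u_or_w, dtype=float)).copy()


@dataclass
class HeterogeneitySpec:
    """Population heterogeneity: capacitance CV and spike-threshold SD."""

    C_cv: float = 0.10      # fraction of the mean
    Vth_sd: float = 1.0     # mV
    seed: int = 0


def _check_finite(state: NeuronState) -> None:
    if not (np.all(np.isfinite(state.V)) and np.all(np.isfinite(state.u_or_w))):
        raise ValueError("non-finite neuron state")


def qif_derivatives(state: NeuronState, p: QifAdaptParams, I=0.0):
    """Right-hand side of the QIF-with-adaptation model.

    Returns (dV/dt in mV/ms, du/dt in pA/ms).  For the FSN variant the
    recovery derivative uses the cubic form (see fsn_recovery_derivative).
    """
    _check_finite(state)
    V, u = state.V, state.u_or_w
    dV = (p.k * (V - p.v_r) * (V - p.v_th) - u + I) / p.C
    if p.is_fsn_variant:
        du = fsn_recovery_derivative(state, p)
    else:
        du = p.a * (p.b * (V - p.v_r) - u)
    return dV, du


def fsn_recovery_derivative(state: NeuronState, p: QifAdaptParams):
    """FSN recovery current: du/dt = a [b (V - v_b)^3 - u] for V <= v_b,
    du/dt = -a u above v_b (type-2 nonlinear onset of spiking)."""
    if not p.is_fsn_variant:
        raise ValueError("fsn_recovery_derivative requires the FSN variant")
    V, u = state.V, state.u_or_w
    below = V <= p.v_b
    return np.where(below, p.a * (p.b * (V - p.v_b) ** 3 - u), -p.a * u)


def adex_derivatives(state: NeuronState, p: AdexParams, I=0.0):
    """Right-hand side of the AdEx model: (dV/dt mV/ms, dw/dt pA/ms).

    The exponential argument is clamped; a membrane driven past the clamp is
    treated as spiking by the integrator.  For the STN variant the
    subthreshold adaptation conductance applies only below the gate voltage.
    """
    _check_finite(state)
    V, w = state.V, state.u_or_w
    arg = np.minimum((V - p.V_T) / p.Delta_T, _EXP_ARG_MAX)
    dV = (-p.g_L * (V - p.E_L) + p.g_L * p.Delta_T * np.exp(arg) - w + I) / p.C
    if p.adaptation_gate_mV is None:
        a_eff = p.a_sub
    else:
        a_eff = np.where(V < p.adaptation_gate_mV, p.a_sub, 0.0)
    dw = (a_eff * (V - p.E_L) - w) / p.tau_w
    return dV, dw


def apply_spike_reset(state: NeuronState, p) -> NeuronState:
    """Reset every neuron whose membrane crossed the spike cutoff.

    QIF family:  V <- c,   u <- u + d.
    AdEx family: V <- V_r, w <- w + b_spike; the STN rebound variant resets
    to V_r + max(w - offset, cap) when w < 0 at spike time (the printed rule,
    applied literally; `stn_reset_mode="min"` swaps max for min).
    """
    V, x = state.V, state.u_or_w
    spiked = V >= p.cutoff
    if isinstance(p, QifAdaptParams):
        V[spiked] = p.c
        x[spiked] += p.d
    else:
        if p.stn_rebound:
            w_spk = x[spiked]
            fn = np.maximum if p.stn_reset_mode == "max" else np.minimum
            depol = p.V_r + fn(w_spk - p.stn_reset_offset, p.stn_reset_cap)
            V[spiked] = np.where(w_spk < 0.0, depol, p.V_r)
        else:
            V[spiked] = p.V_r
        x[spiked] += p.b_spike
    return state


def sample_heterogeneity(base: QifAdaptParams | AdexParams,
                         spec: HeterogeneitySpec, n: int):
    """Sample per-neuron capacitances and spike thresholds.

    C ~ Normal(C, C_cv*C), resampled until positive; the threshold (v_th for
    QIF, V_T for AdEx) ~ Normal(mean, Vth_sd).  Returns (C array, threshold
    array); all other parameters are shared.  Reproducible given spec.seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    C = base.C + spec.C_cv * base.C * rng.standard_normal(n)
    for _ in range(100):
        bad = C <= 0
        if not bad.any():
            break
        C[bad] = base.C + spec.C_cv * base.C * rng.standard_normal(bad.sum())
    thr = base.threshold + spec.Vth_sd * rng.standard_normal(n)
    return C, thr


def _step(state: NeuronState, p, I, dt: float):
    """One forward-Euler step; returns boolean spike mask (cutoff crossing
    detected at step end, membrane clamped to cutoff)."""
    if isinstance(p, QifAdaptParams):
        dV, dx = qif_derivatives(state, p, I)
    else:
        dV, dx = adex_derivatives(state, p, I)
    state.V += dt * dV
    state.u_or_w += dt * dx
    spiked = state.V >= p.cutoff
    state.V[spiked] = p.cutoff
    return spiked


def simulate_single(p, I=0.0, duration: float = 2000.0, dt: float = 0.1,
                    V0: float | None = None, w0: float = 0.0,
                    record: bool = False, include_bias: bool = True):
    """Integrate a single neuron with constant current I (pA) plus the tonic
    bias I_e where the model carries one (unless ``include_bias`` is off).
    Returns spike times (ms), and the (t, V, u/w) trace when ``record`` is
    set."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    bias = getattr(p, "I_e", 0.0) if include_bias else 0.0
    V0 = p.rest if V0 is None else V0
    state = NeuronState(np.array([V0]), np.array([w0]))
    n_steps = int(round(duration / dt))
    spikes = []
    trace = np.empty((n_steps, 3)) if record else None
    for i in range(n_steps):
        spiked = _step(state, p, I + bias, dt)
        if record:
            trace[i] = ((i + 1) * dt, state.V[0], state.u_or_w[0])
        if spiked[0]:
            spikes.append((i + 1) * dt)
            apply_spike_reset(state, p)
    spikes = np.asarray(spikes)
    return (spikes, trace) if record else spikes


def fi_curve(p, I_values: Sequence[float], duration: float = 2000.0,
             dt: float = 0.1, transient: float = 1000.0) -> np.ndarray:
    """Mean firing rate (Hz) versus total injected current (I_values replace
    the tonic bias I_e rather than adding to it).

    Each point integrates the neuron for ``duration`` ms and counts spikes
    after discarding the first ``transient`` ms.  The membrane starts just
    above threshold, so neurons whose resting state coexists with a spiking
    limit cycle (the pallidal pacemakers are bistable at low drive) are
    measured on the spiking branch; below rheobase the onset spike decays
    within the transient and the rate is zero.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rates = []
    for I in I_values:
        spikes = simulate_single(p, I=I, duration=duration, dt=dt,
                                 V0=p.threshold + 5.0, include_bias=False)
        n = int(np.sum(spikes > transient))
        rates.append(1000.0 * n / (duration - transient))
    return np.asarray(rates)
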