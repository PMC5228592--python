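"""Tonic dopamine as a parameter-scaling layer.

The dopamine receptor occupancy ``alpha`` in [0, 1] modulates neuron and
synapse parameters multiplicatively:

    p  <-  p * (1 + beta * phi(alpha)),     phi(alpha) = alpha - alpha0,

with alpha0 = 0.8 the normal occupancy (so the control network is the
identity) and alpha = 0 the fully depleted (6-OHDA-lesion) state.  Each
``beta`` coefficient is derived from an experimental amplitude ratio or a
resting-potential shift; the closed-form solvers below re-derive the
catalogued values from those constraints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "DopamineState",
    "BetaCoefficient",
    "ModulationTable",
    "phi",
    "scale_parameter",
    "solve_beta_from_ratio",
    "solve_beta_from_shift",
    "apply_depletion",
]

BETA_RANGE = (-5.0, 1.25)


@dataclass(frozen=True)
class DopamineState:
    """Receptor occupancy alpha and the reference occupancy alpha0."""

    alpha: float
    alpha0: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("occupancy alpha must lie in [0, 1]")


CONTROL = DopamineState(alpha=0.8)
DEPLETED = DopamineState(alpha=0.0)


@dataclass(frozen=True)
class BetaCoefficient:
    """One modulation entry: a target parameter path and its coefficient.

    ``form`` is "multiplicative_phi" (the standard 1 + beta*phi scaling,
    also used for fan-in targets, which are rounded to integers) or
    "literal_alpha" (the 1 - beta*alpha variant kept as a switch for the
    MSN D1 -> SNr entry).
    """

    target: str
    beta: float
    form: str = "multiplicative_phi"
    constraint: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (BETA_RANGE[0] <= self.beta <= BETA_RANGE[1]):
            warnings.warn(
                f"beta {self.beta} for {self.target} outside {BETA_RANGE}",
                stacklevel=2,
            )
        if self.form not in ("multiplicative_phi", "fan_in_scaling", "literal_alpha"):
            raise ValueError(f"unknown modulation form {self.form!r}")


@dataclass
class ModulationTable:
    entries: list[BetaCoefficient]

    def __iter__(self):
        return iter(self.entries)

    def get(self, target: str) -> BetaCoefficient:
        for e in self.entries:
            if e.target == target:
                return e
        raise KeyError(target)


def phi(state: DopamineState) -> float:
    """Occupancy deviation from the normal level: alpha - alpha0."""
    return state.alpha - state.alpha0


def scale_parameter(p_value: float, beta: float, state: DopamineState,
                    form: str = "multiplicative_phi") -> float:
    """Dopamine-scaled parameter value p * (1 + beta * phi(alpha)).

    A conductance driven negative by extreme depletion is clamped to zero
    with a warning (degenerate-depletion guard, applies only to magnitudes
    that must stay non-negative, i.e. positive base values).
    """
    if not (math.isfinite(p_value) and math.isfinite(beta)):
        raise ValueError("non-finite input")
    if form == "literal_alpha":
        scaled = p_value * (1.0 - beta * state.alpha)
    else:
        scaled = p_value * (1.0 + beta * phi(state))
    if p_value > 0 and scaled < 0:
        warnings.warn(
            f"dopamine scaling drove parameter {p_value} negative; clamped to 0",
            stacklevel=2,
        )
        scaled = 0.0
    return scaled


def solve_beta_from_ratio(ratio_low_over_high: float, alpha_low: float = 0.0,
                          alpha_high: float = 1.0, alpha0: float = 0.8) -> float:
    """Solve (1 + beta*phi(a_low)) / (1 + beta*phi(a_high)) = R for beta.

    For the standard endpoints (a_low=0, a_high=1, alpha0=0.8) this is the
    closed form beta = (1 - R) / (0.8 + 0.2 R).
    """
    R = ratio_low_over_high
    if R <= 0:
        raise ValueError("amplitude ratio must be positive")
    pl, ph = alpha_low - alpha0, alpha_high - alpha0
    denom = R * ph - pl
    if denom == 0:
        raise ValueError("degenerate constraint: occupancies coincide")
    beta = (1.0 - R) / denom
    if abs(1.0 + beta * ph) < 1e-12:
        raise ValueError("constraint places the high-occupancy value at zero")
    if not (BETA_RANGE[0] <= beta <= BETA_RANGE[1]):
        warnings.warn(f"solved beta {beta:.4g} outside {BETA_RANGE}", stacklevel=2)
    return beta


def solve_beta_from_shift(delta: float, base: float) -> float:
    """Solve for beta such that the parameter differs by ``delta`` between
    full depletion (alpha=0) and full occupancy (alpha=1):

        base*(1 + beta*phi(0)) - base*(1 + beta*phi(1)) = delta
        =>  beta = -delta / base.
    """
    if base == 0:
        raise ValueError("base value must be nonzero")
    beta = -delta / base
    if not (BETA_RANGE[0] <= beta <= BETA_RANGE[1]):
        warnings.warn(f"solved beta {beta:.4g} outside {BETA_RANGE}", stacklevel=2)
    return beta


def _split_target(target: str):
    parts = target.split(":")
    kind = parts[0]
    if kind == "synapse" and len(parts) == 3:
        return ("synapse", parts[1], parts[2])
    if kind == "drive" and len(parts) == 4:
        return ("drive", parts[1], parts[2], parts[3])
    if kind == "fan_in" and len(parts) == 2:
        return ("fan_in", parts[1])
    if kind == "neuron" and len(parts) == 3:
        return ("neuron", parts[1], parts[2])
    raise ValueError(f"malformed modulation target {target!r}")


def apply_depletion(config, table: ModulationTable, state: DopamineState,
                    restore: tuple[str, ...] = ()):
    """Return a copy of a network configuration with every catalogued
    parameter scaled to the occupancy ``state.alpha``.

    Fan-in targets are rounded half-up and floored at zero.  Targets named
    in ``restore`` are kept at their reference (alpha0) value — the
    one-parameter restoration mode of the lesion experiments.  The input
    configuration is left untouched.
    """
    cfg = config.copy()
    ref = DopamineState(alpha=state.alpha0, alpha0=state.alpha0)
    for entry in table:
        s = ref if entry.target in restore else state
        parts = _split_target(entry.target)
        kind = parts[0]
        if kind == "synapse":
            _, conn, param = parts
            syn = cfg.connections[conn].synapse
            if param != "g0":
                raise KeyError(f"unknown synapse parameter {param!r}")
            cfg.connections[conn].synapse = replace(
                syn, g0=scale_parameter(syn.g0, entry.beta, s, entry.form))
        elif kind == "drive":
            _, drive, receptor, param = parts
            comps = cfg.drives[drive].components
            hit = [i for i, c in enumerate(comps) if c.receptor == receptor]
            if not hit or param != "g0":
                raise KeyError(f"unknown drive target {entry.target!r}")
            for i in hit:
                comps[i] = replace(
                    comps[i],
                    g0=scale_parameter(comps[i].g0, entry.beta, s, entry.form))
        elif kind == "fan_in":
            conn = parts[1]
            spec = cfg.connections[conn]
            scaled = scale_parameter(float(spec.fan_in), entry.beta, s, entry.form)
            spec.fan_in = max(0, int(math.floor(scaled + 0.5)))
        elif kind == "neuron":
            _, pop, param = parts
            np_ = cfg.populations[pop].neuron_params
            if not hasattr(np_, param):
                raise KeyError(f"unknown neuron parameter {param!r} on {pop}")
            cfg.populations[pop].neuron_params = replace(
                np_, **{param: scale_parameter(getattr(np_, param), entry.beta, s,
                                               entry.form)})
    cfg.alpha = state.alpha
    return cfg
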