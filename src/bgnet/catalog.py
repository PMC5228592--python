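"""Parameter-catalogue loading and default network assembly.

The shipped YAML files transcribe the published parameter tables
field-for-field (neuron models, synapse rows, dopamine scaling
coefficients, population sizes, fan-ins and drive rates).  This module
parses them into the typed objects used by the builder and engine, and
assembles the default control-condition configuration at any network size.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import replace

import yaml

from .dopamine import BetaCoefficient, DopamineState, ModulationTable, apply_depletion
from .neuron_models import AdexParams, HeterogeneitySpec, QifAdaptParams
from .network_builder import (ConnectionSpec, DriveConfig, NetworkConfig,
                              PopulationSpec, population_sizes)
from .stimuli import DriveSpec
from .synapse_models import StaticSynapseParams, TsodyksParams

__all__ = [
    "load_neuron_params",
    "load_synapse_catalog",
    "load_modulation_table",
    "default_config",
    "make_drives",
    "lesioned_config",
]

_QIF_FIELDS = {"C", "k", "v_r", "v_th", "v_peak", "c", "a", "b", "d", "v_b",
               "is_fsn_variant"}
_ADEX_FIELDS = {"C", "g_L", "E_L", "V_T", "Delta_T", "a_sub", "tau_w",
                "b_spike", "V_r", "t_f", "I_e", "stn_rebound",
                "adaptation_gate_mV"}


def _read(name: str) -> dict:
    path = resources.files("bgnet.data").joinpath(name)
    with path.open("r") as fh:
        return yaml.safe_load(fh)


def load_neuron_params() -> dict:
    """Neuron parameter sets per population, validated for completeness."""
    raw = _read("neurons.yaml")
    out = {}
    for name, row in raw.items():
        model = row.pop("model")
        row = {k: v for k, v in row.items()
               if k not in ("source",) and not k.startswith("beta")
               and k != "alpha_k"}
        if model == "qif":
            unknown = set(row) - _QIF_FIELDS
            if unknown:
                raise ValueError(f"{name}: unknown fields {unknown}")
            out[name] = QifAdaptParams(name=name, **row)
        elif model == "adex":
            unknown = set(row) - _ADEX_FIELDS
            if unknown:
                raise ValueError(f"{name}: unknown fields {unknown}")
            out[name] = AdexParams(name=name, **row)
        else:
            raise ValueError(f"{name}: unknown model family {model!r}")
    return out


def load_synapse_catalog() -> tuple[dict, dict]:
    """(connection synapse parameters, drive component lists)."""
    raw = _read("synapses.yaml")
    conns = {}
    for name, row in raw["connections"].items():
        std = row.pop("std", None)
        if std is None:
            conns[name] = StaticSynapseParams(name=name, **row)
        else:
            conns[name] = TsodyksParams(name=name, **std, **row)
    drives = {}
    for name, comps in raw["drives"].items():
        drives[name] = [
            StaticSynapseParams(name=f"{name}:{c['receptor']}", **c)
            for c in comps
        ]
    return conns, drives


def load_modulation_table() -> ModulationTable:
    raw = _read("dopamine.yaml")
    entries = [
        BetaCoefficient(target=e["target"], beta=float(e["beta"]),
                        constraint=e.get("constraint", {}))
        for e in raw["entries"]
    ]
    return ModulationTable(entries=entries)


def default_config(n_total: int = 10000, alpha: float = 0.8,
                   het_C_cv: float = 0.10, het_Vth_sd: float = 1.0,
                   action_channels=None) -> NetworkConfig:
    """Assemble the control-condition network configuration.

    Population sizes follow the fixed nucleus fractions; fan-ins are the
    absolute catalogued in-degrees (kept when scaling down).  Dopamine
    occupancy defaults to the normal level 0.8; use lesioned_config() for
    the depleted network.
    """
    neuron = load_neuron_params()
    syn_conns, syn_drives = load_synapse_catalog()
    netraw = _read("network.yaml")
    sizes = population_sizes(n_total)

    populations = {
        name: PopulationSpec(
            name=name, size=sizes[name], neuron_params=neuron[name],
            heterogeneity=HeterogeneitySpec(C_cv=het_C_cv, Vth_sd=het_Vth_sd))
        for name in sizes
    }
    connections = {}
    for name, row in netraw["connections"].items():
        pre, post = name.split("->")
        connections[name] = ConnectionSpec(
            name=name, pre=pre, post=post, fan_in=int(row["fan_in"]),
            synapse=syn_conns[name],
            spatial_window=row.get("spatial_window"),
            pre_subpopulation=row.get("pre_subpopulation"),
        )
    drives = {}
    for name, row in netraw["drives"].items():
        target = name.split("->")[1]
        drives[name] = DriveConfig(
            name=name, target=target,
            rate_slow_wave=float(row["rate_slow_wave"]),
            rate_activation=float(row["rate_activation"]),
            amp_slow_wave=float(row["amp_slow_wave"]),
            amp_activation=float(row["amp_activation"]),
            components=list(syn_drives[name]),
        )
    cfg = NetworkConfig(n_total=n_total, populations=populations,
                        connections=connections, drives=drives, alpha=alpha,
                        action_channels=action_channels)
    cfg.validate()
    return cfg


def lesioned_config(n_total: int = 10000, alpha: float = 0.0,
                    restore: tuple[str, ...] = (), **kwargs) -> NetworkConfig:
    """Dopamine-depleted configuration: the control network with every
    catalogued parameter scaled to occupancy ``alpha`` (optionally with
    selected targets restored to their control values)."""
    cfg = default_config(n_total=n_total, **kwargs)
    table = load_modulation_table()
    return apply_depletion(cfg, table, DopamineState(alpha=alpha),
                           restore=restore)


def make_drives(config: NetworkConfig, condition: str = "activation",
                beta_modulated: bool | None = None) -> dict:
    """Concrete drive specs for one cortical regime.

    ``slow_wave`` applies the 1-Hz square-wave modulation in both dopamine
    conditions; ``activation`` applies the 20-Hz beta modulation only when
    the configuration is dopamine-depleted (override with
    ``beta_modulated``).
    """
    if condition not in ("slow_wave", "activation"):
        raise ValueError("condition must be 'slow_wave' or 'activation'")
    if beta_modulated is None:
        beta_modulated = condition == "activation" and config.alpha < 0.8
    out = {}
    for name, d in config.drives.items():
        if condition == "slow_wave":
            rate, amp, freq = d.rate_slow_wave, d.amp_slow_wave, 1.0
        else:
            rate = d.rate_activation
            amp = d.amp_activation if beta_modulated else 0.0
            freq = 20.0 if beta_modulated else 0.0
        out[name] = DriveSpec(name=name, target=d.target, base_rate=rate,
                              mod_amplitude=amp, mod_freq=freq,
                              components=[replace(c) for c in d.components],
                              phase_offset=d.phase_offset)
    return out
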