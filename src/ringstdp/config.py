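"""Flat key-value configuration, table writers and run manifests.

Every model parameter is a scalar, so configs are flat YAML mappings with
units spelled out in the key names (``tau_plus_ms``, ``D_sp_s``, ``f_Hz``,
``C_m_pF`` ...).  :func:`load_config` validates the composite configuration
and normalises units to SI (ms -> s, Hz -> rad/s via ``nu = 2*pi*f``,
pF/MOhm/nS/mV -> F/Ohm/S/V).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ring_meanfield import RingConfig
from .spiking_sim import NeuronParams, SimConfig
from .stdp_core import STDPRule

__all__ = [
    "ConfigError",
    "load_config",
    "rule_from_dict",
    "rule_to_dict",
    "write_series",
    "read_series",
    "write_profile",
    "read_profile",
    "RunManifest",
]


class ConfigError(ValueError):
    """Invalid or missing configuration key."""


_RULE_KEYS = {
    "family": "exponential",
    "tau_plus_ms": 20.0,
    "tau_minus_ms": 20.0,
    "T_plus_ms": 0.0,
    "T_minus_ms": 0.0,
    "H": 1,
    "alpha": 1.0,
    "mu": 0.0,
    "lambda": 5e-3,
}

_RING_KEYS = {
    "N": 120,
    "D_sp_s": 10.0,
    "A_sp_s": 10.0,
    "f_Hz": 10.0,
    "d_ms": 0.0,
}

_NEURON_KEYS = {
    "C_m_pF": 200.0,
    "R_m_MOhm": 100.0,
    "V_rest_mV": -70.0,
    "E_E_mV": 0.0,
    "E_I_mV": -70.0,
    "V_th_mV": -54.0,
    "tau_E_ms": 5.0,
    "tau_I_ms": 5.0,
    "g_E_R_nS": 30.0,
    "g_I_R_nS": 50.0,
}

_SIM_KEYS = {
    "N_I": 40,
    "inhibitory_rate_sp_s": 10.0,
    "dt_ms": 1.0,
    "duration_s": 60.0,
    "seed": 0,
    "w0": 0.5,
    "w0_jitter": 0.0,
    "record_bin_s": 1.0,
    "post_bin_s": 60.0,
}


def rule_from_dict(cfg: dict) -> STDPRule:
    """Build an :class:`STDPRule` from flat config keys (times in ms)."""
    vals = {k: cfg.get(k, v) for k, v in _RULE_KEYS.items()}
    try:
        return STDPRule(
            family=vals["family"],
            tau_plus=float(vals["tau_plus_ms"]) * 1e-3,
            tau_minus=float(vals["tau_minus_ms"]) * 1e-3,
            T_plus=float(vals["T_plus_ms"]) * 1e-3,
            T_minus=float(vals["T_minus_ms"]) * 1e-3,
            H=int(vals["H"]),
            alpha=float(vals["alpha"]),
            mu=float(vals["mu"]),
            learning_rate=float(vals["lambda"]),
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid STDP rule configuration: {exc}") from exc


def rule_to_dict(rule: STDPRule) -> dict:
    return {
        "family": rule.family,
        "tau_plus_ms": rule.tau_plus * 1e3,
        "tau_minus_ms": rule.tau_minus * 1e3,
        "T_plus_ms": rule.T_plus * 1e3,
        "T_minus_ms": rule.T_minus * 1e3,
        "H": rule.H,
        "alpha": rule.alpha,
        "mu": rule.mu,
        "lambda": rule.learning_rate,
    }


def _check_unknown(cfg: dict):
    known = set(_RULE_KEYS) | set(_RING_KEYS) | set(_NEURON_KEYS) | set(_SIM_KEYS)
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")


def load_config(path_or_dict) -> SimConfig:
    """Load and validate a composite configuration into a :class:`SimConfig`.

    Accepts a YAML file path or an already-parsed mapping.  Missing keys take
    the documented defaults (the neuron defaults are the standard
    conductance-based parameter set).  Raises :class:`ConfigError` naming the
    offending key on invalid values or violated invariants (e.g. ``A > D``).
    """
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
        if not isinstance(cfg, dict):
            raise ConfigError("config file must contain a flat key-value mapping")
    _check_unknown(cfg)

    rule = rule_from_dict(cfg)

    ring_vals = {k: cfg.get(k, v) for k, v in _RING_KEYS.items()}
    try:
        ring = RingConfig(
            N=int(ring_vals["N"]),
            D=float(ring_vals["D_sp_s"]),
            A=float(ring_vals["A_sp_s"]),
            nu=2.0 * np.pi * float(ring_vals["f_Hz"]),
            d=float(ring_vals["d_ms"]) * 1e-3,
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid ring configuration (keys {sorted(_RING_KEYS)}): {exc}") from exc

    nv = {k: float(cfg.get(k, v)) for k, v in _NEURON_KEYS.items()}
    neuron = NeuronParams(
        C_m=nv["C_m_pF"] * 1e-12,
        R_m=nv["R_m_MOhm"] * 1e6,
        V_rest=nv["V_rest_mV"] * 1e-3,
        E_E=nv["E_E_mV"] * 1e-3,
        E_I=nv["E_I_mV"] * 1e-3,
        V_th=nv["V_th_mV"] * 1e-3,
        tau_E=nv["tau_E_ms"] * 1e-3,
        tau_I=nv["tau_I_ms"] * 1e-3,
        g_E_R=nv["g_E_R_nS"] * 1e-9,
        g_I_R=nv["g_I_R_nS"] * 1e-9,
    )

    sv = {k: cfg.get(k, v) for k, v in _SIM_KEYS.items()}
    dt = float(sv["dt_ms"]) * 1e-3
    if (ring.D + ring.A) * dt > 1.0:
        raise ConfigError("dt_ms too coarse: (D + A) * dt exceeds 1 spike per bin")
    return SimConfig(
        ring=ring,
        rule=rule,
        duration=float(sv["duration_s"]),
        seed=int(sv["seed"]),
        neuron=neuron,
        N_I=int(sv["N_I"]),
        inhibitory_rate=float(sv["inhibitory_rate_sp_s"]),
        dt=dt,
        w0=float(sv["w0"]),
        w0_jitter=float(sv["w0_jitter"]),
        record_bin=float(sv["record_bin_s"]),
        post_bin=float(sv["post_bin_s"]),
    )


def write_series(series: dict, path):
    """Write named columns (equal-length 1-D arrays) as a TSV table.

    Column order follows the dict order; floats are printed with 12
    significant digits so a read-back round-trips to ~1e-9 relative.
    """
    df = pd.DataFrame({k: np.asarray(v) for k, v in series.items()})
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_series(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_profile(profile, path, phases=None):
    """Write a ring weight profile as a two-column (phi, w) TSV table."""
    w = np.asarray(profile, dtype=float)
    if phases is None:
        phases = 2.0 * np.pi * np.arange(w.size) / w.size
    write_series({"phi": phases, "w": w}, path)


def read_profile(path):
    df = read_series(path)
    return df["phi"].to_numpy(), df["w"].to_numpy()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot + seed + code version.

    The same manifest, code version and seed reproduce every stochastic
    output bit-identically.
    """

    config: dict
    seed: int
    command: str = ""
    code_version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: list = field(default_factory=list)

    def start(self):
        self.started = time.strftime("%Y-%m-%dT%H:%M:%S")
        return self

    def finish(self):
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        return self

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
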