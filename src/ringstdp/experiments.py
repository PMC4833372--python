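"""Canned study experiments: drift-velocity sweeps and delay measurement.

These functions fix the study conditions used throughout: ring inputs at
``D = A = 10`` spikes/s, the standard conductance-based neuron, 40 inhibitory
inputs at 10 spikes/s, and the additive rule (``mu = 0``, ``alpha = 1``) with
learning rate ``5e-3``.  The sweeps run a reduced ring of ``N_E = 200``
synapses for 15 simulated minutes per parameter value and estimate the drift
velocity of the weight-profile phase over the second half of each run.
"""

from __future__ import annotations

import numpy as np

from .ring_meanfield import RingConfig
from .spiking_sim import SimConfig, measure_effective_delay, sweep
from .stdp_core import STDPRule

__all__ = [
    "drift_frequency_sweep",
    "effective_delay",
    "mexican_hat_shift_sweep",
    "symmetry_breaking_config",
]

SWEEP_N = 200
SWEEP_DURATION = 900.0  # s per parameter value
SWEEP_LAMBDA = 5e-3


def _antisymmetric_rule(lam=SWEEP_LAMBDA):
    return STDPRule(family="exponential", tau_plus=0.020, tau_minus=0.020,
                    H=1, alpha=1.0, mu=0.0, learning_rate=lam)


def _mexican_hat_rule(lam=SWEEP_LAMBDA):
    return STDPRule(family="gaussian", tau_plus=0.020, tau_minus=0.030,
                    T_plus=0.0, T_minus=0.0, alpha=1.0, mu=0.0, learning_rate=lam)


def drift_frequency_sweep(seed: int, frequencies=(20.0, 24.0, 29.0, 33.0, 36.0)):
    """Drift velocity vs oscillation frequency for the anti-symmetric
    exponential rule; returns ``(rows, crossing_Hz)``."""
    ring = RingConfig(N=SWEEP_N, D=10.0, A=10.0, nu=2 * np.pi * frequencies[0], d=0.0)
    cfg = SimConfig(ring=ring, rule=_antisymmetric_rule(), duration=SWEEP_DURATION, seed=seed)
    return sweep(cfg, "frequency", list(frequencies))


def effective_delay(seed: int, f_hz: float = 29.0, duration: float = 60.0) -> float:
    """Effective post-synaptic delay (seconds) at ``f_hz`` modulation,
    measured with STDP disabled and weights frozen to a binary half-ring."""
    ring = RingConfig(N=SWEEP_N, D=10.0, A=10.0, nu=2 * np.pi * f_hz, d=0.0)
    cfg = SimConfig(ring=ring, rule=_antisymmetric_rule(), duration=duration, seed=seed)
    return measure_effective_delay(cfg)


def mexican_hat_shift_sweep(seed: int, shifts_s=(0.0, 0.005, 0.009, 0.013, 0.016)):
    """Drift velocity vs temporal shift T of the Mexican-hat rule at 10 Hz;
    returns ``(rows, crossing_s)``."""
    ring = RingConfig(N=SWEEP_N, D=10.0, A=10.0, nu=2 * np.pi * 10.0, d=0.0)
    cfg = SimConfig(ring=ring, rule=_mexican_hat_rule(), duration=SWEEP_DURATION, seed=seed)
    return sweep(cfg, "T_shift", list(shifts_s))


def symmetry_breaking_config(seed: int, duration: float = 3600.0) -> SimConfig:
    """The 120-synapse emergence run: anti-symmetric exponential rule with
    alpha = 1.1, mu = 0.1, lambda = 5e-4, inputs at 10 Hz."""
    rule = STDPRule(family="exponential", tau_plus=0.020, tau_minus=0.020,
                    H=1, alpha=1.1, mu=0.1, learning_rate=5e-4)
    ring = RingConfig(N=120, D=10.0, A=10.0, nu=2 * np.pi * 10.0, d=0.0)
    return SimConfig(ring=ring, rule=rule, duration=duration, seed=seed)
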