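"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from ringstdp.stdp_core import STDPRule, kernel_value, weight_dependence


@pytest.fixture
def exp_rule():
    """Temporally anti-symmetric Hebbian exponential rule, tau = 20 ms."""
    return STDPRule(family="exponential", tau_plus=0.020, tau_minus=0.020,
                    H=1, alpha=1.0, mu=0.0, learning_rate=5e-3)


@pytest.fixture
def mexican_hat_rule():
    """Symmetric difference-of-Gaussians rule (tau+ = 20 ms < tau- = 30 ms)."""
    return STDPRule(family="gaussian", tau_plus=0.020, tau_minus=0.030,
                    T_plus=0.0, T_minus=0.0, alpha=1.0, mu=0.0, learning_rate=5e-3)


def stdp_all_pairs(pre_raster, post_raster, rule: STDPRule, dt: float, w0, max_lag_bins=None):
    """Brute-force all-pairs STDP reference: explicit double loop over spikes.

    Processes bins in order; within a bin, pre-spike events first (pairing
    with strictly earlier post spikes), then the post-spike event (pairing
    with earlier and same-bin pre spikes).  Each event applies the summed
    pair contributions evaluated at the weight current at that event and
    clips to [0, 1].  ``max_lag_bins`` truncates the pair history (used to
    mirror the finite history buffer of the Gaussian-family implementation).
    """
    pre = np.asarray(pre_raster, dtype=bool)
    post = np.asarray(post_raster, dtype=bool)
    N, T = pre.shape
    w = np.full(N, 0.0)
    w[:] = w0
    lam = rule.learning_rate
    for n in range(T):
        m_min = 0 if max_lag_bins is None else max(0, n - max_lag_bins)
        for i in range(N):
            if pre[i, n]:
                f_plus, f_minus = weight_dependence(w[i], rule)
                acc = 0.0
                for m in range(m_min, n):  # strictly earlier post spikes
                    if post[m]:
                        lag = (m - n) * dt
                        acc += f_plus * kernel_value(lag, "plus", rule)
                        acc -= f_minus * kernel_value(lag, "minus", rule)
                w[i] = min(1.0, max(0.0, w[i] + lam * acc))
        if post[n]:
            for i in range(N):
                f_plus, f_minus = weight_dependence(w[i], rule)
                acc = 0.0
                for m in range(m_min, n + 1):  # earlier and same-bin pre spikes
                    if pre[i, m]:
                        lag = (n - m) * dt
                        acc += f_plus * kernel_value(lag, "plus", rule)
                        acc -= f_minus * kernel_value(lag, "minus", rule)
                w[i] = min(1.0, max(0.0, w[i] + lam * acc))
    return w
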