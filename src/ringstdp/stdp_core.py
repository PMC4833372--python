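"""Spike-timing dependent plasticity (STDP) rules: weight dependence and temporal kernels.

A separable STDP rule updates a synaptic weight ``w`` on every pre/post spike
pair with lag ``dt = t_post - t_pre``::

    dw = lam * (f_plus(w) * K_plus(dt) - f_minus(w) * K_minus(dt))

where the weight dependence follows the soft-bound family

    f_plus(w)  = (1 - w)**mu
    f_minus(w) = alpha * w**mu

(``mu = 0`` is the additive rule, ``mu = 1`` the multiplicative rule, ``alpha``
the relative strength of depression), and the temporal kernels ``K_plus`` /
``K_minus`` come from one of two families:

* ``exponential`` — temporally asymmetric, one-sided exponentials of time
  constants ``tau_plus`` / ``tau_minus``; the polarity flag ``H = +1`` places
  potentiation on the causal branch (Hebbian), ``H = -1`` on the anti-causal
  branch (anti-Hebbian).
* ``gaussian`` — a pair of Gaussians of widths ``tau_plus`` / ``tau_minus``
  centred at shifts ``T_plus`` / ``T_minus`` (difference-of-Gaussians /
  "Mexican hat" rules and their temporally shifted variants).

All kernels are normalised to unit area, so their Fourier transforms at zero
frequency equal one.  The Fourier convention is

    K_tilde * exp(i * Omega) = integral( exp(-i * nu * dt) * K(dt) ddt )

with ``K_tilde >= 0`` and ``Omega`` wrapped to ``(-pi, pi]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.integrate import quad

__all__ = [
    "STDPRule",
    "KernelSpectrum",
    "weight_dependence",
    "kernel_value",
    "kernel_fourier",
    "kernel_fourier_numeric",
    "wrap_phase",
]

Family = Literal["exponential", "gaussian"]


def wrap_phase(phi):
    """Wrap an angle (or array of angles) to the interval (-pi, pi]."""
    out = -np.mod(-np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi) + np.pi
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class STDPRule:
    """Parameters of a separable STDP rule.

    Parameters
    ----------
    family
        Temporal-kernel family, ``"exponential"`` or ``"gaussian"``.
    tau_plus, tau_minus
        Kernel time constants (widths for the gaussian family), in seconds.
    T_plus, T_minus
        Temporal shifts of the gaussian kernels, in seconds.  Ignored by the
        exponential family.
    H
        Polarity of the exponential family: ``+1`` Hebbian (potentiation for
        ``dt > 0``), ``-1`` anti-Hebbian.  Ignored by the gaussian family.
    alpha
        Relative strength of depression (``>= 0``).
    mu
        Non-linearity of the weight dependence (``>= 0``; ``0`` = additive).
    learning_rate
        Update scale ``lam`` (``> 0``).
    """

    family: Family = "exponential"
    tau_plus: float = 0.020
    tau_minus: float = 0.020
    T_plus: float = 0.0
    T_minus: float = 0.0
    H: int = 1
    alpha: float = 1.0
    mu: float = 0.0
    learning_rate: float = 5e-3

    def __post_init__(self):
        if self.family not in ("exponential", "gaussian"):
            raise ValueError(f"unknown kernel family: {self.family!r}")
        if not (self.tau_plus > 0 and self.tau_minus > 0):
            raise ValueError("tau_plus and tau_minus must be positive")
        if self.family == "exponential" and self.H not in (-1, 1):
            raise ValueError("H must be +1 or -1 for the exponential family")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class KernelSpectrum:
    """Fourier data of the two STDP kernels at one angular frequency.

    ``K_tilde_*`` are the magnitudes of the Fourier transforms, ``Omega_*``
    their phases (radians, in ``(-pi, pi]``), and ``K_bar_*`` the
    zero-frequency integrals (1 for normalised kernels).
    """

    K_tilde_plus: float
    K_tilde_minus: float
    Omega_plus: float
    Omega_minus: float
    K_bar_plus: float = 1.0
    K_bar_minus: float = 1.0


def weight_dependence(w, rule: STDPRule):
    """Evaluate ``(f_plus, f_minus)`` at weight(s) ``w`` in ``[0, 1]``.

    ``f_plus = (1 - w)**mu`` and ``f_minus = alpha * w**mu``; for ``mu = 0``
    both reduce to constants (additive rule).
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    if rule.mu == 0:
        f_plus = np.ones_like(w)
        f_minus = np.full_like(w, rule.alpha)
    else:
        f_plus = (1.0 - w) ** rule.mu
        f_minus = rule.alpha * w**rule.mu
    if w.ndim == 0:
        return float(f_plus), float(f_minus)
    return f_plus, f_minus


def kernel_value(delta_t, branch: str, rule: STDPRule):
    """Evaluate one temporal kernel at lag(s) ``delta_t = t_post - t_pre`` (s).

    Returns a density in 1/s.  The exponential family is one-sided with the
    step function evaluated as ``Theta(0) = 0`` (simultaneous spikes do not
    contribute); the gaussian family is supported on the whole axis.
    """
    if branch not in ("plus", "minus"):
        raise ValueError("branch must be 'plus' or 'minus'")
    dt = np.asarray(delta_t, dtype=float)
    sign = 1.0 if branch == "plus" else -1.0
    tau = rule.tau_plus if branch == "plus" else rule.tau_minus
    if rule.family == "exponential":
        x = sign * rule.H * dt  # kernel supported on x > 0
        out = np.where(x > 0, np.exp(-np.abs(x) / tau) / tau, 0.0)
    else:
        T = rule.T_plus if branch == "plus" else rule.T_minus
        out = np.exp(-0.5 * ((dt - T) / tau) ** 2) / (tau * np.sqrt(2.0 * np.pi))
    return float(out) if out.ndim == 0 else out


def kernel_fourier(rule: STDPRule, nu: float) -> KernelSpectrum:
    """Closed-form Fourier data of both kernels at angular frequency ``nu``.

    Exponential family::

        K_tilde = (1 + (nu*tau)**2)**-0.5,   Omega = -/+ H * arctan(nu*tau)

    Gaussian family::

        K_tilde = exp(-(nu*tau)**2 / 2),     Omega = -nu*T

    (phases wrapped to ``(-pi, pi]``).
    """
    if nu < 0:
        raise ValueError("nu must be non-negative")
    if rule.family == "exponential":
        kt_p = (1.0 + (nu * rule.tau_plus) ** 2) ** -0.5
        kt_m = (1.0 + (nu * rule.tau_minus) ** 2) ** -0.5
        om_p = -rule.H * np.arctan(nu * rule.tau_plus)
        om_m = +rule.H * np.arctan(nu * rule.tau_minus)
    else:
        kt_p = np.exp(-0.5 * (nu * rule.tau_plus) ** 2)
        kt_m = np.exp(-0.5 * (nu * rule.tau_minus) ** 2)
        om_p = -nu * rule.T_plus
        om_m = -nu * rule.T_minus
    return KernelSpectrum(
        K_tilde_plus=float(kt_p),
        K_tilde_minus=float(kt_m),
        Omega_plus=wrap_phase(om_p),
        Omega_minus=wrap_phase(om_m),
    )


def _numeric_transform(rule: STDPRule, branch: str, nu: float):
    """Numerical quadrature of ``integral(exp(-i nu dt) K(dt) ddt)``.

    Support is truncated where the kernel falls below machine precision
    (|dt - T| <= 40 tau); the integrand's discontinuity at dt = 0 for the
    exponential family is passed to the quadrature as a break point.
    """
    tau = rule.tau_plus if branch == "plus" else rule.tau_minus
    T = (rule.T_plus if branch == "plus" else rule.T_minus) if rule.family == "gaussian" else 0.0
    lo, hi = T - 40.0 * tau, T + 40.0 * tau

    def f_re(t):
        return np.cos(nu * t) * kernel_value(t, branch, rule)

    def f_im(t):
        return -np.sin(nu * t) * kernel_value(t, branch, rule)

    kw = dict(points=[0.0, T], limit=400, epsabs=1e-12, epsrel=1e-12)
    re = quad(f_re, lo, hi, **kw)[0]
    im = quad(f_im, lo, hi, **kw)[0]
    return re + 1j * im


def kernel_fourier_numeric(rule: STDPRule, nu: float) -> KernelSpectrum:
    """Quadrature-based counterpart of :func:`kernel_fourier` (slow, exact)."""
    zp = _numeric_transform(rule, "plus", nu)
    zm = _numeric_transform(rule, "minus", nu)
    return KernelSpectrum(
        K_tilde_plus=float(abs(zp)),
        K_tilde_minus=float(abs(zm)),
        Omega_plus=wrap_phase(np.angle(zp)),
        Omega_minus=wrap_phase(np.angle(zm)),
    )
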