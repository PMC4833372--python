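"""Single-synapse STDP under pre/post oscillations (weak-coupling theory).

Pre- and post-synaptic neurons fire as independent inhomogeneous Poisson
processes with cosine-modulated intensities

    r(t) = D + A * cos(nu*t - phi),        0 <= A <= D,

which induces the pre-post correlation

    Gamma(lag) = Gamma0 * (1 + Gamma_r * cos(nu*lag + phi)),
    Gamma0 = D_pre * D_post,   Gamma_r = (A_pre/D_pre)(A_post/D_post)/2 <= 1/2.

Averaging the STDP rule over this correlation gives the slow ("mean-field")
weight dynamics in rescaled time s = lam * t,

    dw/ds = f_plus(w)  * Gamma0 * (1 + Gamma_r*Kt_plus *cos(Om_plus  - phi))
          - f_minus(w) * Gamma0 * (1 + Gamma_r*Kt_minus*cos(Om_minus - phi)),

whose fixed point is w*(phi) = 1 / ((alpha*Q(phi))**(1/mu) + 1) with

    Q(phi) = (1 + Gamma_r*Kt_minus*cos(Om_minus - phi))
           / (1 + Gamma_r*Kt_plus *cos(Om_plus  - phi)).

The phases where w* crosses 1/2 are independent of mu ("mu-invariant"
crossing phases) and characterise the width of the weight profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .stdp_core import STDPRule, kernel_fourier, weight_dependence, wrap_phase

__all__ = [
    "OscillatoryRate",
    "CorrelationParams",
    "correlation_params",
    "q_ratio",
    "fixed_point_weight",
    "mu_invariant_phases",
    "integrate_single_synapse",
]


@dataclass(frozen=True)
class OscillatoryRate:
    """Cosine-modulated Poisson intensity r(t) = D + A cos(nu t - phi)."""

    D: float  # mean rate, spikes/s
    A: float  # modulation amplitude, spikes/s
    nu: float  # angular frequency, rad/s
    phi: float = 0.0  # phase, rad

    def __post_init__(self):
        if not (0 <= self.A <= self.D):
            raise ValueError("need 0 <= A <= D for a non-negative intensity")

    def __call__(self, t):
        return self.D + self.A * np.cos(self.nu * np.asarray(t) - self.phi)


@dataclass(frozen=True)
class CorrelationParams:
    """Pre-post correlation Gamma0*(1 + Gamma_r*cos(nu*lag + phi))."""

    Gamma0: float
    Gamma_r: float
    phi: float  # relative phase phi_pre - phi_post, wrapped to (-pi, pi]
    nu: float


def correlation_params(pre: OscillatoryRate, post: OscillatoryRate) -> CorrelationParams:
    """Correlation structure of two independent oscillatory Poisson trains."""
    if pre.nu != post.nu:
        raise ValueError("pre and post must oscillate at the same frequency")
    if pre.D <= 0 or post.D <= 0:
        raise ValueError("mean rates must be positive")
    gamma_r = 0.5 * (pre.A / pre.D) * (post.A / post.D)
    return CorrelationParams(
        Gamma0=pre.D * post.D,
        Gamma_r=gamma_r,
        phi=wrap_phase(pre.phi - post.phi),
        nu=pre.nu,
    )


def q_ratio(phi, rule: STDPRule, nu: float, gamma_r: float):
    """Depression-to-potentiation drive ratio Q(phi) at the fixed point."""
    if not 0 <= gamma_r <= 0.5:
        raise ValueError("gamma_r must lie in [0, 1/2]")
    spectrum = kernel_fourier(rule, nu)
    phi = np.asarray(phi, dtype=float)
    num = 1.0 + gamma_r * spectrum.K_tilde_minus * np.cos(spectrum.Omega_minus - phi)
    den = 1.0 + gamma_r * spectrum.K_tilde_plus * np.cos(spectrum.Omega_plus - phi)
    out = num / den
    return float(out) if out.ndim == 0 else out


def fixed_point_weight(phi, rule: STDPRule, nu: float, gamma_r: float):
    """Stationary weight w*(phi) of the slow single-synapse dynamics.

    For ``mu > 0``: w* = 1 / ((alpha*Q)**(1/mu) + 1), continuous in (0, 1).
    For ``mu = 0`` (additive rule) the profile is the indicator of
    ``alpha*Q < 1`` (ties at alpha*Q = 1 map to 1/2).
    """
    q = np.asarray(q_ratio(phi, rule, nu, gamma_r))
    aq = rule.alpha * q
    if rule.mu == 0:
        out = np.where(aq < 1, 1.0, np.where(aq > 1, 0.0, 0.5))
    else:
        out = 1.0 / (aq ** (1.0 / rule.mu) + 1.0)
    return float(out) if out.ndim == 0 else out


def mu_invariant_phases(rule: STDPRule, nu: float, gamma_r: float, n_grid: int = 4096):
    """Phases where the fixed-point profile crosses 1/2, for every ``mu > 0``.

    Solves  alpha*Kt_minus*cos(Om_minus - phi) - Kt_plus*cos(Om_plus - phi)
    = (1 - alpha)/gamma_r  on (-pi, pi] by dense sampling followed by
    bracketed bisection.  Returns a sorted array; empty when the profile
    never crosses 1/2.
    """
    if gamma_r <= 0:
        raise ValueError("gamma_r must be positive")
    spectrum = kernel_fourier(rule, nu)

    def g(phi):
        return (
            rule.alpha * spectrum.K_tilde_minus * np.cos(spectrum.Omega_minus - phi)
            - spectrum.K_tilde_plus * np.cos(spectrum.Omega_plus - phi)
            - (1.0 - rule.alpha) / gamma_r
        )

    # circular grid: the last bracket wraps across the -pi/pi seam
    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    vals = g(grid)
    roots = []
    for i in range(n_grid):
        a, fa = grid[i], vals[i]
        if i + 1 < n_grid:
            b, fb = grid[i + 1], vals[i + 1]
        else:
            b, fb = grid[0] + 2 * np.pi, vals[0]
        if fa == 0.0:
            roots.append(a)
        elif fa * fb < 0:
            try:
                roots.append(brentq(g, a, b, xtol=1e-10))
            except ValueError:
                # root within float rounding of an endpoint (e.g. exactly +-pi)
                roots.append(a if abs(fa) <= abs(fb) else b)
    if not roots:
        return np.empty(0)
    return np.sort(np.unique(wrap_phase(np.array(roots))))


def _drive_coefficients(rule: STDPRule, corr: CorrelationParams):
    spectrum = kernel_fourier(rule, corr.nu)
    c_plus = corr.Gamma0 * (
        1.0 + corr.Gamma_r * spectrum.K_tilde_plus * np.cos(spectrum.Omega_plus - corr.phi)
    )
    c_minus = corr.Gamma0 * (
        1.0 + corr.Gamma_r * spectrum.K_tilde_minus * np.cos(spectrum.Omega_minus - corr.phi)
    )
    return c_plus, c_minus


def integrate_single_synapse(
    rule: STDPRule,
    corr: CorrelationParams,
    w0: float,
    horizon: float,
    n_eval: int = 200,
):
    """Integrate the slow weight ODE in rescaled time ``s = lam * t``.

    Returns ``(s, w)`` arrays with ``w`` clipped to [0, 1].  ``horizon`` is in
    rescaled time units; because Gamma0 multiplies the drive, a horizon of a
    few times 1/Gamma0 suffices for convergence.
    """
    if not 0 <= w0 <= 1:
        raise ValueError("w0 must lie in [0, 1]")
    c_plus, c_minus = _drive_coefficients(rule, corr)

    def rhs(_, y):
        w = min(max(y[0], 0.0), 1.0)
        f_plus, f_minus = weight_dependence(w, rule)
        dw = f_plus * c_plus - f_minus * c_minus
        # freeze outward pushes at the hard bounds (needed for mu = 0)
        if (y[0] >= 1.0 and dw > 0) or (y[0] <= 0.0 and dw < 0):
            return [0.0]
        return [dw]

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        [float(w0)],
        method="RK45",
        t_eval=np.linspace(0.0, horizon, n_eval),
        rtol=1e-9,
        atol=1e-11,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"single-synapse integration failed: {sol.message}")
    return sol.t, np.clip(sol.y[0], 0.0, 1.0)
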