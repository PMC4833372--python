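"""Mean-field dynamics of a ring of plastic synapses onto one post-synaptic cell.

``N`` pre-synaptic neurons fire as independent inhomogeneous Poisson processes
with intensities ``D + A*cos(nu*t - phi_j)`` at evenly spaced ring phases
``phi_j = 2*pi*j/N``; their summed activity is constant in time.  The
post-synaptic cell responds with an effective delay ``d``.  In the limit of a
slow learning rate the synaptic weight profile ``w(phi, t)`` evolves (in
rescaled time ``s = lam*t``) as

    dw(phi)/ds = w_bar * F0(phi) + w_tilde * F1(phi),

    F0 = D**2 * (f_plus(w) - f_minus(w)),
    F1 = (A**2/2) * ( Kt_plus  * f_plus(w)  * cos(phi - Om_plus  - nu*d - psi)
                    - Kt_minus * f_minus(w) * cos(phi - Om_minus - nu*d - psi) ),

where ``(w_bar, w_tilde, psi)`` are the mean, first-Fourier magnitude and
phase ("centre of mass") of the profile.  The homogeneous state
``w_h = 1/(1 + alpha**(1/mu))`` is always stable against uniform fluctuations
(eigenvalue ``m0 < 0`` for ``mu > 0``) but can lose stability against the
first Fourier mode (eigenvalue ``m1``), breaking the ring symmetry
spontaneously; the profile then typically converges to a travelling wave
(limit cycle) whose phase drifts at a constant angular velocity ``V``
proportional to the learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .single_synapse import mu_invariant_phases, q_ratio
from .stdp_core import STDPRule, kernel_fourier, weight_dependence, wrap_phase

__all__ = [
    "RingConfig",
    "OrderParameters",
    "StabilityReport",
    "ZeroDriftResult",
    "MeanFieldTrajectory",
    "ring_phases",
    "order_parameters",
    "meanfield_rhs",
    "integrate_meanfield",
    "homogeneous_fixed_point",
    "stability",
    "zero_drift_profile",
    "additive_zero_drift_residual",
    "estimate_drift",
]

_PSI_FLOOR = 1e-12  # below this w_tilde the phase psi is undefined


@dataclass(frozen=True)
class RingConfig:
    """Ring geometry and input statistics.

    ``N`` pre-synaptic phases ``2*pi*j/N``; mean rate ``D`` and modulation
    ``A`` in spikes/s; angular frequency ``nu`` in rad/s; effective
    post-synaptic response delay ``d`` in seconds.
    """

    N: int
    D: float
    A: float
    nu: float
    d: float

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("need at least two ring phases")
        if not (0 <= self.A <= self.D):
            raise ValueError("need 0 <= A <= D")
        if self.nu < 0 or self.d < 0:
            raise ValueError("nu and d must be non-negative")


def ring_phases(N: int) -> np.ndarray:
    """Evenly spaced ring phases phi_j = 2*pi*j/N, j = 0..N-1."""
    return 2.0 * np.pi * np.arange(N) / N


@dataclass(frozen=True)
class OrderParameters:
    """Mean, first-Fourier magnitude and phase of a weight profile."""

    w_bar: float
    w_tilde: float
    psi: float


@dataclass(frozen=True)
class StabilityReport:
    """Linear stability of the homogeneous state (rates per rescaled time).

    ``m0``/``m1`` are the eigenvalues of the uniform and first-Fourier
    directions; ``mu_c_bound`` is the A**2-driven instability scale
    (A**2/4D**2)*(Kt+ cos(Om+ + nu d) - Kt- cos(Om- + nu d)): the homogeneous
    state destabilises for small enough mu exactly when it is positive.
    """

    w_h: float
    m0: float
    m1: float
    mu_c_bound: float


def order_parameters(profile, prev_psi: float = 0.0) -> OrderParameters:
    """Order parameters (w_bar, w_tilde, psi) of a ring weight profile.

    ``psi`` is defined by ``w_tilde * exp(i*psi) = mean(exp(i*phi) * w(phi))``
    with ``w_tilde >= 0``.  When the first mode vanishes (w_tilde below 1e-12)
    the phase is undefined and ``prev_psi`` (default 0) is returned.
    """
    w = np.asarray(profile, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight profile")
    phases = ring_phases(w.size)
    z = np.mean(np.exp(1j * phases) * w)
    w_tilde = float(abs(z))
    psi = float(wrap_phase(np.angle(z))) if w_tilde >= _PSI_FLOOR else float(prev_psi)
    return OrderParameters(w_bar=float(np.mean(w)), w_tilde=w_tilde, psi=psi)


def meanfield_rhs(profile, rule: STDPRule, ring: RingConfig, *, _spectrum=None, _phases=None):
    """Right-hand side dw/ds of the mean-field dynamics (rescaled time)."""
    w = np.clip(np.asarray(profile, dtype=float), 0.0, 1.0)
    spectrum = _spectrum if _spectrum is not None else kernel_fourier(rule, ring.nu)
    phases = _phases if _phases is not None else ring_phases(w.size)
    op = order_parameters(w)
    f_plus, f_minus = weight_dependence(w, rule)
    F0 = ring.D**2 * (f_plus - f_minus)
    F1 = 0.5 * ring.A**2 * (
        spectrum.K_tilde_plus * f_plus * np.cos(phases - spectrum.Omega_plus - ring.nu * ring.d - op.psi)
        - spectrum.K_tilde_minus * f_minus * np.cos(phases - spectrum.Omega_minus - ring.nu * ring.d - op.psi)
    )
    return op.w_bar * F0 + op.w_tilde * F1


@dataclass
class MeanFieldTrajectory:
    """Recorded mean-field trajectory (times in rescaled units s = lam*t)."""

    t: np.ndarray  # (n_rec,)
    profiles: np.ndarray  # (n_rec, N)
    w_bar: np.ndarray
    w_tilde: np.ndarray
    psi: np.ndarray  # unwrapped-free raw phases in (-pi, pi], psi carried when w_tilde ~ 0

    def physical_time(self, learning_rate: float) -> np.ndarray:
        return self.t / learning_rate


def integrate_meanfield(
    profile0,
    rule: STDPRule,
    ring: RingConfig,
    horizon: float,
    ds: float | None = None,
    clip: bool = True,
    record_every: int = 10,
) -> MeanFieldTrajectory:
    """Integrate the mean-field ring dynamics with fixed-step RK4.

    ``horizon`` and ``ds`` are in rescaled time ``s = lam*t``.  The default
    step resolves the fastest linear rate, which scales as ``D**2``.  With
    ``clip`` set, weights are clipped to [0, 1] after every step (required for
    the additive rule ``mu = 0``, where the flow pushes through the bounds).
    """
    w = np.clip(np.asarray(profile0, dtype=float).copy(), 0.0, 1.0)
    if ds is None:
        ds = 0.05 / ring.D**2
    n_steps = max(1, int(round(horizon / ds)))
    spectrum = kernel_fourier(rule, ring.nu)
    phases = ring_phases(w.size)

    def rhs(x):
        return meanfield_rhs(x, rule, ring, _spectrum=spectrum, _phases=phases)

    rec_t, rec_w = [0.0], [w.copy()]
    for k in range(n_steps):
        k1 = rhs(w)
        k2 = rhs(w + 0.5 * ds * k1)
        k3 = rhs(w + 0.5 * ds * k2)
        k4 = rhs(w + ds * k3)
        w = w + (ds / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(w)):
            raise RuntimeError("mean-field integration produced non-finite weights")
        if clip:
            np.clip(w, 0.0, 1.0, out=w)
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            rec_t.append((k + 1) * ds)
            rec_w.append(w.copy())

    profiles = np.asarray(rec_w)
    w_bar = np.empty(len(rec_t))
    w_tilde = np.empty(len(rec_t))
    psi = np.empty(len(rec_t))
    prev = 0.0
    for i, prof in enumerate(profiles):
        op = order_parameters(prof, prev_psi=prev)
        w_bar[i], w_tilde[i], psi[i] = op.w_bar, op.w_tilde, op.psi
        prev = op.psi
    return MeanFieldTrajectory(np.asarray(rec_t), profiles, w_bar, w_tilde, psi)


def homogeneous_fixed_point(rule: STDPRule) -> float:
    """Non-trivial uniform fixed point w_h = 1/(1 + alpha**(1/mu)).

    Requires ``mu > 0``; for the additive rule the uniform state is degenerate
    (every uniform profile is stationary only when ``alpha = 1``).
    """
    if rule.mu == 0:
        raise ValueError("w_h is undefined for mu = 0 (additive rule)")
    return 1.0 / (1.0 + rule.alpha ** (1.0 / rule.mu))


def stability(rule: STDPRule, ring: RingConfig) -> StabilityReport:
    """Eigenvalues of the homogeneous state for the uniform and first modes.

    Rates are per rescaled time ``s = lam*t`` (multiply by ``lam`` for
    physical time; the ``D**2`` input scale is kept explicit).  Linearising
    the mean-field flow about ``w_h`` gives

        m0 = -D**2 * mu * (1 - w_h)**mu / (1 - w_h)
        m1 = m0 + (A**2/4) * (1 - w_h)**mu
                * (Kt+ cos(Om+ + nu d) - Kt- cos(Om- + nu d))

    For ``mu = 0`` (only meaningful with ``alpha = 1``, where any uniform
    profile is stationary with w_h = 1/2): ``m0 = 0`` and only the A**2 term
    drives ``m1``.
    """
    spectrum = kernel_fourier(rule, ring.nu)
    osc = spectrum.K_tilde_plus * np.cos(spectrum.Omega_plus + ring.nu * ring.d) - (
        spectrum.K_tilde_minus * np.cos(spectrum.Omega_minus + ring.nu * ring.d)
    )
    mu_c_bound = (ring.A**2 / (4.0 * ring.D**2)) * osc
    if rule.mu == 0:
        if rule.alpha != 1.0:
            raise ValueError("for mu = 0 the homogeneous state exists only at alpha = 1")
        w_h, m0 = 0.5, 0.0
        fp = 1.0
    else:
        w_h = homogeneous_fixed_point(rule)
        fp = (1.0 - w_h) ** rule.mu
        m0 = -ring.D**2 * fp * rule.mu / (1.0 - w_h)
    m1 = m0 + 0.25 * ring.A**2 * fp * osc
    return StabilityReport(w_h=w_h, m0=float(m0), m1=float(m1), mu_c_bound=float(mu_c_bound))


@dataclass(frozen=True)
class ZeroDriftResult:
    """Self-consistent stationary (zero-drift) profile diagnostics."""

    W_bar: float
    W_tilde: float
    psi0: float
    residual: float  # last order-parameter update magnitude
    phase_residual: float  # |psi of iterated profile - psi0|; ~0 iff true fixed point
    converged: bool
    n_iter: int


def zero_drift_profile(
    rule: STDPRule,
    ring: RingConfig,
    n_grid: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    damping: float = 0.5,
):
    """Solve the stationary (zero drift) profile self-consistently.

    Iterates the map (W_bar, W_tilde) -> order parameters of the single-synapse
    fixed-point profile driven by a post-synaptic cell with rate ``D*W_bar``,
    modulation ``A*W_tilde`` and phase ``psi0 + nu*d``; the relative
    correlation strength is ``Gamma_r = A**2 * W_tilde / (2 D**2 W_bar)``.
    ``psi0`` is pinned to 0 (U(1) gauge); the iterated profile is rotated back
    and the leftover rotation reported as ``phase_residual`` — it vanishes
    exactly when the travelling-wave velocity is zero, so a large value means
    the parameters do not admit a stationary profile.

    Returns ``(profile, ZeroDriftResult)`` on the grid of ``n_grid`` phases
    (default: ``ring.N``).
    """
    n = int(n_grid or ring.N)
    phases = ring_phases(n)
    psi0 = 0.0
    if ring.A == 0:
        if rule.mu > 0:
            w = np.full(n, homogeneous_fixed_point(rule))
        else:
            w = np.full(n, 0.5 if rule.alpha == 1.0 else (1.0 if rule.alpha < 1 else 0.0))
        op = order_parameters(w)
        return w, ZeroDriftResult(op.w_bar, op.w_tilde, psi0, 0.0, 0.0, True, 0)

    W_bar, W_tilde = 0.5, 0.25
    w = np.full(n, 0.5)
    phase_res = np.pi
    converged = False
    residual = np.inf
    for it in range(1, max_iter + 1):
        gamma_r = min(0.5, ring.A**2 * W_tilde / (2.0 * ring.D**2 * max(W_bar, 1e-12)))
        # chi = phase relative to the post-synaptic oscillation psi0 + nu*d
        chi = phases - psi0 - ring.nu * ring.d
        q = q_ratio(chi, rule, ring.nu, gamma_r)
        aq = rule.alpha * q
        if rule.mu == 0:
            w = np.where(aq < 1, 1.0, np.where(aq > 1, 0.0, 0.5))
        else:
            w = 1.0 / (aq ** (1.0 / rule.mu) + 1.0)
        op = order_parameters(w, prev_psi=psi0)
        phase_res = abs(wrap_phase(op.psi - psi0))
        # rotate the profile's centre of mass back to psi0 = 0 (gauge fixing)
        if op.w_tilde >= _PSI_FLOOR and phase_res > 0:
            shift = int(round(op.psi * n / (2 * np.pi)))
            w = np.roll(w, -shift)
            op = order_parameters(w, prev_psi=psi0)
        new_bar = (1 - damping) * op.w_bar + damping * W_bar
        new_tilde = (1 - damping) * op.w_tilde + damping * W_tilde
        residual = max(abs(new_bar - W_bar), abs(new_tilde - W_tilde))
        W_bar, W_tilde = new_bar, new_tilde
        if residual < tol:
            converged = True
            break
    return w, ZeroDriftResult(
        W_bar=float(W_bar),
        W_tilde=float(W_tilde),
        psi0=psi0,
        residual=float(residual),
        phase_residual=float(phase_res),
        converged=converged,
        n_iter=it,
    )


def additive_zero_drift_residual(rule: STDPRule, ring: RingConfig) -> float:
    """Zero-drift self-consistency residual for the additive rule (mu = 0).

    The additive stationary profile is binary, equal to 1 on the arc between
    the two half-crossing phases; its centre of mass must sit at ``-nu*d``
    relative to the post-synaptic phase.  Returns
    ``wrap(midpoint(arc) + nu*d)`` in radians; 0 iff the zero-drift condition
    holds.  Raises if the profile never crosses 1/2.
    """
    if rule.mu != 0:
        raise ValueError("additive zero-drift residual requires mu = 0")
    # self-consistent Gamma_r for the binary arc (immediate for alpha = 1)
    gamma_r = 0.5 * (ring.A / ring.D) ** 2 * 0.5
    midpoint = None
    for _ in range(100):
        phis = mu_invariant_phases(rule, ring.nu, max(gamma_r, 1e-9))
        if phis.size < 2:
            raise ValueError("no half-crossings: the additive profile does not cross 1/2")
        if phis.size > 2:
            raise ValueError("more than two half-crossings; arc midpoint is ambiguous")
        lo, hi = phis
        mid_in = wrap_phase(0.5 * (lo + hi))
        if rule.alpha * q_ratio(mid_in, rule, ring.nu, max(gamma_r, 1e-9)) >= 1:
            mid_in = wrap_phase(mid_in + np.pi)
            beta = (np.pi - 0.5 * (hi - lo))
        else:
            beta = 0.5 * (hi - lo)
        new_gamma = 0.5 * (ring.A / ring.D) ** 2 * (np.sin(beta) / beta if beta > 0 else 1.0)
        new_gamma = min(0.5, new_gamma)
        midpoint = mid_in
        if abs(new_gamma - gamma_r) < 1e-12:
            break
        gamma_r = new_gamma
    return float(wrap_phase(midpoint + ring.nu * ring.d))


def estimate_drift(t, psi, burn_in: float = 0.5, min_samples: int = 10):
    """Drift velocity of the order-parameter phase by linear fit.

    Unwraps ``psi(t)`` (adding +-2*pi at jumps larger than pi), discards the
    first ``burn_in`` fraction of samples, and fits ``psi = psi0 + V*t`` by
    least squares.  Returns ``(V, stderr)`` in rad per unit of ``t``.
    """
    t = np.asarray(t, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if t.size != psi.size:
        raise ValueError("t and psi must have equal length")
    start = int(np.floor(burn_in * t.size))
    t_fit, psi_fit = t[start:], np.unwrap(psi[start:])
    if t_fit.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples after burn-in, got {t_fit.size}")
    fit = linregress(t_fit, psi_fit)
    return float(fit.slope), float(fit.stderr)
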