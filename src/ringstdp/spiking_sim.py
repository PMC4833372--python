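"""Stochastic spiking simulation: ring Poisson inputs, conductance-based
integrate-and-fire post-synaptic neuron, and online all-pairs STDP.

The simulation discretises time in ``dt = 1 ms`` bins.  Each of the ``N_E``
excitatory inputs fires as a Bernoulli approximation of an inhomogeneous
Poisson process with intensity ``D + A*cos(nu*t - phi_j)`` at ring phase
``phi_j``; ``N_I`` inhibitory inputs fire homogeneously.  Spikes are filtered
by alpha-shaped conductance kernels ``[t]_+ * exp(-t/tau_X)`` (``[t]_+`` in
seconds, scale ``g0_X = g_X_R * S_X``) that drive the membrane

    C_m dV/dt = (V_rest - V)/R_m + g_E (E_E - V) + g_I (E_I - V)

integrated by the Euler method; a spike is emitted and ``V`` reset to
``V_rest`` (no refractory period) when ``V`` crosses ``V_th``.  Every
pre/post spike pair updates the corresponding weight through the STDP rule
(all pairs contribute additively); exponential kernels are accumulated
exactly with low-pass traces, Gaussian kernels with a spike-history buffer.

The post-synaptic response delay ``d`` is *not* a parameter here: it emerges
from the synaptic and membrane dynamics and can be measured with
:func:`measure_effective_delay`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .ring_meanfield import RingConfig, estimate_drift, order_parameters, ring_phases
from .stdp_core import STDPRule, kernel_value, wrap_phase

__all__ = [
    "NeuronParams",
    "SimConfig",
    "MeasurementSeries",
    "generate_input_spikes",
    "generate_homogeneous_spikes",
    "conductance_trace",
    "lif_step",
    "OnlineSTDPState",
    "run_simulation",
    "measure_post_oscillation",
    "measure_effective_delay",
    "sweep",
]


@dataclass(frozen=True)
class NeuronParams:
    """Conductance-based integrate-and-fire parameters (SI units).

    Defaults give a 20 ms membrane time constant, excitatory/inhibitory
    reversal at 0/-70 mV and alpha-synapse time constants of 5 ms.  The
    conductance scales are ``g0_X = g_X_R * S_X`` with ``S_E = 1000/N_E`` and
    ``S_I = 400/N_I``, so the total drive is independent of the input counts.
    """

    C_m: float = 200e-12  # F
    R_m: float = 100e6  # Ohm
    V_rest: float = -70e-3  # V
    E_E: float = 0.0  # V
    E_I: float = -70e-3  # V
    V_th: float = -54e-3  # V
    tau_E: float = 5e-3  # s
    tau_I: float = 5e-3  # s
    g_E_R: float = 30e-9  # S
    g_I_R: float = 50e-9  # S

    def g0_E(self, N_E: int) -> float:
        return self.g_E_R * 1000.0 / N_E

    def g0_I(self, N_I: int) -> float:
        return self.g_I_R * 400.0 / N_I


@dataclass(frozen=True)
class SimConfig:
    """Full spiking-simulation configuration.

    ``record_bin`` sets the order-parameter sampling (default 1 s) and
    ``post_bin`` the post-synaptic rate/phase estimation window (default 60 s).
    ``w0`` may be a scalar or per-synapse array; ``w0_jitter`` adds seeded
    uniform jitter of that half-width to break the ring symmetry explicitly
    (spike noise alone also suffices).
    """

    ring: RingConfig
    rule: STDPRule
    duration: float  # s
    seed: int
    neuron: NeuronParams = field(default_factory=NeuronParams)
    N_I: int = 40
    inhibitory_rate: float = 10.0  # spikes/s, fixed weights w_I = 1, no plasticity
    dt: float = 1e-3  # s
    w0: float | np.ndarray = 0.5
    w0_jitter: float = 0.0
    plasticity: bool = True
    record_bin: float = 1.0  # s
    post_bin: float = 60.0  # s


@dataclass
class MeasurementSeries:
    """Time-binned measurements of one simulation run."""

    t_s: np.ndarray  # order-parameter bin ends (s)
    w_bar: np.ndarray
    w_tilde: np.ndarray
    psi: np.ndarray
    t_post: np.ndarray  # post-rate window centres (s)
    D_post: np.ndarray  # spikes/s
    A_post: np.ndarray  # spikes/s (nan where the window is empty)
    phi_post: np.ndarray  # rad (nan where the window is empty)
    final_weights: np.ndarray
    post_spike_times: np.ndarray  # s
    weight_snapshots: np.ndarray = None  # (n_record_bins, N), at record_bin ends


def generate_input_spikes(ring: RingConfig, dt: float, duration: float, seed) -> np.ndarray:
    """Bernoulli spike raster of the ring inputs, shape ``(N, T)`` uint8.

    Each source ``j`` spikes in bin ``n`` with probability
    ``(D + A*cos(nu*t_n - phi_j)) * dt``; sources use independent seeded
    substreams so the raster of source ``j`` is stable under changes of ``N``.
    Raises if any probability exceeds 1.
    """
    if (ring.D + ring.A) * dt > 1.0:
        raise ValueError(
            f"rate*dt = {(ring.D + ring.A) * dt:.3f} > 1: dt too coarse for a Bernoulli approximation"
        )
    T = int(round(duration / dt))
    t = (np.arange(T) + 0.5) * dt
    phases = ring_phases(ring.N)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(ring.N)
    raster = np.empty((ring.N, T), dtype=np.uint8)
    for j in range(ring.N):
        p = (ring.D + ring.A * np.cos(ring.nu * t - phases[j])) * dt
        rng = np.random.Generator(np.random.PCG64(children[j]))
        raster[j] = rng.random(T) < p
    return raster


def generate_homogeneous_spikes(n_sources: int, rate: float, dt: float, duration: float, seed):
    """Summed spike counts per bin of ``n_sources`` homogeneous Bernoulli
    sources (binomial draw per bin; identical in law to summing the sources)."""
    p = rate * dt
    if p > 1.0:
        raise ValueError("rate*dt > 1")
    T = int(round(duration / dt))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    return rng.binomial(n_sources, p, size=T).astype(np.float64)


def conductance_trace(raster, weights, params: NeuronParams, branch: str, dt: float = 1e-3):
    """Conductance time series from a spike raster by discrete convolution.

    ``g_X(t) = g0_X * sum_i w_i * sum_j k(t - t_ij)`` with the alpha kernel
    ``k(t) = [t]_+ * exp(-t/tau_X)`` ([t]_+ in seconds) truncated at
    ``10*tau_X``.  ``raster`` has shape (n_sources, T); returns a length-T
    array in the units of ``g0_X``.
    """
    if branch not in ("E", "I"):
        raise ValueError("branch must be 'E' or 'I'")
    raster = np.atleast_2d(np.asarray(raster))
    weights = np.broadcast_to(np.asarray(weights, dtype=float), (raster.shape[0],))
    tau = params.tau_E if branch == "E" else params.tau_I
    n_sources = raster.shape[0]
    g0 = params.g0_E(n_sources) if branch == "E" else params.g0_I(n_sources)
    lags = np.arange(int(round(10 * tau / dt)) + 1) * dt
    kernel = lags * np.exp(-lags / tau)
    drive = weights @ raster  # weighted spike counts per bin
    return g0 * np.convolve(drive, kernel)[: raster.shape[1]]


def lif_step(V: float, g_E: float, g_I: float, params: NeuronParams, dt: float = 1e-3):
    """One Euler step of the membrane equation; returns ``(V_new, spiked)``.

    On a threshold crossing the membrane is reset to ``V_rest`` (no
    refractory period) and ``spiked`` is True.
    """
    dV = (dt / params.C_m) * (
        (params.V_rest - V) / params.R_m + g_E * (params.E_E - V) + g_I * (params.E_I - V)
    )
    V_new = V + dV
    if not np.isfinite(V_new):
        raise FloatingPointError("membrane potential diverged")
    if V_new >= params.V_th:
        return params.V_rest, True
    return V_new, False


# ---------------------------------------------------------------------------
# online STDP
# ---------------------------------------------------------------------------


def _fpow(x, mu):
    return 1.0 if mu == 0.0 else x**mu


class OnlineSTDPState:
    """Step-wise online all-pairs STDP accumulator for one post-synaptic cell.

    Call :meth:`step` once per ``dt`` bin with the boolean pre-spike vector
    and the post-spike flag; weights are updated in place and clipped to
    [0, 1] after every event.  Exponential kernels use exact low-pass traces,
    Gaussian kernels a spike-history ring buffer of depth
    ``max(T) + 5*max(tau)``.  Simultaneous (same-bin) pre/post pairs follow
    the kernel at lag zero — nothing for the one-sided exponential family
    (``Theta(0) = 0``), ``K(0)`` for the Gaussian family.

    Within a bin, pre-spike events are processed before the post-spike event;
    each event applies the summed pair contributions with the weight
    dependence evaluated at the weight current at that event.
    """

    def __init__(self, rule: STDPRule, n_synapses: int, dt: float = 1e-3, w0=0.5):
        self.rule = rule
        self.dt = dt
        self.n = n_synapses
        self.w = np.full(n_synapses, np.nan)
        self.w[:] = w0
        if np.any(self.w < 0) or np.any(self.w > 1):
            raise ValueError("initial weights must lie in [0, 1]")
        if rule.family == "exponential":
            tau_pre = rule.tau_plus if rule.H == 1 else rule.tau_minus
            tau_post = rule.tau_minus if rule.H == 1 else rule.tau_plus
            self._dec_pre = np.exp(-dt / tau_pre)
            self._dec_post = np.exp(-dt / tau_post)
            self._inc_pre = 1.0 / tau_pre
            self._inc_post = 1.0 / tau_post
            self._pre_tr = np.zeros(n_synapses)
            self._post_tr = 0.0
        else:
            L = int(np.ceil((max(abs(rule.T_plus), abs(rule.T_minus))
                             + 5.0 * max(rule.tau_plus, rule.tau_minus)) / dt))
            self.L = L
            lags = np.arange(L + 1) * dt
            self._Kp_pos = kernel_value(lags, "plus", rule)
            self._Km_pos = kernel_value(lags, "minus", rule)
            self._Kp_neg = kernel_value(-lags, "plus", rule)
            self._Km_neg = kernel_value(-lags, "minus", rule)
            self._pre_hist = np.zeros((n_synapses, L + 1), dtype=np.uint8)
            self._post_hist = np.zeros(L + 1, dtype=np.uint8)
            self._step_no = 0

    def step(self, pre_spikes, post_spike: bool):
        """Process one time bin; returns the updated weight vector."""
        rule = self.rule
        lam, alpha, mu = rule.learning_rate, rule.alpha, rule.mu
        pre = np.asarray(pre_spikes, dtype=bool)
        if rule.family == "exponential":
            self._pre_tr *= self._dec_pre
            self._post_tr *= self._dec_post
            for i in np.nonzero(pre)[0]:
                if rule.H == 1:
                    self.w[i] -= lam * alpha * _fpow(self.w[i], mu) * self._post_tr
                else:
                    self.w[i] += lam * _fpow(1.0 - self.w[i], mu) * self._post_tr
                self.w[i] = min(1.0, max(0.0, self.w[i]))
            if post_spike:
                for i in range(self.n):
                    if rule.H == 1:
                        self.w[i] += lam * _fpow(1.0 - self.w[i], mu) * self._pre_tr[i]
                    else:
                        self.w[i] -= lam * alpha * _fpow(self.w[i], mu) * self._pre_tr[i]
                    self.w[i] = min(1.0, max(0.0, self.w[i]))
            self._pre_tr[pre] += self._inc_pre
            if post_spike:
                self._post_tr += self._inc_post
        else:
            n, L = self._step_no, self.L
            size = L + 1
            for i in np.nonzero(pre)[0]:
                acc = 0.0
                for ell in range(1, min(L, n) + 1):
                    if self._post_hist[(n - ell) % size]:
                        acc += (_fpow(1.0 - self.w[i], mu) * self._Kp_neg[ell]
                                - alpha * _fpow(self.w[i], mu) * self._Km_neg[ell])
                self.w[i] = min(1.0, max(0.0, self.w[i] + lam * acc))
            if post_spike:
                for i in range(self.n):
                    acc = 0.0
                    if pre[i]:  # simultaneous pair, counted once here
                        acc += (_fpow(1.0 - self.w[i], mu) * self._Kp_pos[0]
                                - alpha * _fpow(self.w[i], mu) * self._Km_pos[0])
                    for ell in range(1, min(L, n) + 1):
                        if self._pre_hist[i, (n - ell) % size]:
                            acc += (_fpow(1.0 - self.w[i], mu) * self._Kp_pos[ell]
                                    - alpha * _fpow(self.w[i], mu) * self._Km_pos[ell])
                    self.w[i] = min(1.0, max(0.0, self.w[i] + lam * acc))
            idx = n % size
            self._pre_hist[:, idx] = pre
            self._post_hist[idx] = 1 if post_spike else 0
            self._step_no += 1
        return self.w


# ---------------------------------------------------------------------------
# compiled simulation core
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sim_core(
    exc_spikes,  # (N, T) uint8
    inh_counts,  # (T,) float64
    post_override,  # (T,) uint8, length 0 -> integrate the neuron
    w,  # (N,) float64, updated in place
    dt,
    Cm, Rm, Vrest, EE, EI, Vth, tauE, tauI, g0E, g0I,
    is_exponential,
    lam, alpha, mu, H,
    tau_p, tau_m,
    L, Kp_pos, Km_pos, Kp_neg, Km_neg,
    record_stride,
):
    N, T = exc_spikes.shape
    use_neuron = post_override.shape[0] == 0
    n_rec = T // record_stride
    w_snap = np.empty((n_rec, N))
    post = np.zeros(T, np.uint8)

    betaE = np.exp(-dt / tauE)
    betaI = np.exp(-dt / tauI)
    sE = np.zeros(N)
    cE = np.zeros(N)
    sI = 0.0
    cI = 0.0
    V = Vrest

    # exponential-family traces
    if H == 1:
        tau_pre_tr, tau_post_tr = tau_p, tau_m
    else:
        tau_pre_tr, tau_post_tr = tau_m, tau_p
    dec_pre = np.exp(-dt / tau_pre_tr)
    dec_post = np.exp(-dt / tau_post_tr)
    inc_pre = 1.0 / tau_pre_tr
    inc_post = 1.0 / tau_post_tr
    pre_tr = np.zeros(N)
    post_tr = 0.0

    # gaussian-family spike history ring buffers
    size = L + 1
    pre_hist = np.zeros((N, size), np.uint8)
    post_hist = np.zeros(size, np.uint8)

    rec = 0
    for n in range(T):
        # conductance recursions (alpha kernel = dt * m * beta**m at lag m bins)
        cEs = 0.0
        for i in range(N):
            cE[i] = betaE * (cE[i] + sE[i])
            sE[i] = betaE * sE[i] + exc_spikes[i, n]
            cEs += w[i] * cE[i]
        cI = betaI * (cI + sI)
        sI = betaI * sI + inh_counts[n]
        gE = g0E * dt * cEs
        gI = g0I * dt * cI

        if use_neuron:
            V = V + (dt / Cm) * ((Vrest - V) / Rm + gE * (EE - V) + gI * (EI - V))
            spiked = V >= Vth
            if spiked:
                V = Vrest
        else:
            spiked = post_override[n] == 1
        if spiked:
            post[n] = 1

        if lam > 0.0:
            if is_exponential:
                post_tr *= dec_post
                for i in range(N):
                    pre_tr[i] *= dec_pre
                for i in range(N):
                    if exc_spikes[i, n]:
                        if H == 1:
                            wi = w[i] - lam * alpha * (w[i] ** mu if mu > 0 else 1.0) * post_tr
                        else:
                            wi = w[i] + lam * ((1.0 - w[i]) ** mu if mu > 0 else 1.0) * post_tr
                        w[i] = min(1.0, max(0.0, wi))
                if spiked:
                    for i in range(N):
                        if H == 1:
                            wi = w[i] + lam * ((1.0 - w[i]) ** mu if mu > 0 else 1.0) * pre_tr[i]
                        else:
                            wi = w[i] - lam * alpha * (w[i] ** mu if mu > 0 else 1.0) * pre_tr[i]
                        w[i] = min(1.0, max(0.0, wi))
                    post_tr += inc_post
                # same-bin pairs are excluded (Theta(0) = 0): traces gain the
                # current bin's spikes only after both events ran
                for i in range(N):
                    if exc_spikes[i, n]:
                        pre_tr[i] += inc_pre
            else:
                lmax = min(L, n)
                for i in range(N):
                    if exc_spikes[i, n]:
                        acc = 0.0
                        fp = (1.0 - w[i]) ** mu if mu > 0 else 1.0
                        fm = alpha * (w[i] ** mu if mu > 0 else 1.0)
                        for ell in range(1, lmax + 1):
                            if post_hist[(n - ell) % size]:
                                acc += fp * Kp_neg[ell] - fm * Km_neg[ell]
                        w[i] = min(1.0, max(0.0, w[i] + lam * acc))
                if spiked:
                    for i in range(N):
                        acc = 0.0
                        fp = (1.0 - w[i]) ** mu if mu > 0 else 1.0
                        fm = alpha * (w[i] ** mu if mu > 0 else 1.0)
                        if exc_spikes[i, n]:
                            acc += fp * Kp_pos[0] - fm * Km_pos[0]
                        for ell in range(1, lmax + 1):
                            if pre_hist[i, (n - ell) % size]:
                                acc += fp * Kp_pos[ell] - fm * Km_pos[ell]
                        w[i] = min(1.0, max(0.0, w[i] + lam * acc))
                idx = n % size
                for i in range(N):
                    pre_hist[i, idx] = exc_spikes[i, n]
                post_hist[idx] = 1 if spiked else 0

        if (n + 1) % record_stride == 0 and rec < n_rec:
            for i in range(N):
                w_snap[rec, i] = w[i]
            rec += 1

    return post, w_snap


def _gaussian_tables(rule: STDPRule, dt: float):
    L = int(np.ceil((max(abs(rule.T_plus), abs(rule.T_minus))
                     + 5.0 * max(rule.tau_plus, rule.tau_minus)) / dt))
    lags = np.arange(L + 1) * dt
    return (
        L,
        kernel_value(lags, "plus", rule),
        kernel_value(lags, "minus", rule),
        kernel_value(-lags, "plus", rule),
        kernel_value(-lags, "minus", rule),
    )


def run_simulation(config: SimConfig, post_override=None, return_raster: bool = False):
    """Run the full spiking loop and return a :class:`MeasurementSeries`.

    Deterministic for a fixed ``config.seed``.  ``post_override`` (a uint8
    per-bin spike vector) replaces the integrate-and-fire neuron with a
    prescribed post-synaptic spike train — the weak-coupling surrogate used
    to compare against single-synapse theory.  With ``return_raster`` the
    excitatory input raster is returned alongside (large!).
    """
    ring, rule, dt = config.ring, config.rule, config.dt
    T = int(round(config.duration / dt))
    ss = np.random.SeedSequence(config.seed)
    exc_ss, inh_ss, jit_ss = ss.spawn(3)

    exc = generate_input_spikes(ring, dt, config.duration, exc_ss)
    inh = generate_homogeneous_spikes(config.N_I, config.inhibitory_rate, dt, config.duration, inh_ss)

    w = np.empty(ring.N)
    w[:] = config.w0
    if config.w0_jitter:
        rng = np.random.Generator(np.random.PCG64(jit_ss))
        w += rng.uniform(-config.w0_jitter, config.w0_jitter, size=ring.N)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("initial weights must lie in [0, 1]")

    if rule.family == "gaussian":
        L, kpp, kmp, kpn, kmn = _gaussian_tables(rule, dt)
        is_exp = False
    else:
        L, kpp, kmp, kpn, kmn = 0, np.zeros(1), np.zeros(1), np.zeros(1), np.zeros(1)
        is_exp = True

    if post_override is None:
        override = np.empty(0, dtype=np.uint8)
    else:
        override = np.asarray(post_override, dtype=np.uint8)
        if override.shape != (T,):
            raise ValueError("post_override must have one entry per time bin")

    p = config.neuron
    record_stride = max(1, int(round(config.record_bin / dt)))
    lam = rule.learning_rate if config.plasticity else 0.0
    post, w_snap = _sim_core(
        exc, inh, override, w, dt,
        p.C_m, p.R_m, p.V_rest, p.E_E, p.E_I, p.V_th, p.tau_E, p.tau_I,
        p.g0_E(ring.N), p.g0_I(config.N_I),
        is_exp, lam, rule.alpha, rule.mu, rule.H,
        rule.tau_plus, rule.tau_minus,
        L, kpp, kmp, kpn, kmn,
        record_stride,
    )

    n_rec = w_snap.shape[0]
    t_s = (np.arange(1, n_rec + 1)) * record_stride * dt
    w_bar = np.empty(n_rec)
    w_tilde = np.empty(n_rec)
    psi = np.empty(n_rec)
    prev = 0.0
    for i in range(n_rec):
        op = order_parameters(w_snap[i], prev_psi=prev)
        w_bar[i], w_tilde[i], psi[i] = op.w_bar, op.w_tilde, op.psi
        prev = op.psi

    spike_times = (np.nonzero(post)[0] + 0.5) * dt
    post_window = min(config.post_bin, config.duration)
    t_post, D_post, A_post, phi_post = measure_post_oscillation(
        spike_times, ring.nu, post_window, config.duration
    )

    series = MeasurementSeries(
        t_s=t_s, w_bar=w_bar, w_tilde=w_tilde, psi=psi,
        t_post=t_post, D_post=D_post, A_post=A_post, phi_post=phi_post,
        final_weights=w, post_spike_times=spike_times, weight_snapshots=w_snap,
    )
    return (series, exc) if return_raster else series


def measure_post_oscillation(spike_times, nu: float, window: float, duration: float):
    """Windowed rate, oscillation amplitude and phase of a spike train.

    Fits ``r(t) = D + A*cos(nu*t - phi)`` per window of length ``window`` by
    projecting the spikes onto ``exp(-i*nu*t)`` (amplitude = 2x the complex
    projection magnitude).  Returns ``(t_centres, D, A, phi)``; empty windows
    are flagged with ``A = phi = nan``.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    n_win = int(np.floor(duration / window + 1e-9))
    if n_win < 1:
        raise ValueError("window longer than the recording")
    t_c = (np.arange(n_win) + 0.5) * window
    D = np.zeros(n_win)
    A = np.full(n_win, np.nan)
    phi = np.full(n_win, np.nan)
    idx = np.floor(spike_times / window).astype(int)
    for k in range(n_win):
        tk = spike_times[idx == k]
        D[k] = tk.size / window
        if tk.size:
            z = 2.0 / window * np.sum(np.exp(-1j * nu * tk))
            A[k] = abs(z)
            phi[k] = wrap_phase(-np.angle(z))
    return t_c, D, A, phi


def measure_effective_delay(
    config: SimConfig, frozen_weights=None, post_override=None
) -> float:
    """Effective post-synaptic response delay ``d`` (seconds).

    Runs the conductance-based neuron with plasticity disabled and weights
    frozen to a profile with a non-zero first Fourier mode (default: the
    binary half-ring profile ``w = 1`` for ``cos(phi) > 0``), measures the
    phase of the weighted modulated input drive and of the post-synaptic
    rate, and returns ``d = wrap(phi_post - phi_input)/nu`` averaged over the
    whole run (at least 60 s recommended).  ``post_override`` substitutes a
    prescribed post spike train for the neuron (e.g. a delayed linear Poisson
    read-out, for which the imposed delay is recovered by construction).
    """
    ring = config.ring
    if frozen_weights is None:
        frozen_weights = (np.cos(ring_phases(ring.N)) > 0).astype(float)
    frozen_weights = np.asarray(frozen_weights, dtype=float)
    op = order_parameters(frozen_weights)
    if op.w_tilde < 1e-9:
        raise ValueError("frozen weight profile has no first Fourier mode; delay undefined")
    cfg = replace(config, plasticity=False, w0=frozen_weights, w0_jitter=0.0)
    series, exc = run_simulation(cfg, post_override=post_override, return_raster=True)

    # phase of the summed modulated synaptic drive sum_j w_j rho_j(t)
    T = exc.shape[1]
    t = (np.arange(T) + 0.5) * cfg.dt
    drive = frozen_weights @ exc
    z_in = np.sum(drive * np.exp(-1j * ring.nu * t))
    phi_in = wrap_phase(-np.angle(z_in))

    spikes = series.post_spike_times
    if spikes.size == 0:
        raise RuntimeError("post-synaptic neuron never fired; cannot measure the delay")
    z_out = np.sum(np.exp(-1j * ring.nu * spikes))
    phi_out = wrap_phase(-np.angle(z_out))
    return float(wrap_phase(phi_out - phi_in) / ring.nu)


def sweep(config: SimConfig, parameter: str, values, burn_in: float = 0.5):
    """Drift velocity across a one-parameter family of simulations.

    ``parameter`` is ``"frequency"`` (values in Hz, rescales ``ring.nu``) or
    ``"T_shift"`` (values in seconds, sets both Gaussian shifts).  For each
    value the full simulation runs, the order-parameter phase ``psi(t)`` is
    unwrapped over the post-burn-in samples and its slope fitted, giving the
    drift velocity ``V`` (rad/s) with its standard error.  Returns
    ``(rows, crossing)`` where ``rows`` is a list of dicts and ``crossing``
    the linearly interpolated zero of ``V`` (None if the sign never changes).
    """
    if parameter not in ("frequency", "T_shift"):
        raise ValueError("parameter must be 'frequency' or 'T_shift'")
    rows = []
    for val in values:
        if parameter == "frequency":
            cfg = replace(config, ring=replace(config.ring, nu=2.0 * np.pi * val))
        else:
            cfg = replace(config, rule=replace(config.rule, T_plus=val, T_minus=val))
        series = run_simulation(cfg)
        V, se = estimate_drift(series.t_s, series.psi, burn_in=burn_in)
        rows.append({"value": float(val), "V": V, "stderr": se,
                     "V_rph": V * 3600.0 / (2.0 * np.pi)})
    crossing = None
    for a, b in zip(rows[:-1], rows[1:]):
        if a["V"] == 0.0:
            crossing = a["value"]
            break
        if a["V"] * b["V"] < 0:
            crossing = a["value"] + (b["value"] - a["value"]) * (
                -a["V"] / (b["V"] - a["V"])
            )
            break
    return rows, crossing
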