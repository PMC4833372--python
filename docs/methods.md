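# Methods

## Model

A single post-synaptic neuron receives feed-forward input from `N` excitatory
synapses whose pre-synaptic neurons fire as independent inhomogeneous Poisson
processes with intensities

    r_j(t) = D + A * cos(nu*t - phi_j),     phi_j = 2*pi*j/N,

i.e. all inputs oscillate at the same frequency with phases evenly spaced on a
ring, so the *summed* input rate is constant in time.  Each synapse is plastic
under a separable STDP rule

    dw = lam * [ f_plus(w) K_plus(dt) - f_minus(w) K_minus(dt) ],
    f_plus(w) = (1-w)^mu,   f_minus(w) = alpha * w^mu,

applied additively to every pre/post spike pair (`dt = t_post - t_pre`).  Two
normalised kernel families are implemented: one-sided exponentials (time
constants `tau_±`, polarity `H = ±1`) and Gaussians with widths `tau_±` and
temporal shifts `T_±` (difference-of-Gaussians / "Mexican hat" rules).

The question the package addresses: under what conditions does this
homogeneous, non-oscillating configuration spontaneously break its ring
symmetry so that the weight profile — and with it the post-synaptic rate —
acquires a phase preference, and what does the weight profile then do?

## Theory layers

1. **Single synapse** (`single_synapse`).  With independent oscillatory pre
   and post trains the pair-rate correlation is
   `Gamma0 * (1 + Gamma_r cos(nu*lag + phi))` with `Gamma0 = D_pre*D_post`
   and `Gamma_r = (A_pre/D_pre)(A_post/D_post)/2 <= 1/2`.  Averaging the STDP
   rule over this correlation (slow-learning limit) gives a one-dimensional
   flow whose fixed point is `w*(phi) = 1/((alpha*Q(phi))^(1/mu) + 1)`,
   with `Q` the ratio of depression to potentiation drives built from the
   kernel Fourier data `(K~_±, Omega_±)` at the oscillation frequency.  The
   phases where `w* = 1/2` are independent of `mu` and are found by a
   4096-point grid scan plus bracketed root refinement (`brentq`, 1e-10 rad);
   the grid is treated circularly so roots at ±pi are not lost, and a root
   landing within float rounding of a grid endpoint falls back to that
   endpoint.

2. **Ring mean field** (`ring_meanfield`).  For the full ring, the
   weight-profile flow in rescaled time `s = lam*t` is
   `dw(phi)/ds = w_bar*F0(phi) + w_tilde*F1(phi)` (see module docstring),
   driven by the order parameters `(w_bar, w_tilde, psi)`.  The uniform state
   `w_h = 1/(1+alpha^(1/mu))` has eigenvalues

       m0 = -D^2 * mu * (1-w_h)^mu / (1-w_h)                    (uniform mode)
       m1 = m0 + (A^2/4)(1-w_h)^mu [K~+ cos(Om+ + nu d) - K~- cos(Om- + nu d)]

   The expression for `m1` is the direct linearisation of the implemented
   flow; it is verified in the tests against finite differences of the
   right-hand side (1e-4 relative) and against log-growth rates of integrated
   trajectories (2%).  Note the first term enters with its full weight: the
   `w_bar*F0` product contributes its pointwise rate to *every* Fourier mode
   because `F0(w_h) = 0` kills the cross term in `delta w_bar`.  The reported
   `mu_c_bound = (A^2/4D^2)[K~+ cos(Om+ + nu d) - K~- cos(Om- + nu d)]` is the
   modulation-driven bracket whose sign decides whether a small-`mu`
   instability exists at all; the critical non-linearity itself is
   `mu_c = (1-w_h) * mu_c_bound`.

   When `m1 > 0` the ring symmetry breaks and the profile generically
   converges to a travelling wave `w(phi,t) = W(phi - V t)`: amplitude
   stationary, centre of mass drifting at constant `V` proportional to `lam`.
   A genuinely stationary profile (`V = 0`) exists only when the
   self-consistency between the profile phase and the post-synaptic phase
   `psi + nu*d` is met; for the additive rule this reduces to
   `midpoint(potentiated arc) + nu*d = 0`, e.g. `nu*d = pi/2` for the
   anti-symmetric exponential kernel and `T = d` for the shifted Mexican hat.
   `zero_drift_profile` solves the general self-consistency by damped fixed-
   point iteration on `(W_bar, W_tilde)` with the gauge `psi0 = 0` (the
   left-over rotation per iteration is reported as `phase_residual`; it
   vanishes exactly at zero drift, so non-convergence of that residual is the
   diagnostic for "these parameters drift").

3. **Spiking simulation** (`spiking_sim`).  Time is discretised at
   `dt = 1 ms`.  Inputs are Bernoulli approximations of the Poisson processes
   (`p = r*dt`, hard error if `p > 1` — silent clipping would bias rates).
   Spikes drive alpha-shaped conductances `g0 * [t]_+ e^{-t/tau}` ([t]_+ in
   seconds; `g0_E = 30 nS * 1000/N_E`, `g0_I = 50 nS * 400/N_I`,
   `tau_E = tau_I = 5 ms`), computed by exact linear recursions equivalent to
   the discrete convolution.  The membrane (200 pF, 100 MOhm, rest/inhibitory
   reversal -70 mV, excitatory reversal 0 mV, threshold -54 mV) is integrated
   with the Euler method and reset to rest on a spike, without a refractory
   period.  STDP runs online over all spike pairs: exponential kernels by
   exact low-pass traces, Gaussian kernels by a spike-history ring buffer of
   depth `max|T| + 5*max(tau)`.  Same-bin pre/post pairs use the kernel at
   lag zero — nothing for the one-sided exponentials (we take `Theta(0) = 0`;
   the rule leaves this open), `K(0)` for Gaussians.  The hot loop is a
   single numba-compiled kernel; a step-wise pure-Python reference
   (`OnlineSTDPState`) implements identical semantics and the tests require
   both to agree with an explicit all-pairs double loop to 1e-12.

   The post-synaptic response delay `d` is *not* a parameter of the
   simulator: it emerges from the synaptic and membrane dynamics and is
   measured (`measure_effective_delay`) as the phase lag between the weighted
   modulated input drive and the post-synaptic rate, divided by `nu`.  The
   mean-field module takes `d` as an explicit input.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `D`, `A` | 10, 10 | spikes/s | input mean rate and modulation (A = D is maximal) |
| `f = nu/2pi` | 10 | Hz | input oscillation frequency |
| `tau_±` | 20 (, 30) | ms | kernel time constants; sensitivity to oscillations dies for `nu*tau >> 1` |
| `alpha` | 1 | – | depression strength; sets profile width and `w_h` |
| `mu` | 0 | – | weight-dependence non-linearity; `mu < mu_c` required for symmetry breaking |
| `lam` | 5e-3 | – | learning rate; drift velocity scales with it, so do weight fluctuations |
| `N_E` | 120–1200 | – | ring size; conductances scale as `1/N_E`, finite-N noise as above |
| `N_I`, inhibitory rate | 40, 10 | –, spikes/s | inhibitory operating point; **sets the emergent delay d** (see below) |
| `dt` | 1 | ms | Euler/Bernoulli step |

The inhibitory sources are homogeneous Poisson with fixed weights
`w_I = 1` and no plasticity.  Their rate is a genuinely free choice (only the
counts and conductance scales are standard); we fixed 10 spikes/s a priori.
The emergent delay depends on it and on `N_E` through the membrane operating
point: measured values range from ~7 ms (weak inhibition, large kicks) to
~11 ms (strong inhibition, mean-driven regime).  At the default it is
8.3–8.6 ms at 29 Hz for `N_E = 200`, and ~9.3–9.6 ms at 10–29 Hz for
`N_E = 120`–1200.

## Study experiments and problem sizes

`experiments.py` packages the three headline measurements, all with
`D = A = 10` sp/s, `mu = 0`, `alpha = 1`, `lam = 5e-3`, and a ring of
`N_E = 200` synapses simulated for 15 minutes per parameter value (drift is
estimated from the second half of each run by unwrapping the order-parameter
phase and fitting a line):

* **Frequency sweep** (anti-symmetric exponential rule, 20–36 Hz): the drift
  velocity changes sign where `nu*d ≈ pi/2`.  With the measured `d ≈ 8.4 ms`
  this predicts ~30 Hz; the simulated crossing sits at ~31–33 Hz.  The ~2–3 Hz
  excess is a reproducible finite-size effect of this reduced configuration:
  the additive rule takes per-pair jumps of order `lam*K ≈ 0.25`, and on a
  200-synapse binary front the resulting shot noise rectifies into a small
  extra drift.  The bias shrinks with `lam` and vanishes at `N_E = 1200`
  (where, in turn, the emergent delay itself is longer, ~9.6 ms, moving the
  crossing to ~25 Hz — the crossing always tracks `1/(4d)` for the delay the
  neuron actually exhibits).
* **Effective delay** at 29 Hz, weights frozen to a binary half-ring, 60 s,
  no STDP.
* **Shift sweep** (Mexican hat, `T` = 0–16 ms at 10 Hz): the drift velocity
  changes sign at `T ≈ d ≈ 9 ms`; this crossing is insensitive to the
  finite-size bias because `dV/dT` is steep.

A fourth experiment (`symmetry_breaking_config`) reproduces the canonical
emergence run: 120 synapses, `alpha = 1.1`, `mu = 0.1`, `lam = 5e-4`, 10 Hz.
The first Fourier mode grows from the noise floor to a sustained plateau
(`w~ ≈ 0.25`) while its phase drifts steadily and the post-synaptic
oscillation amplitude rises well above the Poisson floor.  Note that at these
parameters the idealised mean field gives `m1` slightly *negative*
(≈ −1.3 against `|m0| ≈ 13`): the instability observed in the spiking run is
carried by the causal self-correlation term (each synapse's own spikes help
trigger the post spikes that potentiate it), which is `O(1/N)` and excluded
from the mean-field flow by construction but contributes ≈ +2.6 to every
mode's rate at `N_E = 120`.  For the additive sweeps (`mu = 0`, `m0 = 0`) the
modulation term alone decides, and mean field and simulation agree.

## What the synthetic inputs do and do not emulate

The generator produces exactly the model's assumed statistics: independent
Bernoulli-thinned cosine-modulated Poisson sources with evenly spaced phases,
plus homogeneous inhibition.  Real oscillating populations have shared rate
fluctuations, non-Poisson spiking, heterogeneous rates/phases and conduction
delays; none of these are modelled, so passing tests validate the theory and
its implementation, not the model's biological adequacy.

## Numerical choices

* Phases are wrapped to `(-pi, pi]` everywhere; `psi` is carried forward
  in trajectories when `w~ < 1e-12` (it is undefined there) and reported as 0
  by standalone calls.
* Kernel quadratures truncate support at `|dt - T| <= 40*tau` (the kernel is
  below 1e-17 of its peak there).
* The mean-field integrator is fixed-step RK4 with per-step clipping to
  [0, 1] (default step `0.05/D^2` rescaled units).  A fixed step was chosen
  over an adaptive one because the fastest linear rate is known in advance
  (`~D^2`), the flow is smooth away from the bounds, and clipped (`mu = 0`)
  trajectories stay exactly reproducible.
* Symmetry breaking in deterministic mean-field runs is induced by seeded
  noise (1e-5 to 1e-6) on the initial profile; exact uniformity is an
  invariant manifold.
* The zero-drift iteration damps updates by 0.5 and declares convergence at
  1e-8 on the order parameters.
* Euler at `dt = 1 ms` overestimates nothing relevant here: the effective
  membrane time constant stays >= 10 ms at the default operating point; the
  constant-drive firing period matches the analytic charging time within one
  step (tested).
* All randomness flows from one `SeedSequence`; every input source gets its
  own spawned substream, so rasters are reproducible and stable under
  changes of `N`.  Inhibitory sources are aggregated into one binomial draw
  per bin (identical in law to summing independent Bernoulli sources).

## Known limitations

* Single post-synaptic neuron, feed-forward only; no recurrence, no
  inhibitory plasticity, no triplet/voltage effects.
* The stability analysis covers Fourier modes 0 and 1 only, matching the
  order-parameter description; higher-mode instabilities are out of scope.
* No general travelling-wave boundary-value solver is provided (the
  co-moving-frame equations couple all Fourier modes); the package offers the
  zero-drift solver plus numerical drift measurement instead.
* `m0`/`m1` are reported per unit of rescaled time `lam*t` with the `D^2`
  input scale kept explicit; multiply by `lam` for physical rates.
* Weak coupling is assumed exactly in the single-synapse theory; the spiking
  tests emulate it with a prescribed post train.  At finite `lam` the
  time-averaged weight near the steep part of `w*(phi)` deviates from the
  fixed point (bistable occupancy), which is why the recovery test compares
  the profile in the mean and pointwise only on its plateaus.
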