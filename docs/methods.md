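# Methods

This note records the model equations as implemented, the numerical
choices behind them, what the synthetic inputs emulate, and the known
limitations.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Model

### Membrane and threshold (SLIF)

The stimulus current `I(t)` (μA; cathodic negative) drives a leaky
integrator, `τ dV/dt = −R I − V` with `V(0) = 0`, `R = 1 Ω` and membrane
time constant `τ` (μs).  A trial draws a threshold `θ ~ N(μ, σ)` once; the
crossing time `t₀` is the first time `V(t) > θ`.  For a rectangular
cathodic pulse of level `l` and duration `d` this yields the analytic
input-output function `P = Φ((l[1−e^(−d/τ)] − μ)/σ)`.  Three consequences
are used as oracles throughout: the threshold level is `m = μ/(1−e^(−d/τ))`
(702.6 μA at `d = 40 μs` for the default fiber), the relative spread `σ/μ`
is duration-independent, and the strength-duration function has rheobase
`μ/R` and chronaxie `τ ln 2` (172.2 μs).

### Initiation period and spike time (TLIF)

The action potential is split into three epochs: crossing `t₀`, end of the
initiation period `t₁`, and observed spike `t_spk`.  Two empirical sigmoids
of the *effective threshold* `x = μ + σΦ⁻¹(p)` carry the level dependence:

    lat(p) = a₃ / (1 + exp((x − a₁)/a₂)) + a₄      (mean delay, μs)
    jit(p) = a₃′/ (1 + exp((x − a₁′)/a₂′))          (initiation SD, μs)

Defaults: `lat` (106, 5.14, 368, 472), `jit` (109, 3.24, 136); at `p = 0.5`
these give 682.7 μs and 108.9 μs.  Because `x` equals the membrane-potential
peak needed for probability `p`, the engines evaluate both sigmoids directly
at `V_peak`, avoiding a quantile round trip.

`t₁` is generated causally: with `Y ~ Exp(1)`, it is the unique fixed point
of `t ↦ t₀ + φ + Y·jit(P_TLIF(t))`, where
`P_TLIF(t) = Φ((V_peak(t) − μ)/σ)` is the probability that the peak over
`[0, t]` exceeded threshold, and `φ ≥ 0` is the minimum initiation duration
(0 in the TLIF reading).  `jit(P_TLIF(t))` is non-increasing in `t`, so the
fixed point is unique; it is bracketed by `[t₀+φ, t₀+φ+Y·a₃′]` and located
by bisection to 0.01 μs.  Placing `φ` inside the fixed-point map (rather
than clamping the result from below) makes the waiting-time CDF of `t₁`
exactly

    P_t1(t; s) = 1 − exp(−(t − s − φ)/jit(P_TLIF(t))),   t ≥ s + φ,

which is the closed form the deterministic engine integrates; the
Monte-Carlo trials and the semi-analytic probability therefore describe the
*same* process, and they agree within binomial error at n = 20,000 across
every tested pulse shape.  A clamped `max(t₀+φ, ·)` variant was measured to
bias the simulated firing fraction several binomial standard errors above
the closed form at small `φ` and was rejected on those grounds.

Finally `t_spk = t₀ + X·jit(p) + lat(p)` with `X` standard normal and
`p = P_TLIF(t₁)` evaluated per trial.  Because `t₁` varies between trials,
the ensemble is a mixture slightly wider than any single Gaussian; the
effect is negligible except near saturating levels (see Limitations).

### Cancelation (BLIF)

A spike initiated at `t₀` is canceled if the cumulative charge
`∫_{t₀}^{t} I` becomes strictly positive (net anodic) for some
`t ∈ [t₀, t₁]` — equivalently if `T_Q0(t₀)`, the first net-anodic time,
precedes `t₁`.  Purely cathodic stimuli have `T_Q0 = ∞` and are never
canceled, so monophasic behavior is untouched.  The marginal firing
probability marginalizes the crossing density against spike survival:

    P_BLIF(t) = ∫₀ᵗ P′_TLIF(s) · P_t1(T_Q0(s); s) ds,

computed as per-sample increments of `P_TLIF` times the closed-form
survival factor at the sample's crossing edge.  Threshold searches bracket
and bisect this deterministic quantity; simulation is reserved for response
statistics and cross-validation.

## Numerical choices

- Sampling: 1 μs (1 MHz) throughout; sample `k` occupies `[k, k+1)` μs, so
  rectangular-phase charge is exact and charge-balanced pulses integrate to
  zero within one round-off-guarded quantum (relative tolerance 1e−9).
- Membrane update: exact exponential step
  `V[k+1] = V[k]e^(−dt/τ) + R(−I[k])(1−e^(−dt/τ))`, exact at sample edges
  for piecewise-constant input (verified against the closed-form step and
  decay responses to 0.1%).
- Crossing times are reported on the sample grid (first edge strictly above
  `θ`), which biases the continuous crossing up by ~0.5 μs; at threshold the
  mean crossing latency computes to 39 μs (continuous ~38.5).
- Between sample edges, `V_peak` is interpolated linearly for the fixed
  point, `P_t1` and `P_BLIF`; sub-sample differences are far below every
  tolerance used.
- Probability clipping at 1e−9 before `Φ⁻¹` (capping `x` at `μ ± 6σ`), and a
  0.01 μs floor on `jit` wherever it is a waiting-time scale, keep every
  expression finite as `p → {0, 1}`.
- `P_t1`'s general integral form is also provided, by trapezoidal
  quadrature on a 4× refined grid with a finite-difference hazard
  derivative; it matches the closed form within 1e−3 and serves as its
  independent oracle.
- Integration horizon: stimulus end + 5τ.  The peak and all cancelation
  times are final by then; later initiation-period endings see constant
  hazard and need no trace.
- Threshold search: Brent root-finding on the semi-analytic probability,
  seeded by the analytic cathodic-phase threshold, bracket widened
  automatically; relative tolerance 1e−7 (≪ 0.01 dB).
- Sigmoid fitting: trust-region least squares in the effective-threshold
  coordinate, initialized at `a₁ = μ`, `a₂ = σ`, `a₃ = range(statistic)`,
  `a₄ = min(latency)`; a collapsed height `a₃ ≈ 0` (constant data) is
  reported as a fitting error rather than returned.

## Simulation protocol

Each trial consumes exactly three random variates — `θ` (normal), `Y`
(exponential), `X` (standard normal).  The vectorized ensemble runner draws
each variate from its own child stream of the run seed, so trial `i` is
reproducible independently of the number of trials, and repeated runs with
one configuration are byte-identical.  Problem sizes used by the shipped
analyses: 20,000–30,000 trials per condition for response statistics,
10,000–20,000 for cross-checks — enough to put binomial error near 0.35
percentage points and latency standard errors near 1 μs.

The φ-invariance analysis (monophasic latency at φ = 1 vs 60 μs, five
levels spanning firing probabilities 0.05–0.95) is run *paired*: both φ
settings reuse the same streams per level, so the reported maxima are the
systematic φ effect (~1.6 μs in mean latency, ~2.8 μs in jitter) rather
than sampling noise.

## Synthetic calibration data

`make_synthetic_latency_dataset` emits (probability, mean latency, jitter)
rows from the fiber's own sigmoids, optionally with additive Gaussian
noise.  It emulates the *form* of single-fiber calibration measurements —
a handful of levels spanning the dynamic range, with roughly
level-independent measurement noise — and nothing else: real recordings
add non-Gaussian latency tails, level drift and electrode artifacts.
Passing the fit-recovery tests therefore shows the fitting pipeline is
correct and well-conditioned on clean sigmoidal data, not that it is robust
to every pathology of physiological recordings.

## Design choices in open territory

- dB convention: threshold shifts are `20·log₁₀` of the current ratio, the
  amplitude convention standard in this literature.
- "Biphasic/monophasic threshold difference" compares the cathodic-phase
  amplitude at `p = 0.5` against the threshold of a monophasic pulse whose
  duration equals the cathodic phase.
- Cancelation is triggered by the cumulative charge becoming *positive*;
  anodic-leading stimuli are constructible but anodic current only ever
  hyperpolarizes or cancels — the model does not excite on anodic phases.
- `φ` is relative to the crossing: the initiation period `t₁ − t₀` is never
  shorter than `φ`, implemented through the shifted fixed-point clock
  described above.

## Limitations

- The computed φ → biphasic-threshold-shift map gives 0.97 dB at
  `φ = 1 μs` and 11.53 dB at `φ = 60 μs` (40 μs/phase, zero IPG).  At large
  `φ` the survival factor becomes a hard cutoff (the jitter scale at the
  post-pulse peak underflows to its floor), pinning the threshold at
  `μ/(1−e^(−(2d−φ)/(2τ)))`; the value is insensitive to the discretization
  to within ±0.2 dB.
- Ensemble jitter at near-saturating levels is inflated by a few μs by the
  per-trial probability mixture (trials whose initiation period ends before
  the stimulus does draw their latency at a lower probability).  This makes
  the systematic φ = 1 vs 60 μs jitter difference ~2.8 μs at the
  `p = 0.95` level, concentrated entirely there.
- Mean latency referenced to stimulus *onset* carries each pulse shape's
  crossing-time geometry (up to tens of μs between 20 μs and 80 μs
  cathodic phases).  The shape-invariant quantity is the spike delay
  `t_spk − t₀`, which collapses across shapes at matched firing probability
  to within a few μs; ensemble jitter collapses to within ~5%.
- Relative spread of *biphasic* stimuli is duration-independent in the
  model, unlike real fibers; linear charge integration for cancelation
  cannot produce that variation.
- Single pulses only: no refractoriness, threshold accommodation, pulse
  trains, anodic-phase excitation, or electrode/current-spread geometry.
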