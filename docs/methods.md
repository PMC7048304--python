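# Methods

## Model

A single-compartment conductance-based leaky integrate-and-fire neuron
represents an auditory cortical cell driven by acoustic pulse trains in
the flutter range.  The membrane equation,

    C dV/dt = −g_e(t)(V−E_e) − g_i(t)(V−E_i) − g_rest(V−E_rest)
              − g_sra(t)(V−E_K) + ξ(t),

is integrated by forward Euler at Δt = 0.1 ms; V ≥ V_th records a spike
at the end of the step and resets V to E_rest.  There is no explicit
refractory period beyond the reset (one step at E_rest); the reset
itself plus the decay of the driving conductances provides the
effective refractoriness.  Non-finite voltages abort the integration
with the offending step index.

Each acoustic pulse is converted to 10 excitatory and 10 inhibitory
synaptic conductances, one alpha kernel each.  Kernels are
**peak-normalised**, α(t) = A·(t/τ_s)·e^(1−t/τ_s), so the amplitude
parameters are interpretable as peak conductances in nS and directly
comparable to the 0–6 nS (excitation) / 0–12 nS (inhibition) ranges the
sweeps explore.  Kernel onsets sit at pulse time + 10 ms synaptic delay
+ per-synapse Gaussian jitter (σ = 1 ms); inhibitory kernels lag a
further 5 ms.  Onsets are continuous (not snapped to the sample grid):
each kernel is evaluated analytically at the grid times past its onset,
truncated 15 time constants out, where the tail is < 2×10⁻⁵ of peak.
Conductance traces are therefore exactly additive over events, and the
integration step imposes no divisibility constraint on the delays.

## Fixed and calibrated parameters

| parameter | value | status |
|---|---|---|
| C | 0.25 nF | fixed |
| g_rest | 25 nS (τ_m = 10 ms) | fixed |
| E_e / E_i | 0 / −85 mV | fixed |
| τ_s | 5 ms | fixed |
| synaptic delay / I–E delay | 10 / 5 ms | fixed |
| Δt | 0.1 ms | fixed |
| E_rest / V_th | −65 / −50 mV | chosen (conventional cortical values) |
| σ_noise | 2.785 mV·ms^(−1/2) | calibrated |
| amp_e / amp_i | 3.7 / 7.0 nS | calibrated |

E_rest and V_th are not part of the fixed published set; they are
conventional cortical values and configurable.  Two quantities are then
calibrated against the model's stated operating points, in this order
and independently of any downstream correlation measurement:

1. **Membrane noise.**  ξ(t) is additive Gaussian voltage noise, per
   step N(0, σ_noise²·Δt), i.e. a diffusion of intensity σ_noise in
   mV/√ms (so the statistics are step-size invariant).  σ_noise is set
   by the shipped seeded bisection routine
   (`fluttersim.core_model.calibrate_noise`) so the silent neuron fires
   at ≈ 4 spk/s; the frozen default 2.785 gives 3.9 ± 0.2 spk/s on
   held-out seeds.  Whether the biological noise source is a current or
   a voltage is not constrained by anything we model; only the
   resulting spontaneous rate is.
2. **Synaptic amplitudes.**  With the noise fixed, the default
   amplitudes (amp_e, amp_i) = (3.7, 7.0) nS were chosen so the onset
   response of the canonical parameterisations falls in the 40–60 spk/s
   operating band (measured ≈ 52 spk/s) while keeping the I/E ratio at
   1.89, inside the physiologically reported 1.4–2.0 band.

## Short-term plasticity

Release probability per synapse class follows
τ_p dP/dt = P_0 − P with the multiplicative post-pulse update
P → (1−A_D)·P.  Three conventions required decisions:

- **Pre-update scaling.**  A pulse's conductance is scaled by the
  release probability in effect when it arrives (then depleted) — the
  Tsodyks–Markram-style "spend what is available" convention.
- **Facilitation cap.**  A_D < 0 grows P multiplicatively; P is capped
  at 1 because it is a probability, and facilitated classes start from
  P_0 = 0.5 so conductance amplitudes stay within the same range the
  depression model spans.  P_0 applies **per class**: in the mixed
  model (depressing excitation, facilitating inhibition) excitation
  keeps P_0 = 1 and inhibition uses 0.5.  The alternatives — P_0 = 0.5
  for both classes, or rescaling facilitated amplitudes by 1/P_0 —
  were both examined and produce qualitatively wrong orderings of the
  facilitation-variant examples.
- **Exact inter-event recovery.**  Between pulses the closed form is
  used instead of per-step integration (the release value is
  piecewise-constant per event inside the integrator).  A brute-force
  ODE oracle (solve_ivp at rtol 10⁻¹²) confirms agreement to 10⁻⁹
  relative.

Plasticity is driven by *stimulus events*; spike-frequency adaptation
is driven by *postsynaptic spikes*: g_sra decays by the same
first-order scheme as the membrane (factor 1 − Δt/τ_sra per step) and
increments by Δg_sra at each spike.  τ_sra (default 50 ms) and E_K
(default −85 mV, any hyperpolarising reversal behaves equivalently) are
exposed in the configuration; Δg_sra of 10–50 nS spans weak to strong
adaptation.

## Stimuli

Pulse trains place events at k/rate on the half-open interval
[0, duration): the first pulse sits at onset and an 8 Hz × 500 ms train
has 4 events.  Trials embed the stimulus between 500 ms of pre- and
post-stimulus silence.  Optional per-trial temporal jitter perturbs
every event time by N(0, σ²) (σ in ms), re-sorts and clips into the
stimulus window.  Pure tones are surrogated by a 200 Hz event train —
far above the flutter range — driving the same synaptic machinery,
which yields net onset excitation followed by sustained overlapping
input; pure-tone analyses are qualitative (temporal profile, median
spike time), not rate-exact.  The acoustic shape of individual pulses
is subsumed into the synaptic kernel and not modelled separately.

## Metrics and classification

Vector strength is the mean resultant length of spike phases
2πt/IPI, computed over the stimulus window shifted by the 10 ms
response latency; zero spikes is an explicit error, never VS = 0.
RS = 2·N·VS² with spikes pooled across trials.  Rate responses are
significant when the driven rate exceeds the spontaneous mean + 2 s.d.
(estimated from all pre-stimulus windows) with > 1 spike per stimulus.
Synchrony requires VS > 0.1 and RS > 13.8 at ≥ 3 consecutive rates of
the 8–48 Hz grid.  Monotonicity is the Spearman ρ of mean rate vs
repetition rate over the same grid; the two-sided p-value uses the
t-approximation (accurate at n = 11 for the 0.05 threshold; exact
permutation enumeration of 11! orderings is impractical at sweep
volume).  A flat (constant) rate profile is reported as ρ = 0, p = 1
rather than an undefined rank correlation.

Per-event counts use windows [event + latency, event + latency + IPI),
which tile the stimulus; adaptation strength between events j and k is
1 − rate(k)/rate(j) on trial-averaged counts, so 0 means none and
positive values mean depression (the bare ratio is ambiguous in sign
convention; this transform makes "significantly different from 0" the
natural test).  PSTHs convolve each spike train with a unit-area
Gaussian (σ = 10 ms) and average across trials.

The "monotonicity index" of sweep maps is ρ itself; the average
positive (negative) index of a grid is the mean of ρ over points
classified Sync+ (Sync−) with zeros elsewhere.

## Randomness and reproducibility

One root seed per experiment; per-trial generators are seeded by the
tuple (root, grid indices, trial index), never drawn from a shared
stream, so sweeps are order-independent and embarrassingly parallel.
Within a trial the draw order is fixed: excitatory jitter, inhibitory
jitter, then membrane noise.  Identical seed and parameters give
bit-identical spike times.  The Euler and kernel-summation loops are
optionally numba-compiled; the pure-Python definitions are the source
of truth and the fallback.

## Problem sizes

Default protocols use 10 trials per repetition rate, 11 rates
(8–48 Hz), 500 ms stimuli in 1.5 s trials; population statistics use
medians over 30 independently seeded neurons (100 for the paired
adaptation-ordering test, 10 × 60 s for the spontaneous rate).  Sweep
grids default to A_D steps of 0.05 on [0, 0.5] and τ steps of 0.01 s on
[0.05, 0.2].

## What the synthetic data does and does not show

All spike data are generated by the model itself; no recordings are
involved.  The generator emulates trial-to-trial variability via
membrane noise, per-synapse timing jitter and optional pulse-timing
jitter, but not heterogeneity across real neurons (best-frequency
tuning, level dependence, across-cell parameter spread), adaptation
sources outside the modelled trio (e.g. stimulus-specific adaptation),
or amplitude-modulated stimuli, which this event-driven input scheme
cannot represent.  Passing tests therefore validate the mechanism —
that release-probability dynamics of this form produce the Sync+/Sync−
dichotomy, its robustness, and its pure-tone signature — not any claim
about a particular recorded population.

## Known limitations

- Responses to pure tones exaggerate sustained firing relative to real
  neurons; only the Sync+ > Sync− ordering of median spike time is a
  robust output.
- At high repetition rates, residual lagging inhibition reduces
  per-event spike counts by up to ~30% even without plasticity, so
  "equal spikes per event" holds only approximately in the static
  model.
- The mixed-model example with a static facilitated class sits at an
  effective I/E ≈ 0.95, at the edge of the regime where negative
  monotonicity is attainable; its measured coefficient is near the
  ceiling (ρ ≈ 0.98) rather than the moderate value a weaker-slope
  configuration would give.
- Single neuron only: no NMDA kinetics, no multi-compartment
  morphology, no network interactions.
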