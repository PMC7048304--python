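"""Conductance-based leaky integrate-and-fire neuron with alpha synapses.

Membrane dynamics (forward Euler, step dt):

    C dV/dt = -g_e(t)(V - E_e) - g_i(t)(V - E_i)
              - g_rest(V - E_rest) - g_sra(t)(V - E_K) + noise

A spike is emitted whenever V crosses V_th; V then resets to E_rest.
Each acoustic pulse contributes n_syn excitatory and n_syn inhibitory
alpha-function conductances, delayed by the synaptic input delay,
individually jittered, with inhibition lagging excitation by the I-E
delay.  Kernel amplitudes are scaled by the per-event release
probability supplied by the plasticity layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._engine import _add_alpha_kernels, _euler_loop
from .params import NeuronParams, ParameterError, PlasticityParams
from .plasticity import release_trace_for_train
from .stimuli import StimulusTrain

#: alpha kernels are evaluated over this many time constants past onset;
#: the truncated tail is 15 e^-14 < 2e-5 of the peak.
KERNEL_SUPPORT_TAUS = 15.0


class IntegrationError(RuntimeError):
    """Raised when the membrane integration produces a non-finite voltage."""


def alpha_kernel(t_since_onset, amplitude: float, tau_s: float):
    """Peak-normalised alpha conductance  A * (t/tau) * e^(1 - t/tau).

    Zero at onset, single maximum of ``amplitude`` (nS) at t = tau_s,
    and causal: negative times return 0.  Accepts scalars or arrays.
    """
    if tau_s <= 0:
        raise ParameterError("tau_s must be positive")
    t = np.asarray(t_since_onset, dtype=float)
    x = t / tau_s
    out = np.where(t > 0.0, amplitude * x * np.exp(1.0 - x), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TrialResult:
    """Spikes, state traces and provenance for one simulated trial."""

    spike_times_ms: np.ndarray     # ascending, trial time
    v_trace: np.ndarray            # mV, sampled at dt
    g_e_trace: np.ndarray          # nS
    g_i_trace: np.ndarray          # nS
    release_e: np.ndarray          # per-event release probability, E class
    release_i: np.ndarray          # per-event release probability, I class
    dt_ms: float
    seed: object

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_ms.size)

    def times_ms(self) -> np.ndarray:
        """Sample-time axis for the traces."""
        return np.arange(self.v_trace.size) * self.dt_ms

    def to_json(self, path: str | Path, *, metadata: dict | None = None) -> None:
        """Serialise spike times plus metadata (traces go to CSV separately)."""
        doc = {
            "seed": self.seed if not isinstance(self.seed, np.integer)
            else int(self.seed),
            "dt_ms": self.dt_ms,
            "n_spikes": self.n_spikes,
            "spike_times_ms": [float(t) for t in self.spike_times_ms],
            "release_e": [float(p) for p in self.release_e],
            "release_i": [float(p) for p in self.release_i],
        }
        if metadata:
            doc["metadata"] = metadata
        Path(path).write_text(json.dumps(doc, indent=1))

    def trace_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({
            "time_ms": self.times_ms(),
            "V_mV": self.v_trace,
            "g_e_nS": self.g_e_trace,
            "g_i_nS": self.g_i_trace,
        }).to_csv(path, index=False)


def _n_steps(train: StimulusTrain, dt: float) -> int:
    return int(round(train.total_ms / dt)) + 1


def build_conductance_traces(train: StimulusTrain, params: NeuronParams,
                             release_e: np.ndarray, release_i: np.ndarray,
                             rng: np.random.Generator | int,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Summed synaptic conductance time series for one trial.

    For each acoustic event, ``n_syn`` excitatory kernels are placed at
    event + syn_delay + jitter and ``n_syn`` inhibitory kernels a further
    ie_delay later, each with peak amplitude amp * P_rel(event).  Returns
    (g_e, g_i) sampled at dt over the full pre/stimulus/post window.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    events = train.events_trial_ms()
    if np.asarray(release_e).size != events.size or \
            np.asarray(release_i).size != events.size:
        raise ParameterError("need one release value per event and class")
    if events.size and (events[0] < train.pre_ms - 1e-9
                        or events[-1] >= train.offset_ms):
        raise ParameterError("events fall outside the stimulus window")
    n = _n_steps(train, params.dt)
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    if events.size == 0:
        return g_e, g_i
    support = int(np.ceil(KERNEL_SUPPORT_TAUS * params.tau_s / params.dt))
    base_e = events + params.syn_delay
    base_i = base_e + params.ie_delay

    # one jitter draw per synapse, E class first, then I (fixed order for
    # seed reproducibility)
    jit_e = rng.normal(0.0, params.sigma_jitter, (events.size, params.n_syn)) \
        if params.sigma_jitter > 0 else np.zeros((events.size, params.n_syn))
    jit_i = rng.normal(0.0, params.sigma_jitter, (events.size, params.n_syn)) \
        if params.sigma_jitter > 0 else np.zeros((events.size, params.n_syn))

    onsets_e = (base_e[:, None] + jit_e).ravel()
    onsets_i = (base_i[:, None] + jit_i).ravel()
    amps_e = np.repeat(params.amp_e * np.asarray(release_e, float), params.n_syn)
    amps_i = np.repeat(params.amp_i * np.asarray(release_i, float), params.n_syn)
    _add_alpha_kernels(g_e, onsets_e, amps_e, params.tau_s, params.dt, support)
    _add_alpha_kernels(g_i, onsets_i, amps_i, params.tau_s, params.dt, support)
    return g_e, g_i


def integrate_membrane(g_e: np.ndarray, g_i: np.ndarray, params: NeuronParams,
                       plasticity: PlasticityParams,
                       noise_steps: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Run the Euler loop; returns (spike times ms, membrane trace mV)."""
    n = g_e.size
    v_out = np.empty(n)
    spike_idx = np.empty(n, dtype=np.int64)
    dt = params.dt
    dt_over_c = dt * 1e-3 / params.capacitance  # (ms -> s) x nS x mV / nF = mV
    sfa_decay = 1.0 - dt / plasticity.tau_sra
    n_spikes = _euler_loop(
        g_e, g_i, noise_steps, n, dt, dt_over_c, params.g_rest,
        params.e_exc, params.e_inh, params.e_rest, params.v_thresh,
        plasticity.e_k, plasticity.delta_g_sra, sfa_decay,
        v_out, spike_idx)
    if not np.all(np.isfinite(v_out)):
        bad = int(np.argmin(np.isfinite(v_out)))
        raise IntegrationError(f"non-finite membrane potential at step {bad}")
    return spike_idx[:n_spikes] * dt, v_out


def simulate_trial(stimulus: StimulusTrain, neuron: NeuronParams,
                   plasticity: PlasticityParams | None = None,
                   rng_seed: int | np.random.Generator = 0,
                   ) -> TrialResult:
    """Simulate one trial: stimulus -> conductances -> spikes.

    Fully reproducible from ``rng_seed``: synaptic jitter is drawn first
    (excitatory then inhibitory class), then the per-step membrane noise.
    """
    if plasticity is None:
        plasticity = PlasticityParams.none()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)

    release_e = release_trace_for_train(stimulus.events_ms, plasticity.a_de,
                                        plasticity.tau_pe, plasticity.p0_e)
    release_i = release_trace_for_train(stimulus.events_ms, plasticity.a_di,
                                        plasticity.tau_pi, plasticity.p0_i)
    g_e, g_i = build_conductance_traces(stimulus, neuron, release_e,
                                        release_i, rng)
    n = g_e.size
    noise = rng.normal(0.0, neuron.sigma_noise * np.sqrt(neuron.dt), n) \
        if neuron.sigma_noise > 0 else np.zeros(n)
    spikes, v = integrate_membrane(g_e, g_i, neuron, plasticity, noise)
    return TrialResult(spike_times_ms=spikes, v_trace=v, g_e_trace=g_e,
                       g_i_trace=g_i, release_e=release_e,
                       release_i=release_i, dt_ms=neuron.dt, seed=rng_seed)


def spontaneous_rate(neuron: NeuronParams, duration_s: float = 60.0,
                     rng_seed: int | np.random.Generator = 0,
                     plasticity: PlasticityParams | None = None) -> float:
    """Firing rate (spk/s) over silence: membrane noise is the only drive."""
    if plasticity is None:
        plasticity = PlasticityParams.none()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    n = int(round(duration_s * 1000.0 / neuron.dt)) + 1
    zeros = np.zeros(n)
    noise = rng.normal(0.0, neuron.sigma_noise * np.sqrt(neuron.dt), n)
    spikes, _ = integrate_membrane(zeros, zeros, neuron, plasticity, noise)
    return spikes.size / duration_s


def calibrate_noise(target_hz: float = 4.0, *,
                    neuron: NeuronParams | None = None,
                    duration_s: float = 30.0, n_seeds: int = 4,
                    rng_seed: int = 0, tol_hz: float = 0.05,
                    lo: float = 0.5, hi: float = 12.0,
                    max_iter: int = 30) -> float:
    """Bisect the noise intensity so the silent neuron fires at ``target_hz``.

    The spontaneous rate is monotone in sigma_noise, so bisection on the
    seed-averaged rate converges; the returned value is what the default
    ``NeuronParams.sigma_noise`` was frozen from.
    """
    base = neuron or NeuronParams()

    def mean_rate(sigma: float) -> float:
        p = base.with_(sigma_noise=sigma)
        rates = [spontaneous_rate(p, duration_s, rng_seed=rng_seed + k)
                 for k in range(n_seeds)]
        return float(np.mean(rates))

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = mean_rate(mid)
        if abs(r - target_hz) < tol_hz:
            return mid
        if r < target_hz:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
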