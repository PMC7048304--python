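"""Spike-train statistics and response classification.

A neuron's responses to pulse trains across the flutter range (8-48 Hz)
are summarised by the mean discharge rate, the vector strength (VS) of
spike phases relative to the inter-pulse interval, and its Rayleigh
statistic RS = 2 N VS^2.  A neuron is "Sync" when VS > 0.1 with
RS > 13.8 at three consecutive repetition rates and its rate response is
significant (driven rate more than 2 s.d. above the spontaneous mean,
and more than one spike per stimulus on average).  Monotonicity is the
Spearman rank correlation rho of mean rate against repetition rate:
rho > 0.8 (p < 0.05) is positive monotonic, rho < -0.8 negative, else
non-monotonic.  The combined labels are Sync+/Sync-/SyncNM,
nSync+/nSync-/nSyncNM, or non-responsive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .params import ParameterError
from .stimuli import ANALYSIS_RATES_HZ, StimulusTrain

#: Rayleigh-statistic significance threshold.
RS_THRESHOLD = 13.8
#: Minimum vector strength for the synchrony criterion.
VS_THRESHOLD = 0.1
#: Spearman |rho| threshold for monotonic classification.
RHO_THRESHOLD = 0.8
#: Number of consecutive rates that must pass the synchrony criterion.
N_CONSECUTIVE = 3


class InsufficientSpikesError(ValueError):
    """Raised when a statistic is undefined for an empty spike train."""


def vector_strength(spike_times_ms: np.ndarray, ipi_ms: float,
                    window: tuple[float, float]) -> tuple[float, int]:
    """Mean resultant length of spike phases 2*pi*t/IPI within a window.

    Returns (VS, N).  VS = 1 when every spike sits at the same stimulus
    phase, 0 for phases that cancel.  Undefined for N = 0, which raises
    :class:`InsufficientSpikesError` rather than returning 0.
    """
    if ipi_ms <= 0:
        raise ParameterError("ipi_ms must be positive")
    t = np.asarray(spike_times_ms, dtype=float)
    t = t[(t >= window[0]) & (t < window[1])]
    n = t.size
    if n == 0:
        raise InsufficientSpikesError("no spikes in analysis window")
    phase = 2.0 * np.pi * t / ipi_ms
    vs = np.hypot(np.sin(phase).sum(), np.cos(phase).sum()) / n
    return float(vs), int(n)


def rayleigh_statistic(vs: float, n: int) -> float:
    """RS = 2 N VS^2; RS > 13.8 marks significant phase locking."""
    if n < 1:
        raise ParameterError("n must be at least 1")
    return 2.0 * n * vs * vs


def rate_response_significant(driven_rate: float, spont_mean: float,
                              spont_sd: float,
                              spikes_per_stim: float) -> bool:
    """Driven rate > spontaneous mean + 2 s.d. and > 1 spike per stimulus."""
    sd = max(spont_sd, 0.0)
    return bool(driven_rate > spont_mean + 2.0 * sd and spikes_per_stim > 1.0)


@dataclass(frozen=True)
class RateResponse:
    """Summary statistics of one neuron's response at one repetition rate."""

    rate_hz: float
    mean_rate: float               # spk/s across trials, driven window
    sem_rate: float
    spikes_per_stim: float
    vs: float                      # nan if undefined (no spikes)
    rs: float                      # nan if undefined
    significant: bool


@dataclass(frozen=True)
class ResponseClassification:
    """Per-neuron classification over the flutter range."""

    responses: tuple[RateResponse, ...]
    spont_mean: float
    spont_sd: float
    spearman_rho: float
    spearman_p: float
    label: str

    @property
    def is_sync(self) -> bool:
        return self.label.startswith("Sync")

    @property
    def monotonicity_index(self) -> float:
        """Spearman rho of mean rate vs repetition rate (8-48 Hz)."""
        return self.spearman_rho

    def rates(self) -> np.ndarray:
        return np.array([r.rate_hz for r in self.responses])

    def mean_rates(self) -> np.ndarray:
        return np.array([r.mean_rate for r in self.responses])


def _synchrony_met(responses: list[RateResponse]) -> bool:
    run = 0
    for r in responses:
        ok = np.isfinite(r.vs) and r.vs > VS_THRESHOLD and r.rs > RS_THRESHOLD
        run = run + 1 if ok else 0
        if run >= N_CONSECUTIVE:
            return True
    return False


def classify_neuron(responses: list[RateResponse], spont_mean: float,
                    spont_sd: float) -> ResponseClassification:
    """Apply the synchrony, rate-response and monotonicity decision rules.

    ``responses`` must cover 8-48 Hz in 4-Hz steps.  Monotonicity uses
    the Spearman rank correlation of mean rate against repetition rate
    with the two-sided t-approximation p-value.
    """
    responses = sorted(responses, key=lambda r: r.rate_hz)
    have = [r.rate_hz for r in responses]
    missing = [r for r in ANALYSIS_RATES_HZ if r not in have]
    if missing:
        raise ParameterError(f"missing repetition rates: {missing}")
    responses = [r for r in responses if r.rate_hz in ANALYSIS_RATES_HZ]

    rates = np.array([r.rate_hz for r in responses])
    means = np.array([r.mean_rate for r in responses])
    if np.allclose(means, means[0]):
        rho, p = 0.0, 1.0   # degenerate flat profile: ranks undefined
    else:
        rho, p = stats.spearmanr(rates, means)

    responsive = any(r.significant for r in responses)
    sync = responsive and _synchrony_met(responses)

    if not responsive:
        label = "non-responsive"
    else:
        prefix = "Sync" if sync else "nSync"
        if rho > RHO_THRESHOLD and p < 0.05:
            suffix = "+"
        elif rho < -RHO_THRESHOLD and p < 0.05:
            suffix = "-"
        else:
            suffix = "NM"
        label = prefix + suffix

    return ResponseClassification(
        responses=tuple(responses), spont_mean=float(spont_mean),
        spont_sd=float(spont_sd), spearman_rho=float(rho),
        spearman_p=float(p), label=label)


def per_event_counts(spike_times_ms: np.ndarray, train: StimulusTrain,
                     latency_ms: float = 10.0) -> np.ndarray:
    """Spike count in one IPI-wide window per acoustic event.

    Window j is [event_j + latency, event_j + latency + IPI) in trial
    time; for a periodic train the windows tile the stimulus.
    """
    if latency_ms < 0:
        raise ParameterError("latency_ms must be non-negative")
    t = np.asarray(spike_times_ms, dtype=float)
    starts = train.events_trial_ms() + latency_ms
    counts = np.empty(starts.size, dtype=float)
    for j, s in enumerate(starts):
        counts[j] = np.count_nonzero((t >= s) & (t < s + train.ipi_ms))
    return counts


def adaptation_strength(mean_counts: np.ndarray, from_event: int = 0,
                        to_event: int = 1) -> float:
    """1 - rate(to_event)/rate(from_event) on trial-averaged event counts.

    0 means no adaptation; positive values are depression of the later
    response, negative values facilitation.  Undefined when the
    reference event has zero rate.
    """
    counts = np.asarray(mean_counts, dtype=float)
    ref = counts[from_event]
    if ref <= 0:
        raise InsufficientSpikesError("reference event has zero rate")
    return float(1.0 - counts[to_event] / ref)


@dataclass(frozen=True)
class PSTH:
    """Gaussian-kernel smoothed firing-rate estimate (spk/s)."""

    time_ms: np.ndarray
    rate: np.ndarray
    sigma_ms: float


def psth(spike_trains: list[np.ndarray], sigma_ms: float = 10.0,
         t_max_ms: float | None = None, dt_ms: float = 1.0) -> PSTH:
    """Trial-averaged PSTH: convolve each spike train with a Gaussian kernel.

    Each spike contributes a unit-area Gaussian (s.d. ``sigma_ms``), so
    the per-trial curve integrates to the spike count; the population
    PSTH is the mean across trials, in spk/s.
    """
    if sigma_ms <= 0:
        raise ParameterError("sigma_ms must be positive")
    if t_max_ms is None:
        t_max_ms = max((float(t[-1]) for t in spike_trains
                        if len(t)), default=0.0) + 4 * sigma_ms
    grid = np.arange(0.0, t_max_ms + dt_ms, dt_ms)
    acc = np.zeros_like(grid)
    for t in spike_trains:
        t = np.asarray(t, dtype=float)
        if t.size:
            # unit-area Gaussians in ms -> spk/ms; x1000 for spk/s
            d = grid[:, None] - t[None, :]
            acc += np.exp(-0.5 * (d / sigma_ms) ** 2).sum(axis=1) \
                / (sigma_ms * np.sqrt(2 * np.pi))
    rate = 1000.0 * acc / max(len(spike_trains), 1)
    return PSTH(time_ms=grid, rate=rate, sigma_ms=sigma_ms)


def median_spike_time(spike_times_ms: np.ndarray,
                      stimulus_window: tuple[float, float]) -> float:
    """Median in-window spike time relative to stimulus onset (ms)."""
    t = np.asarray(spike_times_ms, dtype=float)
    t = t[(t >= stimulus_window[0]) & (t < stimulus_window[1])]
    if t.size == 0:
        raise InsufficientSpikesError("no spikes in stimulus window")
    return float(np.median(t) - stimulus_window[0])
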