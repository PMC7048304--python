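"""Acoustic stimulus schedules: periodic pulse trains and pure-tone surrogates.

Stimuli are represented only by their event times; the acoustic waveform
of each pulse is subsumed into the synaptic conductance kernel of the
model neuron.  Repetition rates between 4 and 48 Hz span the perceptual
range of acoustic flutter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .params import ParameterError

#: Repetition rates used throughout: 4-48 Hz in 4-Hz steps.
FLUTTER_RATES_HZ: tuple[int, ...] = tuple(range(4, 49, 4))
#: Rates over which synchrony and monotonicity are evaluated (8-48 Hz).
ANALYSIS_RATES_HZ: tuple[int, ...] = tuple(range(8, 49, 4))


@dataclass(frozen=True)
class StimulusTrain:
    """An ordered schedule of acoustic events.

    ``events_ms`` holds event times relative to stimulus onset, all in
    the half-open interval [0, duration_ms).  The simulated trial spans
    ``pre_ms`` of silence, the stimulus, then ``post_ms`` of silence.
    """

    rate_hz: float
    duration_ms: float
    events_ms: np.ndarray
    pre_ms: float = 500.0
    post_ms: float = 500.0
    jitter_sigma_ms: float = 0.0
    label: str = "pulse_train"

    def __post_init__(self) -> None:
        ev = np.asarray(self.events_ms, dtype=float)
        object.__setattr__(self, "events_ms", ev)
        if ev.ndim != 1:
            raise ParameterError("events_ms must be one-dimensional")
        if np.any(np.diff(ev) < 0):
            raise ParameterError("event times must be ascending")
        if ev.size and (ev[0] < 0 or ev[-1] >= self.duration_ms):
            raise ParameterError("event times must lie in [0, duration_ms)")

    @property
    def ipi_ms(self) -> float:
        """Inter-pulse interval, ms."""
        return 1000.0 / self.rate_hz

    @property
    def onset_ms(self) -> float:
        """Stimulus onset in trial time."""
        return self.pre_ms

    @property
    def offset_ms(self) -> float:
        return self.pre_ms + self.duration_ms

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.duration_ms + self.post_ms

    @property
    def n_events(self) -> int:
        return int(self.events_ms.size)

    def events_trial_ms(self) -> np.ndarray:
        """Event times in trial time (offset by the pre-stimulus silence)."""
        return self.events_ms + self.pre_ms


def make_pulse_train(rate_hz: float, duration_ms: float = 500.0, *,
                     pre_ms: float = 500.0, post_ms: float = 500.0,
                     label: str = "pulse_train") -> StimulusTrain:
    """Periodic pulse train: events at k/rate for k = 0, 1, ... < duration.

    The first pulse sits at stimulus onset and the interval is half-open,
    so a train at ``rate_hz`` r and duration D carries ceil(r*D/1000)
    events; e.g. 8 Hz x 500 ms gives pulses at 0, 125, 250 and 375 ms.
    """
    if rate_hz <= 0:
        raise ParameterError("rate_hz must be positive")
    if duration_ms <= 0:
        raise ParameterError("duration_ms must be positive")
    ipi = 1000.0 / rate_hz
    n = int(np.ceil(rate_hz * duration_ms / 1000.0))
    events = np.arange(n) * ipi
    events = events[events < duration_ms]
    return StimulusTrain(rate_hz=rate_hz, duration_ms=duration_ms,
                         events_ms=events, pre_ms=pre_ms, post_ms=post_ms,
                         label=label)


def apply_temporal_jitter(train: StimulusTrain, sigma_ms: float,
                          rng: np.random.Generator | int) -> StimulusTrain:
    """Perturb each event time by independent Gaussian noise (s.d. sigma_ms).

    Events are re-sorted afterwards and clipped into [0, duration) so the
    schedule remains valid; with sigma_ms = 0 the train is returned
    unchanged.  Reproducible given a seed or Generator.
    """
    if sigma_ms < 0:
        raise ParameterError("sigma_ms must be non-negative")
    if sigma_ms == 0 or train.n_events == 0:
        return train
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    jittered = train.events_ms + rng.normal(0.0, sigma_ms, train.n_events)
    jittered = np.clip(np.sort(jittered), 0.0,
                       np.nextafter(train.duration_ms, 0.0))
    return replace(train, events_ms=jittered, jitter_sigma_ms=sigma_ms)


def make_pure_tone(duration_ms: float = 200.0, effective_rate_hz: float = 200.0,
                   *, pre_ms: float = 500.0,
                   post_ms: float = 500.0) -> StimulusTrain:
    """Pure-tone surrogate: a pulse train far above the flutter range.

    A continuous tone is represented as a dense event train (default
    200 Hz) driving the same synaptic machinery, i.e. a net onset
    excitation followed by sustained, overlapping input for the tone
    duration.
    """
    train = make_pulse_train(effective_rate_hz, duration_ms,
                             pre_ms=pre_ms, post_ms=post_ms)
    return replace(train, label="pure_tone")
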