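"""Simulation protocols, canonical presets, and parameter sweeps.

The unit of work is one "simulated neuron": a fixed parameter set run
through the full stimulus battery (pulse trains at 8-48 Hz, 10 trials
each by default) and summarised by the classification metrics.  Sweeps
repeat that over parameter grids with pre-assigned per-point seeds, so
results are independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import simulate_trial
from .metrics import (RateResponse, ResponseClassification, classify_neuron,
                      per_event_counts, rate_response_significant,
                      rayleigh_statistic, vector_strength)
from .params import NeuronParams, PlasticityParams
from .stimuli import (ANALYSIS_RATES_HZ, StimulusTrain, apply_temporal_jitter,
                      make_pulse_train)

#: Canonical plasticity parameterisations.  The depressing pairs follow
#: the rule that strong depression of excitation with weak depression of
#: inhibition yields a negative rate slope (Sync-) and the converse a
#: positive slope (Sync+); recovery time constants 0.15 s (E) / 0.10 s (I).
PRESETS: dict[str, PlasticityParams] = {
    "sync_plus": PlasticityParams.depression(0.1, 0.4),
    "sync_minus": PlasticityParams.depression(0.4, 0.1),
    # depression of excitation + facilitation of inhibition examples
    "mixed_1": PlasticityParams.mixed(0.1, -0.0),
    "mixed_2": PlasticityParams.mixed(0.1, -0.4),
    "mixed_3": PlasticityParams.mixed(0.3, -0.0),
    "mixed_4": PlasticityParams.mixed(0.3, -0.4),
    # facilitation of both classes examples
    "fac_1": PlasticityParams.facilitation(-0.2, -0.2),
    "fac_2": PlasticityParams.facilitation(-0.0, -0.4),
    # Sync- base model with added spike-frequency adaptation
    "sfa_weak": PlasticityParams.depression(0.4, 0.1, delta_g_sra=10.0),
    "sfa_strong": PlasticityParams.depression(0.4, 0.1, delta_g_sra=50.0),
}


def trial_rng(root_seed: int, *indices: int) -> np.random.Generator:
    """Deterministic per-trial stream: seeded by (root, *grid indices).

    Streams are pre-assigned from the index tuple, never drawn from a
    shared sequential source, so any loop order yields identical trials.
    """
    return np.random.default_rng([int(root_seed) & 0x7FFFFFFF,
                                  *[int(i) for i in indices]])


@dataclass(frozen=True)
class NeuronRun:
    """Spike data and classification for one simulated neuron."""

    neuron: NeuronParams
    plasticity: PlasticityParams
    seed: int
    stimuli: dict[float, StimulusTrain]
    spikes: dict[float, list[np.ndarray]]      # rate -> per-trial trains
    classification: ResponseClassification
    onset_rate: float                          # spk/s, mean over rates/trials

    @property
    def rho(self) -> float:
        return self.classification.spearman_rho

    @property
    def label(self) -> str:
        return self.classification.label


def simulate_neuron(neuron: NeuronParams, plasticity: PlasticityParams,
                    seed: int, *, rates=ANALYSIS_RATES_HZ,
                    n_trials: int = 10, duration_ms: float = 500.0,
                    stimulus_jitter_ms: float = 0.0,
                    latency_ms: float | None = None) -> NeuronRun:
    """Run the full stimulus battery for one parameter set and classify it.

    Per repetition rate, ``n_trials`` independent trials are simulated;
    spontaneous statistics come from the 500 ms pre-stimulus windows of
    every trial.  The driven analysis window is the stimulus period
    shifted by the response latency (default: the synaptic input delay).
    """
    if latency_ms is None:
        latency_ms = neuron.syn_delay
    spikes: dict[float, list[np.ndarray]] = {}
    stimuli: dict[float, StimulusTrain] = {}
    spont_rates: list[float] = []
    onset_rates: list[float] = []
    responses: list[RateResponse] = []

    for ri, rate in enumerate(rates):
        base = make_pulse_train(rate, duration_ms)
        trains: list[np.ndarray] = []
        driven: list[float] = []
        stim_used = base
        for trial in range(n_trials):
            rng = trial_rng(seed, ri, trial)
            stim = apply_temporal_jitter(base, stimulus_jitter_ms, rng) \
                if stimulus_jitter_ms > 0 else base
            stim_used = stim
            res = simulate_trial(stim, neuron, plasticity, rng)
            t = res.spike_times_ms
            trains.append(t)
            pre = stim.pre_ms
            spont_rates.append(
                np.count_nonzero(t < pre) / (pre / 1000.0))
            w0 = pre + latency_ms
            w1 = stim.offset_ms + latency_ms
            driven.append(np.count_nonzero((t >= w0) & (t < w1)))
            onset_rates.append(
                np.count_nonzero((t >= w0) & (t < w0 + stim.ipi_ms))
                / (stim.ipi_ms / 1000.0))
        stimuli[rate] = stim_used
        spikes[rate] = trains

        dur_s = duration_ms / 1000.0
        counts = np.asarray(driven, dtype=float)
        mean_rate = counts.mean() / dur_s
        sem_rate = counts.std(ddof=1) / np.sqrt(len(counts)) / dur_s \
            if len(counts) > 1 else 0.0
        w0 = base.pre_ms + latency_ms
        w1 = base.offset_ms + latency_ms
        pooled = np.concatenate(trains) if trains else np.empty(0)
        try:
            vs, n = vector_strength(pooled, base.ipi_ms, (w0, w1))
            rs = rayleigh_statistic(vs, n)
        except Exception:
            vs, rs = float("nan"), float("nan")
        responses.append(RateResponse(
            rate_hz=float(rate), mean_rate=float(mean_rate),
            sem_rate=float(sem_rate), spikes_per_stim=float(counts.mean()),
            vs=vs, rs=rs, significant=False))

    spont = np.asarray(spont_rates)
    spont_mean, spont_sd = float(spont.mean()), float(spont.std(ddof=1))
    responses = [
        RateResponse(
            rate_hz=r.rate_hz, mean_rate=r.mean_rate, sem_rate=r.sem_rate,
            spikes_per_stim=r.spikes_per_stim, vs=r.vs, rs=r.rs,
            significant=rate_response_significant(
                r.mean_rate, spont_mean, spont_sd, r.spikes_per_stim))
        for r in responses]
    cls = classify_neuron(responses, spont_mean, spont_sd)
    return NeuronRun(neuron=neuron, plasticity=plasticity, seed=int(seed),
                     stimuli=stimuli, spikes=spikes, classification=cls,
                     onset_rate=float(np.mean(onset_rates)))


def population_rho(neuron: NeuronParams, plasticity: PlasticityParams,
                   seeds: range | list[int], **kwargs) -> pd.DataFrame:
    """Classification summary over independent simulated neurons (seeds)."""
    rows = []
    for s in seeds:
        run = simulate_neuron(neuron, plasticity, s, **kwargs)
        rows.append({"seed": int(s), "rho": run.rho,
                     "p": run.classification.spearman_p,
                     "label": run.label, "onset_rate": run.onset_rate})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

def sweep_ei_plane(e_values, i_values, neuron: NeuronParams | None = None,
                   seed: int = 0, *, n_trials: int = 10,
                   rates=ANALYSIS_RATES_HZ) -> pd.DataFrame:
    """Classify the static-synapse model across the (E, I) amplitude plane.

    Plasticity is disabled; each grid point is one simulated neuron.
    Columns include the I/E ratio and whether it falls in the
    biologically plausible 1.4-2.0 band.
    """
    base = neuron or NeuronParams()
    rows = []
    for ei, e in enumerate(e_values):
        for ii, i in enumerate(i_values):
            run = simulate_neuron(base.with_(amp_e=float(e), amp_i=float(i)),
                                  PlasticityParams.none(),
                                  seed * 10007 + ei * 101 + ii,
                                  rates=rates, n_trials=n_trials)
            rows.append({"amp_e": float(e), "amp_i": float(i),
                         "ie_ratio": float(i) / float(e) if e else np.inf,
                         "plausible": bool(e and 1.4 <= i / e <= 2.0),
                         "rho": run.rho, "p": run.classification.spearman_p,
                         "label": run.label, "onset_rate": run.onset_rate})
    return pd.DataFrame(rows)


def _plasticity_grid(mode: str, a_de: float, a_di: float,
                     tau_pe: float, tau_pi: float) -> PlasticityParams:
    ctor = {"depression": PlasticityParams.depression,
            "mixed": PlasticityParams.mixed,
            "facilitation": PlasticityParams.facilitation}[mode]
    return ctor(a_de, a_di, tau_pe=tau_pe, tau_pi=tau_pi)


def sweep_adaptation_plane(ade_values, adi_values, *, tau_pe: float = 0.15,
                           tau_pi: float = 0.10, mode: str = "depression",
                           neuron: NeuronParams | None = None, seed: int = 0,
                           n_trials: int = 10,
                           rates=ANALYSIS_RATES_HZ) -> pd.DataFrame:
    """Monotonicity map over the (A_DE, A_DI) plane at fixed time constants."""
    base = neuron or NeuronParams()
    rows = []
    for ei, a_de in enumerate(ade_values):
        for ii, a_di in enumerate(adi_values):
            plas = _plasticity_grid(mode, float(a_de), float(a_di),
                                    tau_pe, tau_pi)
            run = simulate_neuron(base, plas, seed * 10007 + ei * 101 + ii,
                                  rates=rates, n_trials=n_trials)
            rows.append({"a_de": float(a_de), "a_di": float(a_di),
                         "tau_pe": tau_pe, "tau_pi": tau_pi, "mode": mode,
                         "rho": run.rho, "p": run.classification.spearman_p,
                         "label": run.label, "onset_rate": run.onset_rate})
    return pd.DataFrame(rows)


def sweep_facilitation(mode: str, ade_values, adi_values, *,
                       tau_pe: float = 0.15, tau_pi: float = 0.10,
                       neuron: NeuronParams | None = None, seed: int = 0,
                       n_trials: int = 10) -> pd.DataFrame:
    """Facilitation-variant monotonicity maps.

    ``mode`` is "mixed" (depressing excitation, facilitating inhibition)
    or "facilitation" (both classes facilitating, P_0 = 0.5).
    """
    if mode not in ("mixed", "facilitation"):
        raise ValueError("mode must be 'mixed' or 'facilitation'")
    return sweep_adaptation_plane(ade_values, adi_values, tau_pe=tau_pe,
                                  tau_pi=tau_pi, mode=mode, neuron=neuron,
                                  seed=seed, n_trials=n_trials)


def average_monotonicity(df: pd.DataFrame) -> dict[str, float]:
    """Average positive/negative monotonicity index over a sweep grid.

    The positive index averages rho over grid points classified Sync+
    (zero elsewhere), the negative index over Sync- points.
    """
    pos = np.where(df["label"] == "Sync+", df["rho"], 0.0)
    neg = np.where(df["label"] == "Sync-", df["rho"], 0.0)
    return {"positive": float(np.mean(pos)), "negative": float(np.mean(neg))}


def robustness_suite(*, noise_amplitudes=None, jitter_sigmas=None,
                     e_strengths=None, ie_ratios=None,
                     neuron: NeuronParams | None = None,
                     plasticity_plus: PlasticityParams | None = None,
                     plasticity_minus: PlasticityParams | None = None,
                     seed: int = 0, n_trials: int = 10) -> pd.DataFrame:
    """Monotonicity and synchrony of the canonical neurons under perturbation.

    Sweeps, one axis at a time: membrane-noise intensity, stimulus
    temporal jitter, excitatory amplitude (fixed I/E ratio), and I/E
    ratio (fixed E).  Each row is one simulated neuron for either the
    canonical Sync+ or Sync- parameterisation.
    """
    base = neuron or NeuronParams()
    plas = {"sync_plus": plasticity_plus or PRESETS["sync_plus"],
            "sync_minus": plasticity_minus or PRESETS["sync_minus"]}
    axes: list[tuple[str, float, NeuronParams, float]] = []
    for v in (noise_amplitudes if noise_amplitudes is not None else []):
        axes.append(("noise", float(v), base.with_(sigma_noise=float(v)), 0.0))
    for v in (jitter_sigmas if jitter_sigmas is not None else []):
        axes.append(("jitter", float(v), base, float(v)))
    ratio0 = base.amp_i / base.amp_e
    for v in (e_strengths if e_strengths is not None else []):
        axes.append(("e_strength", float(v),
                     base.with_(amp_e=float(v), amp_i=float(v) * ratio0), 0.0))
    for v in (ie_ratios if ie_ratios is not None else []):
        axes.append(("ie_ratio", float(v),
                     base.with_(amp_i=base.amp_e * float(v)), 0.0))

    rows = []
    for ai, (axis, value, params, jit) in enumerate(axes):
        for pi, (name, p) in enumerate(plas.items()):
            run = simulate_neuron(params, p, seed * 10007 + ai * 11 + pi,
                                  n_trials=n_trials, stimulus_jitter_ms=jit)
            vs48 = run.classification.responses[-1].vs
            rows.append({"axis": axis, "value": value, "preset": name,
                         "rho": run.rho, "p": run.classification.spearman_p,
                         "label": run.label, "vs_48": vs48,
                         "onset_rate": run.onset_rate})
    return pd.DataFrame(rows)


def run_experiment(config_path, out_dir, seed: int = 0) -> pd.DataFrame:
    """Run the configured stimulus battery and write a result bundle.

    Writes, under ``out_dir``: ``classification.csv`` (one row per
    simulated neuron), ``rasters.csv`` (neuron, rate, trial, spike time),
    and ``manifest.json`` with full parameter provenance and seeds.
    Byte-identical outputs for identical config and seed.
    """
    import json
    from pathlib import Path

    from .config import load_config

    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rates = cfg.stimulus["rates_hz"]
    rows, raster_rows = [], []
    for k in range(int(cfg.experiment["n_seeds"])):
        run = simulate_neuron(
            cfg.neuron, cfg.plasticity, seed + k, rates=rates,
            n_trials=int(cfg.experiment["n_trials"]),
            duration_ms=float(cfg.stimulus["duration_ms"]),
            stimulus_jitter_ms=float(cfg.stimulus["jitter_ms"]))
        rows.append({"neuron_id": k, "seed": seed + k, "label": run.label,
                     "rho": run.rho, "p": run.classification.spearman_p,
                     "spont_mean": run.classification.spont_mean,
                     "spont_sd": run.classification.spont_sd,
                     "onset_rate": run.onset_rate})
        for rate, trains in run.spikes.items():
            for trial, t in enumerate(trains):
                for s in t:
                    raster_rows.append((k, float(rate), trial, float(s)))
    table = pd.DataFrame(rows)
    table.to_csv(out / "classification.csv", index=False)
    pd.DataFrame(raster_rows, columns=["neuron_id", "rate_hz", "trial",
                                       "spike_time_ms"]
                 ).to_csv(out / "rasters.csv", index=False)
    manifest = {"seed": int(seed),
                "neuron": cfg.neuron.to_dict(),
                "plasticity": cfg.plasticity.to_dict(),
                "stimulus": cfg.stimulus, "experiment": cfg.experiment}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return table


def adaptation_by_pulse(neuron: NeuronParams, plasticity: PlasticityParams,
                        seeds, *, rate_hz: float = 40.0, n_trials: int = 10,
                        latency_ms: float | None = None) -> pd.DataFrame:
    """Per-seed adaptation strength between early pulses at one rate.

    For each seed, trial-averaged per-event counts at ``rate_hz`` give
    the adaptation strength 1 - rate(k)/rate(1) between the 1st and 2nd
    and the 1st and 3rd pulses.  Seeds whose first-two-pulse firing rate
    falls below the spontaneous rate are excluded (column ``excluded``).
    """
    from .metrics import adaptation_strength
    if latency_ms is None:
        latency_ms = neuron.syn_delay
    train = make_pulse_train(rate_hz, 500.0)
    rows = []
    for s in seeds:
        counts = []
        spont = []
        for trial in range(n_trials):
            rng = trial_rng(s, 0, trial)
            res = simulate_trial(train, neuron, plasticity, rng)
            counts.append(per_event_counts(res.spike_times_ms, train,
                                           latency_ms))
            spont.append(np.count_nonzero(
                res.spike_times_ms < train.pre_ms) / (train.pre_ms / 1000.0))
        mean_counts = np.mean(counts, axis=0)
        early_rate = mean_counts[:2].mean() / (train.ipi_ms / 1000.0)
        excluded = early_rate < np.mean(spont)
        row = {"seed": int(s), "excluded": bool(excluded)}
        try:
            row["adapt_1_2"] = adaptation_strength(mean_counts, 0, 1)
            row["adapt_1_3"] = adaptation_strength(mean_counts, 0, 2)
        except Exception:
            row["adapt_1_2"] = np.nan
            row["adapt_1_3"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
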