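"""YAML configuration for simulations and experiments.

A config file has up to four sections, all optional::

    neuron:            # any NeuronParams field
      amp_e: 4.5
      amp_i: 8.5
    plasticity:
      mode: depression      # none | depression | facilitation | mixed
      a_de: 0.4
      a_di: 0.1
      tau_pe: 0.15
      tau_pi: 0.10
      delta_g_sra: 0.0
    stimulus:
      rates_hz: [8, 12, 16, 20, 24, 28, 32, 36, 40, 44, 48]
      duration_ms: 500
      pre_ms: 500
      post_ms: 500
      jitter_ms: 0.0
    experiment:
      n_trials: 10
      n_seeds: 1

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .params import NeuronParams, ParameterError, PlasticityParams
from .stimuli import ANALYSIS_RATES_HZ


class ConfigError(ValueError):
    """Raised for unknown or inconsistent configuration keys."""


_STIM_DEFAULTS = {"rates_hz": list(ANALYSIS_RATES_HZ), "duration_ms": 500.0,
                  "pre_ms": 500.0, "post_ms": 500.0, "jitter_ms": 0.0}
_EXP_DEFAULTS = {"n_trials": 10, "n_seeds": 1}


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    neuron: NeuronParams
    plasticity: PlasticityParams
    stimulus: dict[str, Any]
    experiment: dict[str, Any]


def _check_keys(section: str, given: dict, allowed) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown keys in [{section}]: {sorted(unknown)}")


def _build_plasticity(spec: dict[str, Any]) -> PlasticityParams:
    spec = dict(spec)
    mode = spec.pop("mode", "none")
    sfa = {k: spec.pop(k) for k in ("delta_g_sra", "tau_sra", "e_k")
           if k in spec}
    if mode == "none":
        _check_keys("plasticity", spec, ())
        return PlasticityParams.none().with_(**sfa)
    allowed = ("a_de", "a_di", "tau_pe", "tau_pi")
    _check_keys("plasticity", spec, allowed)
    ctor = {"depression": PlasticityParams.depression,
            "facilitation": PlasticityParams.facilitation,
            "mixed": PlasticityParams.mixed}.get(mode)
    if ctor is None:
        raise ConfigError(f"unknown plasticity mode {mode!r}")
    try:
        return ctor(**spec).with_(**sfa)
    except (TypeError, ParameterError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    _check_keys("<root>", raw, ("neuron", "plasticity", "stimulus",
                                "experiment"))
    neuron_spec = raw.get("neuron") or {}
    fields = {f.name for f in dataclasses.fields(NeuronParams)}
    _check_keys("neuron", neuron_spec, fields)
    try:
        neuron = NeuronParams(**neuron_spec)
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    plasticity = _build_plasticity(raw.get("plasticity") or {})

    stim = dict(_STIM_DEFAULTS)
    given = raw.get("stimulus") or {}
    _check_keys("stimulus", given, _STIM_DEFAULTS)
    stim.update(given)

    exp = dict(_EXP_DEFAULTS)
    given = raw.get("experiment") or {}
    _check_keys("experiment", given, _EXP_DEFAULTS)
    exp.update(given)
    return ExperimentConfig(neuron=neuron, plasticity=plasticity,
                            stimulus=stim, experiment=exp)
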