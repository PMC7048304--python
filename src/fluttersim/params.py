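"""Parameter containers for the model neuron and its synaptic dynamics.

Internal unit system: time in ms, voltage in mV, conductance in nS,
capacitance in nF.  Recovery time constants of the release-probability
dynamics are the one deliberate exception: they are specified in seconds,
matching the convention of the short-term-plasticity literature
(tau_p of 0.05-0.2 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any


class ParameterError(ValueError):
    """Raised when a model parameter violates its documented range."""


@dataclass(frozen=True)
class NeuronParams:
    """Biophysics of the conductance-based leaky integrate-and-fire neuron.

    Defaults are the fixed single-compartment parameters of the auditory
    cortex E-I model: a 0.25 nF membrane with 25 nS leak (membrane time
    constant 10 ms), AMPA-like excitation reversing at 0 mV and
    GABA_A-like inhibition at -85 mV.  Each acoustic pulse is delivered
    as ``n_syn`` excitatory and ``n_syn`` inhibitory alpha-function
    conductances (peak-normalised, tau_s = 5 ms), delayed by 10 ms from
    the pulse and individually jittered (sigma = 1 ms); inhibition lags
    excitation by a further 5 ms.

    Spike threshold and reset are not part of the published fixed set;
    the defaults E_rest = -65 mV, V_th = -50 mV are conventional cortical
    values, and the synaptic amplitudes ``amp_e``/``amp_i`` were
    calibrated so that the default presets produce onset responses of
    40-60 spk/s (see docs/methods.md).

    ``sigma_noise`` is the intensity of the additive membrane-voltage
    noise in mV/sqrt(ms); each Euler step receives a Gaussian increment
    of s.d. ``sigma_noise * sqrt(dt)``.  The default is calibrated so a
    silent neuron fires spontaneously at ~4 spk/s
    (:func:`fluttersim.core_model.calibrate_noise`).
    """

    capacitance: float = 0.25      # C, nF
    g_rest: float = 25.0           # leak conductance, nS
    e_exc: float = 0.0             # excitatory reversal, mV
    e_inh: float = -85.0           # inhibitory reversal, mV
    e_rest: float = -65.0          # resting / reset potential, mV
    v_thresh: float = -50.0        # spike threshold, mV
    tau_s: float = 5.0             # alpha-function time constant, ms
    syn_delay: float = 10.0        # acoustic pulse -> cortex delay, ms
    ie_delay: float = 5.0          # inhibition lag behind excitation, ms
    dt: float = 0.1                # integration step, ms
    sigma_noise: float = 2.785     # noise intensity, mV/sqrt(ms); see docstring
    amp_e: float = 3.7             # peak conductance per excitatory synapse, nS
    amp_i: float = 7.0             # peak conductance per inhibitory synapse, nS
    n_syn: int = 10                # synapses per class per acoustic pulse
    sigma_jitter: float = 1.0      # per-synapse onset jitter, ms

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise ParameterError("capacitance must be positive")
        if self.g_rest <= 0:
            raise ParameterError("g_rest must be positive")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.tau_s <= 0:
            raise ParameterError("tau_s must be positive")
        if not (self.e_inh < self.e_rest < self.e_exc):
            raise ParameterError("require e_inh < e_rest < e_exc")
        if self.v_thresh <= self.e_rest:
            raise ParameterError("v_thresh must exceed e_rest")
        if self.amp_e < 0 or self.amp_i < 0:
            raise ParameterError("synaptic amplitudes must be non-negative")
        if self.n_syn < 1:
            raise ParameterError("n_syn must be at least 1")
        if self.sigma_jitter < 0 or self.sigma_noise < 0:
            raise ParameterError("noise scales must be non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_rest in ms."""
        return 1000.0 * self.capacitance / self.g_rest

    def with_(self, **kwargs: Any) -> "NeuronParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass(frozen=True)
class PlasticityParams:
    """Short-term plasticity and spike-frequency adaptation settings.

    Release-probability dynamics act per synapse class (excitatory,
    inhibitory).  ``a_de``/``a_di`` are the per-pulse update amplitudes:
    positive values deplete release (depression), negative values
    increase it (facilitation).  ``p0_e``/``p0_i`` are the baselines the
    release probability relaxes to with time constants
    ``tau_pe``/``tau_pi`` (seconds).  Depression runs from a baseline of
    1.0; facilitated classes start from 0.5 so the evoked conductances
    stay in a comparable range.

    Spike-frequency adaptation (SFA) is a spike-triggered potassium-like
    conductance: each postsynaptic spike increments g_sra by
    ``delta_g_sra`` (nS); g_sra relaxes to zero with ``tau_sra`` (ms)
    and pulls the membrane toward ``e_k`` (mV).  ``delta_g_sra = 0``
    disables the mechanism.
    """

    a_de: float = 0.0
    a_di: float = 0.0
    tau_pe: float = 0.15           # s
    tau_pi: float = 0.10           # s
    p0_e: float = 1.0
    p0_i: float = 1.0
    delta_g_sra: float = 0.0       # nS
    tau_sra: float = 50.0          # ms
    e_k: float = -85.0             # mV

    def __post_init__(self) -> None:
        for name, a in (("a_de", self.a_de), ("a_di", self.a_di)):
            if abs(a) > 0.5:
                raise ParameterError(f"{name} must lie in [-0.5, 0.5], got {a}")
        if self.tau_pe <= 0 or self.tau_pi <= 0:
            raise ParameterError("recovery time constants must be positive")
        for name, p0 in (("p0_e", self.p0_e), ("p0_i", self.p0_i)):
            if not (0 < p0 <= 1):
                raise ParameterError(f"{name} must lie in (0, 1], got {p0}")
        if self.delta_g_sra < 0:
            raise ParameterError("delta_g_sra must be non-negative")
        if self.tau_sra <= 0:
            raise ParameterError("tau_sra must be positive")

    @classmethod
    def none(cls) -> "PlasticityParams":
        """Static synapses, no adaptation (the plain E-I model)."""
        return cls()

    @classmethod
    def depression(cls, a_de: float, a_di: float,
                   tau_pe: float = 0.15, tau_pi: float = 0.10,
                   **kwargs: Any) -> "PlasticityParams":
        """Depressing synapses on both classes (P_0 = 1)."""
        if a_de < 0 or a_di < 0:
            raise ParameterError("depression amplitudes must be >= 0")
        return cls(a_de=a_de, a_di=a_di, tau_pe=tau_pe, tau_pi=tau_pi,
                   p0_e=1.0, p0_i=1.0, **kwargs)

    @classmethod
    def facilitation(cls, a_de: float, a_di: float,
                     tau_pe: float = 0.15, tau_pi: float = 0.10,
                     **kwargs: Any) -> "PlasticityParams":
        """Facilitating synapses on both classes (P_0 = 0.5)."""
        if a_de > 0 or a_di > 0:
            raise ParameterError("facilitation amplitudes must be <= 0")
        return cls(a_de=a_de, a_di=a_di, tau_pe=tau_pe, tau_pi=tau_pi,
                   p0_e=0.5, p0_i=0.5, **kwargs)

    @classmethod
    def mixed(cls, a_de: float, a_di: float,
              tau_pe: float = 0.15, tau_pi: float = 0.10,
              **kwargs: Any) -> "PlasticityParams":
        """Depressing excitation (P_0 = 1), facilitating inhibition (P_0 = 0.5).

        ``a_di`` is interpreted on the facilitation branch, so it must be
        <= 0 (a value of -0.0 keeps inhibition static at P_0 = 0.5).
        """
        if a_de < 0:
            raise ParameterError("mixed mode depresses excitation: a_de >= 0")
        if a_di > 0:
            raise ParameterError("mixed mode facilitates inhibition: a_di <= 0")
        return cls(a_de=a_de, a_di=a_di, tau_pe=tau_pe, tau_pi=tau_pi,
                   p0_e=1.0, p0_i=0.5, **kwargs)

    def with_(self, **kwargs: Any) -> "PlasticityParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
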