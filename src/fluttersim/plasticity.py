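"""Short-term synaptic plasticity and spike-frequency adaptation dynamics.

The release probability P_rel of a synapse class is a dynamic scalar.
Between acoustic pulses it relaxes exponentially to its baseline P_0,

    tau_p dP_rel/dt = P_0 - P_rel,

and immediately after each pulse it is updated multiplicatively,

    P_rel -> (1 - A_D) * P_rel,

with A_D > 0 depleting release (depression) and A_D < 0 increasing it
(facilitation, capped at 1).  The conductance amplitude evoked by a
pulse is the static amplitude scaled by the release probability in
effect when the pulse arrives (pre-update: a pulse spends the currently
available resources, then depletes them).

Spike-frequency adaptation is a separate, postsynaptically driven
mechanism: a potassium-like conductance g_sra incremented at each
output spike and decaying as tau_sra dg_sra/dt = -g_sra.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ParameterError


def release_after_pulse(p_rel: float, a_d: float) -> float:
    """Post-pulse update P_rel -> (1 - A_D) P_rel, capped at 1 for facilitation."""
    if abs(a_d) > 0.5:
        raise ParameterError(f"|a_d| must not exceed 0.5, got {a_d}")
    return min(1.0, (1.0 - a_d) * p_rel)


def release_recovery(p_rel: float, elapsed_s: float, tau_p_s: float,
                     p_0: float) -> float:
    """Exact relaxation of P_rel toward P_0 over ``elapsed_s`` seconds."""
    if tau_p_s <= 0:
        raise ParameterError("tau_p_s must be positive")
    if elapsed_s < 0:
        raise ParameterError("elapsed_s must be non-negative")
    return p_0 - (p_0 - p_rel) * math.exp(-elapsed_s / tau_p_s)


def release_trace_for_train(events_ms: np.ndarray, a_d: float, tau_p_s: float,
                            p_0: float) -> np.ndarray:
    """Release probability in effect at each event of a pulse train.

    Starting from P_rel = P_0, alternately applies exact recovery over
    each inter-event interval and the post-pulse update.  The returned
    values are the pre-update probabilities, i.e. the factors scaling
    each event's conductance amplitude.
    """
    events = np.asarray(events_ms, dtype=float)
    if np.any(np.diff(events) < 0):
        raise ParameterError("events must be ascending")
    out = np.empty(events.size)
    p = p_0
    for i in range(events.size):
        if i > 0:
            dt_s = (events[i] - events[i - 1]) / 1000.0
            p = release_recovery(p, dt_s, tau_p_s, p_0)
        out[i] = p
        p = release_after_pulse(p, a_d)
    return out


def steady_state_release(ipi_s: float, a_d: float, tau_p_s: float,
                         p_0: float) -> float:
    """Fixed point of the per-period map p -> P_0 - (P_0 - (1-A_D)p) e^(-IPI/tau).

    For a periodic train the pre-update release probability converges
    geometrically to this value (contraction factor (1-A_D) e^(-IPI/tau)
    when below the facilitation cap).  If the uncapped fixed point
    exceeds 1 the capped dynamics pin the post-update value at 1, so the
    pre-update steady state is the one-period recovery from 1.
    """
    d = math.exp(-ipi_s / tau_p_s)
    k = (1.0 - a_d) * d
    if k < 1.0:
        p_star = p_0 * (1.0 - d) / (1.0 - k)
    else:
        p_star = math.inf
    if a_d < 0 and (1.0 - a_d) * p_star > 1.0:
        # facilitation saturates: post-pulse value capped at 1
        p_star = release_recovery(1.0, ipi_s, tau_p_s, p_0)
    return p_star


def sfa_step(g_sra: float, spiked: bool, delta_g: float, tau_sra_ms: float,
             dt_ms: float) -> float:
    """One integrator step of the adaptation conductance.

    First-order decay by (1 - dt/tau_sra) — the same scheme as the
    membrane integrator — plus the spike-triggered increment.
    """
    if g_sra < 0:
        raise ParameterError("g_sra must be non-negative")
    if tau_sra_ms <= 0 or dt_ms <= 0:
        raise ParameterError("tau_sra_ms and dt_ms must be positive")
    g = g_sra * (1.0 - dt_ms / tau_sra_ms)
    if spiked:
        g += delta_g
    return max(0.0, g)
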