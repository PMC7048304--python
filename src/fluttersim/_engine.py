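"""Numerical kernels for the Euler integrator and conductance assembly.

Compiled with numba when available; the pure-Python definitions are the
single source of truth and are used as a fallback, so results do not
depend on the accelerator being present (up to floating-point identity
of the identical operation sequence).
"""

from __future__ import annotations

import numpy as np


def _euler_loop(g_e, g_i, noise, n_steps, dt_ms, dt_over_c, g_rest,
                e_exc, e_inh, e_rest, v_thresh, e_k, sfa_delta, sfa_decay,
                v_out, spike_idx):
    """Forward-Euler threshold-and-reset integration.

    Per step k:  V += (dt/C) [ -g_e (V-E_e) - g_i (V-E_i)
                               - g_rest (V-E_rest) - g_sra (V-E_K) ] + noise_k
    then g_sra decays; on V >= V_th the spike is recorded at (k+1) dt,
    V resets to E_rest and g_sra += delta_g.  Returns the spike count.
    """
    v = e_rest
    g_sra = 0.0
    n_spikes = 0
    v_out[0] = v
    for k in range(n_steps - 1):
        dv = dt_over_c * (-g_e[k] * (v - e_exc)
                          - g_i[k] * (v - e_inh)
                          - g_rest * (v - e_rest)
                          - g_sra * (v - e_k))
        v = v + dv + noise[k]
        g_sra = g_sra * sfa_decay
        if v >= v_thresh:
            spike_idx[n_spikes] = k + 1
            n_spikes += 1
            v = e_rest
            g_sra = g_sra + sfa_delta
        v_out[k + 1] = v
    return n_spikes


def _add_alpha_kernels(trace, onsets_ms, amps, tau_s, dt_ms, support_steps):
    """Accumulate peak-normalised alpha kernels A (t/tau) e^(1-t/tau).

    Each kernel is evaluated on the sample grid over ``support_steps``
    samples past its onset (the tail beyond is < 2e-5 of peak for the
    default 15-tau support).
    """
    n = trace.shape[0]
    for j in range(onsets_ms.shape[0]):
        t0 = onsets_ms[j]
        a = amps[j]
        k0 = int(np.floor(t0 / dt_ms)) + 1
        if k0 < 0:
            k0 = 0
        k1 = k0 + support_steps
        if k1 > n:
            k1 = n
        for k in range(k0, k1):
            t = k * dt_ms - t0
            if t > 0.0:
                x = t / tau_s
                trace[k] += a * x * np.exp(1.0 - x)


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit

    _euler_loop = njit(cache=True, fastmath=False)(_euler_loop)
    _add_alpha_kernels = njit(cache=True, fastmath=False)(_add_alpha_kernels)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False
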