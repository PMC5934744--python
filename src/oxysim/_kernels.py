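"""Numba-compiled inner loops for the 1-ms-step state updates.

These implement the sequential parts of the model that cannot be
vectorised (spike feedback onto the membrane, spike-triggered terminal
updates, compartment exchange).  Stochastic input is drawn outside the
loops with a seeded numpy Generator, so the kernels are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "membrane_loop",
    "membrane_loop_traces",
    "cck_drive_loop",
    "secretion_loop",
    "plasma_loop",
]


@njit(cache=True)
def membrane_loop(syn_input, dt, f_syn, f_hap, f_ahp, k_hap, k_ahp,
                  v_rest, v_thresh):
    """Integrate the membrane over ``syn_input`` (mV per step).

    Per step: decay V_syn, HAP and AHP; add the synaptic input; fire if
    V = V_rest + V_syn - HAP - AHP exceeds threshold.  Post-spike
    increments take effect from the next step.  Returns a boolean spike
    flag per step.
    """
    n = syn_input.shape[0]
    v_syn = 0.0
    hap = 0.0
    ahp = 0.0
    spikes = np.zeros(n, np.bool_)
    for k in range(n):
        v_syn *= f_syn
        hap *= f_hap
        ahp *= f_ahp
        v_syn += syn_input[k]
        if v_rest + v_syn - hap - ahp > v_thresh:
            spikes[k] = True
            hap += k_hap
            ahp += k_ahp
    return spikes


@njit(cache=True)
def membrane_loop_traces(syn_input, dt, f_syn, f_hap, f_ahp, k_hap, k_ahp,
                         v_rest, v_thresh):
    """As :func:`membrane_loop` but also records V, V_syn, HAP, AHP."""
    n = syn_input.shape[0]
    v_syn = 0.0
    hap = 0.0
    ahp = 0.0
    spikes = np.zeros(n, np.bool_)
    v_tr = np.empty(n)
    vs_tr = np.empty(n)
    hap_tr = np.empty(n)
    ahp_tr = np.empty(n)
    for k in range(n):
        v_syn *= f_syn
        hap *= f_hap
        ahp *= f_ahp
        v_syn += syn_input[k]
        v = v_rest + v_syn - hap - ahp
        if v > v_thresh:
            spikes[k] = True
            hap += k_hap
            ahp += k_ahp
        v_tr[k] = v
        vs_tr[k] = v_syn
        hap_tr[k] = hap
        ahp_tr[k] = ahp
    return spikes, v_tr, vs_tr, hap_tr, ahp_tr


@njit(cache=True)
def cck_drive_loop(n_steps, dt, ramp_rate, start, duration, tau):
    """Extra EPSP rate I_rCCK (Hz) per step.

    During ``start <= t < start + duration`` the rate gains
    ``ramp_rate`` Hz/s; it always decays with time constant ``tau``.
    """
    out = np.zeros(n_steps)
    v = 0.0
    k0 = int(round(start / dt))
    k1 = int(round((start + duration) / dt))
    if k0 >= n_steps:
        return out
    for k in range(k0, n_steps):
        r = ramp_rate if k < k1 else 0.0
        v += dt * (r - v / tau)
        if v < 0.0:
            v = 0.0
        out[k] = v
    return out


@njit(cache=True)
def secretion_loop(spikes, dt, k_b, f_b, b_base, k_c, f_c, k_e, f_e,
                   c_theta, c_n, e_theta, e_n, beta, r_max, p_max,
                   alpha, phi, b0, c0, e0, p0, r0):
    """Terminal dynamics driven by per-step spike flags.

    On a spike, calcium entry is computed from the pre-increment values
    of b, c and e (two inverted Hill inhibitions times ``b + b_base``),
    then the three variables are incremented.  Secretion
    ``s = e**phi * alpha * p`` depletes the releasable pool p, which
    refills from the reserve r at ``beta * r / r_max`` while below
    capacity; transfers are clipped so that mass is conserved.

    Returns (s_series, cumulative_secretion, b, c, e, p, r).
    """
    n = spikes.shape[0]
    b, c, e, p, r = b0, c0, e0, p0, r0
    s_series = np.empty(n)
    cum = 0.0
    for k in range(n):
        b *= f_b
        c *= f_c
        e *= f_e
        if spikes[k]:
            c_inh = 1.0 - c ** c_n / (c ** c_n + c_theta ** c_n)
            e_inh = 1.0 - e ** e_n / (e ** e_n + e_theta ** e_n)
            ca_ent = e_inh * c_inh * (b + b_base)
            b += k_b
            c += k_c * ca_ent
            e += k_e * ca_ent
        s = e ** phi * alpha * p
        release = s * dt
        if release > p:
            release = p
            s = release / dt
        p -= release
        cum += release
        if p < p_max:
            transfer = beta * (r / r_max) * dt
            if transfer > r:
                transfer = r
            if p + transfer > p_max:
                transfer = p_max - p
            p += transfer
            r -= transfer
        s_series[k] = s
    return s_series, cum, b, c, e, p, r


@njit(cache=True)
def plasma_loop(inflow, dt, tau_clr, tau_diff, c_plasma, c_evf, x0, xe0):
    """Two-compartment clearance driven by ``inflow`` (pg/s per step).

    Plasma mass x receives the inflow, is cleared at x/tau_clr and
    exchanges DiffRate/tau_diff with the extravascular mass, where
    DiffRate is the concentration gradient times the mean compartment
    volume.  Returns (x_series, x_evf_series).
    """
    n = inflow.shape[0]
    x = x0
    xe = xe0
    x_series = np.empty(n)
    xe_series = np.empty(n)
    half_vol = (c_plasma + c_evf) / 2.0
    for k in range(n):
        diff = (x / c_plasma - xe / c_evf) * half_vol
        x += dt * (inflow[k] - x / tau_clr - diff / tau_diff)
        xe += dt * (diff / tau_diff)
        if x < 0.0:
            x = 0.0
        if xe < 0.0:
            xe = 0.0
        x_series[k] = x
        xe_series[k] = xe
    return x_series, xe_series
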