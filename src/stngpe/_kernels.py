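"""Compiled (numba) network right-hand side and fixed-step RK4 integrator.

This module mirrors the reference implementation in :mod:`stngpe.model_core`
exactly; the test suite asserts element-wise agreement between the two.
Neuron parameters arrive as flat float64 arrays packed in the order of
:data:`stngpe.params.PARAM_ORDER`; the literal indices below follow that
order.  Synapse parameter arrays follow ``SYN_PARAM_ORDER``:
(alpha, beta, theta_g, Theta_gH, sigma_gH, g_syn, v_syn).

State-vector layout (n cells per population):
v_stn | n_stn | h_stn | r_stn | ca_stn | v_gpe | n_gpe | h_gpe | r_gpe |
ca_gpe | s_stn | s_gpe  -> total 12 n.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["network_rhs_packed", "rk4_integrate"]


@njit(cache=True, fastmath=True)
def _cell_derivs(v, n, h, r, ca, p, i_app, i_syn, i_ext, out, base, stride):
    """Derivatives of one cell written into out[base + k*stride], k=0..4."""
    minf = 1.0 / (1.0 + math.exp(-(v - p[18]) / p[19]))   # theta_m, sigma_m
    ninf = 1.0 / (1.0 + math.exp(-(v - p[22]) / p[23]))   # theta_n, sigma_n
    hinf = 1.0 / (1.0 + math.exp(-(v - p[20]) / p[21]))   # theta_h, sigma_h
    rinf = 1.0 / (1.0 + math.exp(-(v - p[24]) / p[25]))   # theta_r, sigma_r
    ainf = 1.0 / (1.0 + math.exp(-(v - p[26]) / p[27]))   # theta_a, sigma_a
    sinf = 1.0 / (1.0 + math.exp(-(v - p[28]) / p[29]))   # theta_s, sigma_s
    binf = 1.0 / (1.0 + math.exp((r - p[30]) / p[31])) - 1.0 / (
        1.0 + math.exp(-p[30] / p[31])
    )

    i_na = p[1] * minf * minf * minf * h * (v - p[7])
    i_k = p[2] * n * n * n * n * (v - p[8])
    i_l = p[3] * (v - p[9])
    i_ca = p[4] * sinf * sinf * (v - p[10])
    i_t = p[5] * ainf * ainf * ainf * binf * binf * (v - p[10])
    i_ahp = p[6] * (ca / (ca + p[12])) * (v - p[11])

    tau_n = p[32] + p[33] / (1.0 + math.exp(-(v - p[34]) / p[35]))
    tau_h = p[36] + p[37] / (1.0 + math.exp(-(v - p[38]) / p[39]))
    tau_r = p[40] + p[41] / (1.0 + math.exp(-(v - p[42]) / p[43]))

    out[base] = (-i_na - i_k - i_l - i_ca - i_t - i_ahp + i_app - i_syn + i_ext) / p[0]
    out[base + stride] = p[15] * (ninf - n) / tau_n
    out[base + 2 * stride] = p[16] * (hinf - h) / tau_h
    out[base + 3 * stride] = p[17] * (rinf - r) / tau_r
    out[base + 4 * stride] = p[13] * (-i_ca - i_t - p[14] * ca)


@njit(cache=True, fastmath=True)
def network_rhs_packed(y, i_ext, p_stn, p_gpe, syn_sg, syn_gs, ia_stn, ia_gpe, dy):
    """Full network derivative; ring topology GPe i -> STN i-1, i, i+1.

    ``ia_stn`` / ``ia_gpe`` are the per-cell applied currents (the
    population I_app plus any configured jitter realization).
    """
    n = y.shape[0] // 12
    g_gs, v_gs = syn_gs[5], syn_gs[6]
    g_sg, v_sg = syn_sg[5], syn_sg[6]
    for i in range(n):
        gates = (
            y[11 * n + (i - 1) % n] + y[11 * n + i] + y[11 * n + (i + 1) % n]
        )
        i_syn = g_gs * (y[i] - v_gs) * gates
        _cell_derivs(
            y[i], y[n + i], y[2 * n + i], y[3 * n + i], y[4 * n + i],
            p_stn, ia_stn[i], i_syn, i_ext, dy, i, n,
        )
    for i in range(n):
        i_syn = g_sg * (y[5 * n + i] - v_sg) * y[10 * n + i]
        _cell_derivs(
            y[5 * n + i], y[6 * n + i], y[7 * n + i], y[8 * n + i], y[9 * n + i],
            p_gpe, ia_gpe[i], i_syn, 0.0, dy, 5 * n + i, n,
        )
    # output synaptic gates: one per presynaptic cell
    for i in range(n):
        v_pre = y[i]
        hval = 1.0 / (1.0 + math.exp(-(v_pre - syn_sg[2] - syn_sg[3]) / syn_sg[4]))
        s = y[10 * n + i]
        dy[10 * n + i] = syn_sg[0] * hval * (1.0 - s) - syn_sg[1] * s
    for i in range(n):
        v_pre = y[5 * n + i]
        hval = 1.0 / (1.0 + math.exp(-(v_pre - syn_gs[2] - syn_gs[3]) / syn_gs[4]))
        s = y[11 * n + i]
        dy[11 * n + i] = syn_gs[0] * hval * (1.0 - s) - syn_gs[1] * s


@njit(cache=True, fastmath=True)
def rk4_integrate(
    y0, dt, n_steps, i_half,
    p_stn, p_gpe, syn_sg, syn_gs, ia_stn, ia_gpe,
    rec_v_stn, rec_v_gpe, rec_r_stn, rec_ca_stn, rec_s_stn, rec_s_gpe,
):
    """Classical RK4 with fixed step ``dt``.

    ``i_half`` holds the external STN current on the half-step grid
    (2 n_steps + 1 values).  State traces are recorded at every step into
    the pre-allocated (n_steps+1, n) arrays.  Returns -1 on success or
    the index of the first step producing a non-finite state.
    """
    dim = y0.shape[0]
    n = dim // 12
    y = y0.copy()
    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    yt = np.empty(dim)

    for i in range(n):
        rec_v_stn[0, i] = y[i]
        rec_v_gpe[0, i] = y[5 * n + i]
        rec_r_stn[0, i] = y[3 * n + i]
        rec_ca_stn[0, i] = y[4 * n + i]
        rec_s_stn[0, i] = y[10 * n + i]
        rec_s_gpe[0, i] = y[11 * n + i]

    for step in range(n_steps):
        i0 = i_half[2 * step]
        im = i_half[2 * step + 1]
        i1 = i_half[2 * step + 2]

        network_rhs_packed(y, i0, p_stn, p_gpe, syn_sg, syn_gs, ia_stn, ia_gpe, k1)
        for j in range(dim):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        network_rhs_packed(yt, im, p_stn, p_gpe, syn_sg, syn_gs, ia_stn, ia_gpe, k2)
        for j in range(dim):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        network_rhs_packed(yt, im, p_stn, p_gpe, syn_sg, syn_gs, ia_stn, ia_gpe, k3)
        for j in range(dim):
            yt[j] = y[j] + dt * k3[j]
        network_rhs_packed(yt, i1, p_stn, p_gpe, syn_sg, syn_gs, ia_stn, ia_gpe, k4)

        ok = True
        for j in range(dim):
            y[j] = y[j] + (dt / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if not math.isfinite(y[j]):
                ok = False
        if not ok:
            return step

        row = step + 1
        for i in range(n):
            rec_v_stn[row, i] = y[i]
            rec_v_gpe[row, i] = y[5 * n + i]
            rec_r_stn[row, i] = y[3 * n + i]
            rec_ca_stn[row, i] = y[4 * n + i]
            rec_s_stn[row, i] = y[10 * n + i]
            rec_s_gpe[row, i] = y[11 * n + i]
    return -1
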