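"""Membrane currents, gating kinetics, synapse kinetics, and the network RHS.

Each model cell is the five-variable conductance-based system

    C dv/dt   = -I_Na - I_K - I_L - I_Ca - I_T - I_AHP + I_app - I_syn + I_ext(t)
    dx/dt     = phi_x (x_inf(v) - x) / tau_x(v)          for x in {n, h, r}
    d[Ca]/dt  = epsilon (-I_Ca - I_T - k_Ca [Ca])

with instantaneous gates m_inf, a_inf, s_inf, the sigmoid T-current gate
b_inf(r), and first-order kinetic synapses

    ds/dt = alpha H_inf(v_pre - theta_g) (1 - s) - beta s,
    I_syn = g_syn (v - v_syn) sum_j s_j.

The functions here are the *reference* implementation: plain numpy,
vectorized over neurons, used directly by tests and mirrored by the
compiled integration kernel in :mod:`stngpe._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelConfig, NeuronParameters, SynapseParameters

__all__ = [
    "NeuronState",
    "StateLayout",
    "ionic_current",
    "gating_derivative",
    "calcium_derivative",
    "synaptic_gate_derivative",
    "synaptic_current",
    "network_rhs",
    "steady_gates",
]

CURRENT_KINDS = ("Na", "K", "L", "Ca", "T", "AHP")


@dataclass
class NeuronState:
    """State of one model cell (or, with array fields, one population)."""

    v: float | np.ndarray
    n: float | np.ndarray
    h: float | np.ndarray
    r: float | np.ndarray
    Ca: float | np.ndarray

    def as_array(self) -> np.ndarray:
        return np.asarray([self.v, self.n, self.h, self.r, self.Ca], dtype=float)


# ---------------------------------------------------------------------------
# gating curves


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def x_inf(v, theta, sigma):
    """Sigmoidal steady-state curve with midpoint ``theta`` and slope ``sigma``."""
    return sigmoid((np.asarray(v, dtype=float) - theta) / sigma)


def tau_x(v, tau0, tau1, theta, sigma):
    """Voltage-dependent time constant tau0 + tau1 * sigmoid((v-theta)/sigma)."""
    return tau0 + tau1 * sigmoid((np.asarray(v, dtype=float) - theta) / sigma)


def b_inf(r, theta_b, sigma_b):
    """T-current gate as a sigmoid-difference function of the slow gate r.

    Normalized so that b_inf(0) = 0; with the default negative slope it
    increases with r, so the T current de-inactivates under sustained
    hyperpolarization and supports post-inhibitory rebound.
    """
    r = np.asarray(r, dtype=float)
    return 1.0 / (1.0 + np.exp((r - theta_b) / sigma_b)) - 1.0 / (
        1.0 + np.exp(-theta_b / sigma_b)
    )


def steady_gates(v, p: NeuronParameters) -> tuple:
    """(n_inf, h_inf, r_inf) at membrane potential ``v``."""
    return (
        x_inf(v, p.theta_n, p.sigma_n),
        x_inf(v, p.theta_h, p.sigma_h),
        x_inf(v, p.theta_r, p.sigma_r),
    )


# ---------------------------------------------------------------------------
# single-cell operations


def ionic_current(kind: str, state: NeuronState, p: NeuronParameters):
    """One named membrane current evaluated at ``state``.

    kind is one of Na, K, L, Ca, T, AHP.  Outward currents are positive.
    """
    arr = np.asarray(state.as_array(), dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite neuron state")
    v, n, h, r, ca = state.v, state.n, state.h, state.r, state.Ca
    if kind == "Na":
        return p.g_Na * x_inf(v, p.theta_m, p.sigma_m) ** 3 * h * (v - p.v_Na)
    if kind == "K":
        return p.g_K * np.asarray(n, dtype=float) ** 4 * (v - p.v_K)
    if kind == "L":
        return p.g_L * (v - p.v_L)
    if kind == "Ca":
        return p.g_Ca * x_inf(v, p.theta_s, p.sigma_s) ** 2 * (v - p.v_Ca)
    if kind == "T":
        return (
            p.g_T
            * x_inf(v, p.theta_a, p.sigma_a) ** 3
            * b_inf(r, p.theta_b, p.sigma_b) ** 2
            * (v - p.v_Ca)
        )
    if kind == "AHP":
        # Ca-activated K+ current: reverses at v_AHP (= v_K by default)
        ca = np.asarray(ca, dtype=float)
        return p.g_AHP * (ca / (ca + p.k1)) * (v - p.v_AHP)
    raise ValueError(f"unknown current kind {kind!r}")


def total_ionic_current(state: NeuronState, p: NeuronParameters):
    return sum(ionic_current(k, state, p) for k in CURRENT_KINDS)


def gating_derivative(x, v, curve: str, p: NeuronParameters):
    """dx/dt = phi_x (x_inf(v) - x) / tau_x(v) for curve in {n, h, r}."""
    if curve not in ("n", "h", "r"):
        raise ValueError(f"unknown gating curve {curve!r}")
    phi = getattr(p, f"phi_{curve}")
    xin = x_inf(v, getattr(p, f"theta_{curve}"), getattr(p, f"sigma_{curve}"))
    tau = tau_x(
        v,
        getattr(p, f"tau_{curve}0"),
        getattr(p, f"tau_{curve}1"),
        getattr(p, f"theta_tau_{curve}"),
        getattr(p, f"sigma_tau_{curve}"),
    )
    if np.any(tau <= 0):
        raise ValueError(f"tau_{curve}(v) <= 0: check time-constant parameters")
    return phi * (xin - x) / tau


def calcium_derivative(state: NeuronState, p: NeuronParameters):
    """d[Ca]/dt = epsilon (-I_Ca - I_T - k_Ca [Ca])."""
    i_ca = ionic_current("Ca", state, p)
    i_t = ionic_current("T", state, p)
    return p.epsilon * (-i_ca - i_t - p.k_Ca * state.Ca)


def synaptic_gate_derivative(s, v_pre, p: SynapseParameters):
    """ds/dt = alpha H_inf(v_pre - theta_g) (1 - s) - beta s."""
    h = sigmoid((np.asarray(v_pre, dtype=float) - p.theta_g - p.Theta_gH) / p.sigma_gH)
    return p.alpha * h * (1.0 - s) - p.beta * s


def synaptic_current(v_post, gates, p: SynapseParameters):
    """I_syn = g_syn (v_post - v_syn) sum_j s_j over afferent gates."""
    total = np.sum(np.asarray(gates, dtype=float), axis=-1)
    return p.g_syn * (np.asarray(v_post, dtype=float) - p.v_syn) * total


# ---------------------------------------------------------------------------
# full network


class StateLayout:
    """Index slices of the flat network state vector.

    Order: v/n/h/r/Ca for STN (n_stn each), same for GPe, then the output
    synaptic gates of STN neurons and of GPe neurons (one gate per
    presynaptic cell; all its efferent synapses share it).
    """

    def __init__(self, n_stn: int, n_gpe: int):
        self.n_stn, self.n_gpe = n_stn, n_gpe
        names = ["v_stn", "n_stn", "h_stn", "r_stn", "ca_stn",
                 "v_gpe", "n_gpe", "h_gpe", "r_gpe", "ca_gpe",
                 "s_stn", "s_gpe"]
        sizes = [n_stn] * 5 + [n_gpe] * 5 + [n_stn, n_gpe]
        off = 0
        for name, size in zip(names, sizes):
            setattr(self, name, slice(off, off + size))
            off += size
        self.size = off


def _population_derivs(v, n, h, r, ca, p: NeuronParameters, i_syn, i_ext, i_app):
    state = NeuronState(v=v, n=n, h=h, r=r, Ca=ca)
    dv = (-total_ionic_current(state, p) + i_app - i_syn + i_ext) / p.C
    dn = gating_derivative(n, v, "n", p)
    dh = gating_derivative(h, v, "h", p)
    dr = gating_derivative(r, v, "r", p)
    dca = calcium_derivative(state, p)
    return dv, dn, dh, dr, dca


def network_rhs(
    y: np.ndarray,
    t: float,
    config: ModelConfig,
    i_stn: float = 0.0,
    i_app_stn: np.ndarray | None = None,
    i_app_gpe: np.ndarray | None = None,
) -> np.ndarray:
    """Time derivative of the full network state.

    ``i_stn`` is the value of the external current I_ext(t) at time ``t``
    (the realization of the input; applied to STN cells only).  The
    optional per-cell applied-current arrays default to the population
    I_app values; a nonzero configured jitter realization is passed here
    by the integrator.  The evaluation is deterministic given its
    arguments.
    """
    topo = config.topology
    lay = StateLayout(topo.n_stn, topo.n_gpe)
    y = np.asarray(y, dtype=float)
    if y.shape != (lay.size,):
        raise ValueError(f"state dimension {y.shape} != ({lay.size},)")

    v_s, n_s = y[lay.v_stn], y[lay.n_stn]
    h_s, r_s, ca_s = y[lay.h_stn], y[lay.r_stn], y[lay.ca_stn]
    v_g, n_g = y[lay.v_gpe], y[lay.n_gpe]
    h_g, r_g, ca_g = y[lay.h_gpe], y[lay.r_gpe], y[lay.ca_gpe]
    s_s, s_g = y[lay.s_stn], y[lay.s_gpe]

    # synaptic input: GPe -> STN (3 afferents on the ring), STN -> GPe (1:1)
    p_gs, p_sg = config.gpe_to_stn, config.stn_to_gpe
    gates_on_stn = topo.gpe_to_stn @ s_g
    gates_on_gpe = topo.stn_to_gpe @ s_s
    i_syn_stn = p_gs.g_syn * (v_s - p_gs.v_syn) * gates_on_stn
    i_syn_gpe = p_sg.g_syn * (v_g - p_sg.v_syn) * gates_on_gpe

    if i_app_stn is None:
        i_app_stn = np.full(topo.n_stn, config.stn.I_app)
    if i_app_gpe is None:
        i_app_gpe = np.full(topo.n_gpe, config.gpe.I_app)

    dy = np.empty_like(y)
    (dy[lay.v_stn], dy[lay.n_stn], dy[lay.h_stn], dy[lay.r_stn], dy[lay.ca_stn]) = (
        _population_derivs(v_s, n_s, h_s, r_s, ca_s, config.stn, i_syn_stn, i_stn,
                           i_app_stn)
    )
    (dy[lay.v_gpe], dy[lay.n_gpe], dy[lay.h_gpe], dy[lay.r_gpe], dy[lay.ca_gpe]) = (
        _population_derivs(v_g, n_g, h_g, r_g, ca_g, config.gpe, i_syn_gpe, 0.0,
                           i_app_gpe)
    )
    dy[lay.s_stn] = synaptic_gate_derivative(s_s, v_s, p_sg)
    dy[lay.s_gpe] = synaptic_gate_derivative(s_g, v_g, p_gs)
    return dy
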