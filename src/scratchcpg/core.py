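"""Single-population dynamics: currents, gating functions, right-hand sides.

The voltage equation balances a persistent sodium current, a leak
current, synaptic input and an excitatory external drive::

    C_m dV/dt = -I_NaP(V, h) - I_L(V) - sum_j I_syn(V, s_j) - I_ext(V)

The inactivation variable relaxes toward ``h_inf(V)`` with the
voltage-dependent *rate* ``tau_h(V) = epsilon * cosh((V - h_half)/(2 theta_h))``
(note: the rate multiplies, it does not divide -- the cosh factor makes h
move faster away from the half-inactivation voltage).  The synaptic gate
obeys ``ds/dt = alpha (1 - s) s_inf(V) - beta s`` with a near-Heaviside
``s_inf``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .params import GatingSpec, ParameterError, PopulationParams, PopulationState

__all__ = [
    "sigmoid_gate",
    "tau_h_rate",
    "currents",
    "rhs",
    "pa_transform",
]

#: Exponent clamp for numerically stable sigmoids (theta_s = -0.1 mV makes
#: s_inf near-Heaviside and easily overflows a bare exp).
_EXP_CLAMP = 500.0


def sigmoid_gate(v, spec: GatingSpec):
    """Steady-state sigmoid ``x_inf(v) = 1/(1 + exp((v - half)/theta))``.

    Monotone increasing for ``theta < 0`` and decreasing for ``theta > 0``.
    Accepts scalars or arrays.
    """
    if spec.theta == 0:
        raise ParameterError("gating slope theta must be nonzero")
    x = np.clip((np.asarray(v, dtype=float) - spec.half) / spec.theta,
                -_EXP_CLAMP, _EXP_CLAMP)
    out = 1.0 / (1.0 + np.exp(x))
    return out if out.ndim else float(out)


def tau_h_rate(v, params: PopulationParams):
    """Relaxation rate of h (ms^-1): ``epsilon * cosh((v - h_half)/(2 theta_h))``.

    Minimum ``epsilon`` at ``v = h_half``; even about that voltage.
    """
    arg = (np.asarray(v, dtype=float) - params.h_gate.half) / (2.0 * params.h_gate.theta)
    out = params.epsilon * np.cosh(arg)
    return out if out.ndim else float(out)


def currents(
    state: PopulationState,
    s_in: Sequence[float],
    weights: Sequence[tuple[float, float]],
    i_ext: float,
    params: PopulationParams,
) -> tuple[float, float, float, float]:
    """Evaluate (I_NaP, I_L, I_syn_total, I_ext) for one population.

    Parameters
    ----------
    s_in : presynaptic gating variables, one per synapse.
    weights : per-synapse ``(g, e_rev)`` pairs; conductances must be >= 0.
    i_ext : external drive conductance (nS), reversing at ``e_syn_exc``.
    """
    v, h = state.v, state.h
    if i_ext < 0:
        raise ParameterError("external drive conductance must be nonnegative")
    i_nap = params.g_nap * sigmoid_gate(v, params.m_gate) * h * (v - params.e_na)
    i_leak = params.g_leak * (v - params.e_leak)
    i_syn = 0.0
    for s_j, (g, e_rev) in zip(s_in, weights, strict=True):
        if g < 0:
            raise ParameterError("synaptic conductance must be nonnegative")
        i_syn += g * s_j * (v - e_rev)
    i_drive = i_ext * (v - params.e_syn_exc)
    return i_nap, i_leak, i_syn, i_drive


def rhs(
    state: PopulationState,
    s_in: Sequence[float],
    weights: Sequence[tuple[float, float]],
    i_ext: float,
    params: PopulationParams,
) -> tuple[float, float, float]:
    """Time derivatives (dV/dt, dh/dt, ds/dt) of one population."""
    i_nap, i_leak, i_syn, i_drive = currents(state, s_in, weights, i_ext, params)
    dv = (-i_nap - i_leak - i_syn - i_drive) / params.c_m
    dh = (sigmoid_gate(state.v, params.h_gate) - state.h) * tau_h_rate(state.v, params)
    ds = (
        params.alpha * (1.0 - state.s) * sigmoid_gate(state.v, params.s_gate)
        - params.beta * state.s
    )
    return dv, dh, ds


def pa_transform(v):
    """Population activity: rescaled voltage ``PA(V) = 1/(1 + exp(-(V+30)/2))``.

    Maps the plateau voltage range onto (0, 1); 0.5 at V = -30 mV.
    """
    x = np.clip(-(np.asarray(v, dtype=float) + 30.0) / 2.0, -_EXP_CLAMP, _EXP_CLAMP)
    out = 1.0 / (1.0 + np.exp(x))
    return out if out.ndim else float(out)
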