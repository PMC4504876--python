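"""Biophysical parameters for a single model population.

Each neuronal pool in the scratch CPG is represented by one
persistent-sodium (I_NaP) relaxation unit with three state variables:
membrane potential ``V`` (mV), I_NaP deinactivation ``h`` (dimensionless),
and a synaptic gating variable ``s`` (dimensionless).  All populations
share one default parameter set; drives and synaptic weights carry the
network structure.

Units follow the model convention: voltages in mV, conductances in nS,
capacitance in pF, rates in ms^-1.  No unit conversion layer is applied;
the raw values reproduce the model's time scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ParameterError(ValueError):
    """Invalid biophysical parameter."""


@dataclass(frozen=True)
class GatingSpec:
    """Half-activation voltage and slope of a sigmoidal (in)activation curve.

    The steady-state curve is ``x_inf(v) = 1 / (1 + exp((v - half)/theta))``,
    increasing in ``v`` for ``theta < 0`` and decreasing for ``theta > 0``.
    """

    half: float
    theta: float

    def __post_init__(self) -> None:
        if self.theta == 0:
            raise ParameterError("gating slope theta must be nonzero")


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of one population (defaults reproduce the model's table).

    Attributes
    ----------
    c_m : membrane capacitance (pF).
    g_nap, e_na : persistent sodium conductance (nS) and reversal (mV).
    g_leak, e_leak : leak conductance (nS) and reversal (mV).
    m_gate, h_gate, s_gate : activation, inactivation and synaptic-release
        gating curves.
    epsilon : base rate of h (ms^-1); the small parameter of the slow
        subsystem.
    alpha, beta : synaptic activation and decay rates (ms^-1).
    e_syn_exc, e_syn_inh : synaptic reversal potentials (mV).
    """

    c_m: float = 0.21
    g_nap: float = 10.0
    e_na: float = 50.0
    g_leak: float = 2.8
    e_leak: float = -65.0
    m_gate: GatingSpec = field(default_factory=lambda: GatingSpec(-37.0, -6.0))
    h_gate: GatingSpec = field(default_factory=lambda: GatingSpec(-30.0, 6.0))
    s_gate: GatingSpec = field(default_factory=lambda: GatingSpec(-43.0, -0.1))
    epsilon: float = 0.01
    alpha: float = 1.0
    beta: float = 0.08
    e_syn_exc: float = 0.0
    e_syn_inh: float = -80.0

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ParameterError("c_m must be positive")
        for name in ("g_nap", "g_leak", "alpha", "beta"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if not (0 < self.epsilon < 1):
            raise ParameterError("epsilon must lie in (0, 1)")
        if not (self.e_syn_inh < self.e_leak < self.e_syn_exc):
            raise ParameterError(
                "expected e_syn_inh < e_leak < e_syn_exc "
                "(hyperpolarizing inhibition, depolarizing excitation)"
            )

    @property
    def s_max(self) -> float:
        """Asymptotic synaptic gating level alpha / (alpha + beta)."""
        return self.alpha / (self.alpha + self.beta)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParams":
        d = dict(d)
        for g in ("m_gate", "h_gate", "s_gate"):
            if g in d and isinstance(d[g], dict):
                d[g] = GatingSpec(**d[g])
        return cls(**d)


@dataclass
class PopulationState:
    """State (V, h, s) of one population."""

    v: float
    h: float
    s: float

    def validate(self, params: PopulationParams) -> None:
        if not (0.0 <= self.h <= 1.0):
            raise ValueError(f"h out of [0, 1]: {self.h}")
        if not (0.0 <= self.s <= params.s_max + 1e-12):
            raise ValueError(f"s out of [0, s_max]: {self.s}")


#: Shared default parameter set used by every population in the network.
DEFAULT_PARAMS = PopulationParams()
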