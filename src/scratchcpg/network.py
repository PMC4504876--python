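"""Network construction: the 7-population scratch CPG and its reduced module.

The interneuron layer holds two unit generators, a pocket-side pair
(excitatory EP driving the hip extensor, inhibitory IR suppressing the
hip flexor) and a rostral-side pair (ER driving the hip flexor, IP
suppressing the hip extensor).  Reciprocal inhibition links EP with IP
and ER with IR; cross-excitation from each excitatory pool to the
inhibitory pool of its own side (EP->IR, ER->IP) synchronizes the pairs.
The layer feeds forward to three motoneuron pools (HE, KE, HF) that do
not interact and send nothing back.

Two weight classes are shipped:

``S``
    standard weights, cross-excitation 0.5 nS, baseline drive 0.17 nS.
``SCE``
    strong cross-excitation, 0.8 nS, baseline drive 0.16 nS.

The two classes share identical interneuron-to-motoneuron weights.
Numeric weight values are calibrated, not printed: they were recovered
by a seeded constrained search (see ``experiments.calibrate_weights``)
against the qualitative constraints the architecture must satisfy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .params import DEFAULT_PARAMS, PopulationParams

__all__ = [
    "INTERNEURONS",
    "MOTONEURONS",
    "POPULATIONS",
    "SynapseSpec",
    "DriveSet",
    "NetworkConfig",
    "ReducedModuleConfig",
    "ConfigError",
    "ReductionError",
    "build_network",
    "reduce_module",
    "ke_synaptic_input",
    "POCKET_DRIVES",
    "ROSTRAL_DRIVES",
    "ROSTRAL_DRIVES_1",
    "ROSTRAL_DRIVES_2",
    "baseline_drives",
]

INTERNEURONS = ("IP", "EP", "ER", "IR")
MOTONEURONS = ("HE", "KE", "HF")
POPULATIONS = INTERNEURONS + MOTONEURONS


class ConfigError(ValueError):
    """Network configuration violates a structural invariant."""


class ReductionError(RuntimeError):
    """Reduced-module preconditions (pair synchrony) not satisfied."""

    def __init__(self, msg: str, phase_lag: float | None = None):
        super().__init__(msg)
        self.phase_lag = phase_lag


@dataclass(frozen=True)
class SynapseSpec:
    """One synaptic connection; sign is carried by the reversal potential."""

    source: str
    target: str
    g: float
    reversal: str  # "excitatory" | "inhibitory"

    def __post_init__(self) -> None:
        if self.source not in POPULATIONS or self.target not in POPULATIONS:
            raise ConfigError(f"unknown population in synapse {self.source}->{self.target}")
        if self.g < 0:
            raise ConfigError("synaptic conductances are defined positive")
        if self.reversal not in ("excitatory", "inhibitory"):
            raise ConfigError(f"reversal must be excitatory/inhibitory, got {self.reversal}")

    def e_rev(self, params: PopulationParams) -> float:
        return params.e_syn_exc if self.reversal == "excitatory" else params.e_syn_inh


@dataclass(frozen=True)
class DriveSet:
    """External tonic drive conductances (nS) to the interneuron pools.

    Motoneurons receive no external drive by default; the field is kept
    explicit so it can be overridden.
    """

    i_ip: float
    i_ep: float
    i_er: float
    i_ir: float
    i_he: float = 0.0
    i_ke: float = 0.0
    i_hf: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v < 0:
                raise ConfigError(f"drive {name} must be nonnegative")

    def as_dict(self) -> dict[str, float]:
        return {
            "IP": self.i_ip, "EP": self.i_ep, "ER": self.i_er, "IR": self.i_ir,
            "HE": self.i_he, "KE": self.i_ke, "HF": self.i_hf,
        }

    def vector(self) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[p] for p in POPULATIONS])

    @property
    def stimulated_side(self) -> str | None:
        """Which unit receives the stronger drive ('pocket', 'rostral', None)."""
        if self.i_ep > self.i_er:
            return "pocket"
        if self.i_er > self.i_ep:
            return "rostral"
        return None

    def scaled(self, factor: float, target: str = "all") -> "DriveSet":
        """Return drives with interneuron inputs scaled by ``factor``.

        ``target`` selects which pools are scaled: ``all``, ``E`` (EP, ER)
        or ``I`` (IP, IR).
        """
        f_e = factor if target in ("all", "E") else 1.0
        f_i = factor if target in ("all", "I") else 1.0
        return replace(self, i_ep=self.i_ep * f_e, i_er=self.i_er * f_e,
                       i_ip=self.i_ip * f_i, i_ir=self.i_ir * f_i)


# --- calibrated weight tables ------------------------------------------------
# Interneuron layer (class-specific): reciprocal inhibition and
# cross-excitation.  Cross-excitation strengths (0.5 vs 0.8 nS) are the
# printed class difference; the inhibitory values are calibrated.
_IN_LAYER = {
    "S": {
        ("EP", "IP", "inhibitory"): 1.4,
        ("ER", "IR", "inhibitory"): 1.4,
        ("IP", "EP", "inhibitory"): 1.0,
        ("IR", "ER", "inhibitory"): 1.0,
        ("EP", "IR", "excitatory"): 0.5,
        ("ER", "IP", "excitatory"): 0.5,
    },
    # In the strong-cross-excitation class the whole stimulated pool is
    # recruited together; the stronger E->I links (both the 0.8 nS
    # cross-excitation and the calibrated 1.8 nS inhibition) prolong the
    # rostral unit's phase under weak drives, which is what suppresses
    # pocket/rostral bistability in this class.
    "SCE": {
        ("EP", "IP", "inhibitory"): 1.8,
        ("ER", "IR", "inhibitory"): 1.8,
        ("IP", "EP", "inhibitory"): 1.0,
        ("IR", "ER", "inhibitory"): 1.0,
        ("EP", "IR", "excitatory"): 0.8,
        ("ER", "IP", "excitatory"): 0.8,
    },
}

# Interneuron -> motoneuron weights, shared by both classes (calibrated).
# The hip weights obey the mirror symmetry g(HE<-EP) = g(HF<-ER),
# g(HE<-IP) = g(HF<-IR); the KE weights satisfy the rhythm requirement
# that the rostral-side sources (ER, IR) are stronger than their
# pocket-side counterparts (EP, IP).
_MN_LAYER = {
    ("EP", "HE", "excitatory"): 0.6,
    ("IP", "HE", "inhibitory"): 2.0,
    ("ER", "HF", "excitatory"): 0.6,
    ("IR", "HF", "inhibitory"): 2.0,
    ("EP", "KE", "excitatory"): 0.05,
    ("IP", "KE", "inhibitory"): 0.7,
    ("ER", "KE", "excitatory"): 0.2,
    ("IR", "KE", "inhibitory"): 1.48,
}

#: Baseline drives below which no rhythm is elicited from rest.
_BASELINE = {"S": 0.17, "SCE": 0.16}
#: Default drive boost applied to the stimulated side's pools.
_BOOST = {"S": 0.02, "SCE": 0.03}

# Printed drive-set fixtures (S class).
POCKET_DRIVES = DriveSet(i_ip=0.17, i_ep=0.19, i_er=0.17, i_ir=0.19)
ROSTRAL_DRIVES = DriveSet(i_ip=0.19, i_ep=0.17, i_er=0.19, i_ir=0.17)
#: Rostral set that leaves an ongoing pocket rhythm intact (bistability).
ROSTRAL_DRIVES_1 = DriveSet(i_ip=0.19, i_ep=0.18, i_er=0.19, i_ir=0.18)
#: Rostral set that switches an ongoing pocket rhythm to rostral.
ROSTRAL_DRIVES_2 = DriveSet(i_ip=0.19, i_ep=0.17, i_er=0.19, i_ir=0.17)


def baseline_drives(weight_class: str) -> DriveSet:
    b = _BASELINE[weight_class]
    return DriveSet(i_ip=b, i_ep=b, i_er=b, i_ir=b)


def stimulus_drives(weight_class: str, side: str) -> DriveSet:
    """Baseline drives with the standard boost applied to one side's pools."""
    b = _BASELINE[weight_class]
    hi = b + _BOOST[weight_class]
    if side == "pocket":
        return DriveSet(i_ip=b, i_ep=hi, i_er=b, i_ir=hi)
    if side == "rostral":
        return DriveSet(i_ip=hi, i_ep=b, i_er=hi, i_ir=b)
    raise ConfigError(f"side must be pocket/rostral, got {side}")


@dataclass
class NetworkConfig:
    """Full network: populations, synapses, drives and weight-class tag."""

    weight_class: str
    synapses: tuple[SynapseSpec, ...]
    drives: DriveSet
    params: PopulationParams = field(default_factory=lambda: DEFAULT_PARAMS)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for syn in self.synapses:
            if syn.source in MOTONEURONS:
                raise ConfigError(
                    f"motoneurons have no outgoing synapses ({syn.source}->{syn.target})"
                )
        # hip motoneuron mirror symmetry
        w = self.weight_lookup()
        pairs = [(("EP", "HE"), ("ER", "HF")), (("IP", "HE"), ("IR", "HF"))]
        for (a, b) in pairs:
            if a in w and b in w and not np.isclose(w[a], w[b]):
                raise ConfigError(
                    f"hip symmetry violated: g{a} = {w[a]} != g{b} = {w[b]}"
                )

    def weight_lookup(self) -> dict[tuple[str, str], float]:
        return {(s.source, s.target): s.g for s in self.synapses}

    def weight_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(W_inh, W_exc) conductance matrices, row = target population."""
        n = len(POPULATIONS)
        idx = {p: i for i, p in enumerate(POPULATIONS)}
        w_inh = np.zeros((n, n))
        w_exc = np.zeros((n, n))
        for syn in self.synapses:
            m = w_exc if syn.reversal == "excitatory" else w_inh
            m[idx[syn.target], idx[syn.source]] += syn.g
        return w_inh, w_exc

    def with_drives(self, drives: DriveSet) -> "NetworkConfig":
        return NetworkConfig(self.weight_class, self.synapses, drives, self.params)


def build_network(
    weight_class: str = "S",
    drives: DriveSet | None = None,
    overrides: Mapping[tuple[str, str], float] | None = None,
    params: PopulationParams | None = None,
) -> NetworkConfig:
    """Wire the 7-population network for a weight class.

    Parameters
    ----------
    weight_class : "S", "SCE" or "custom".  "custom" starts from the S
        table and applies ``overrides`` without the cross-class checks.
    drives : external drive set; defaults to the class baseline applied
        uniformly to all interneurons.
    overrides : optional ``{(source, target): g}`` replacing calibrated
        conductances.  Overrides must still satisfy structural invariants.
    """
    if weight_class not in ("S", "SCE", "custom"):
        raise ConfigError(f"unknown weight class {weight_class!r}")
    table_class = "S" if weight_class == "custom" else weight_class
    entries: dict[tuple[str, str, str], float] = dict(_IN_LAYER[table_class])
    entries.update(_MN_LAYER)
    if overrides:
        keyed = {(s, t): (s, t, r) for (s, t, r) in entries}
        for (s, t), g in overrides.items():
            if (s, t) not in keyed:
                raise ConfigError(f"no such synapse to override: {s}->{t}")
            entries[keyed[(s, t)]] = float(g)
    synapses = tuple(
        SynapseSpec(s, t, g, r) for (s, t, r), g in sorted(entries.items())
    )
    if drives is None:
        drives = baseline_drives(table_class)
    return NetworkConfig(
        weight_class=weight_class,
        synapses=synapses,
        drives=drives,
        params=params or DEFAULT_PARAMS,
    )


@dataclass(frozen=True)
class ReducedModuleConfig:
    """Two-unit half-center plus the knee extensor it drives.

    The reduction lumps the co-active pairs (EP, IR) and (ER, IP) into
    single units by the identifications ``s_IP = s_ER`` and
    ``s_IR = s_EP``, shrinking KE's slow phase space from five dimensions
    (four synaptic gates plus h_KE) to three: (h_KE, s_EP, s_ER).
    """

    g_ke_ep: float
    g_ke_ip: float
    g_ke_er: float
    g_ke_ir: float
    params: PopulationParams = field(default_factory=lambda: DEFAULT_PARAMS)

    def __post_init__(self) -> None:
        if not (self.g_ke_er > self.g_ke_ep and self.g_ke_ir > self.g_ke_ip):
            raise ConfigError(
                "reduced module requires the rostral-side KE weights "
                "(from ER, IR) to exceed the pocket-side ones (from EP, IP)"
            )


def reduce_module(
    config: NetworkConfig,
    synchrony_check: tuple[np.ndarray, dict[str, np.ndarray]] | None = None,
    tol: float = 0.05,
) -> ReducedModuleConfig:
    """Extract the reduced KE module from a full network config.

    If ``synchrony_check`` is given as ``(t, {pop: s(t)})`` from a
    simulation, the identifications ``s_ER = s_IP`` and ``s_EP = s_IR``
    are verified: the normalized RMS mismatch over the trace must stay
    below ``tol``, otherwise a :class:`ReductionError` carrying the
    measured mismatch is raised.
    """
    w = config.weight_lookup()
    try:
        module = ReducedModuleConfig(
            g_ke_ep=w[("EP", "KE")],
            g_ke_ip=w[("IP", "KE")],
            g_ke_er=w[("ER", "KE")],
            g_ke_ir=w[("IR", "KE")],
            params=config.params,
        )
    except KeyError as e:  # pragma: no cover - structural
        raise ConfigError(f"network lacks a KE synapse: {e}") from e
    if synchrony_check is not None:
        _t, s = synchrony_check
        scale = max(float(np.max(np.abs(s["ER"]))), 1e-12)
        lag1 = float(np.sqrt(np.mean((s["ER"] - s["IP"]) ** 2))) / scale
        lag2 = float(np.sqrt(np.mean((s["EP"] - s["IR"]) ** 2))) / scale
        if max(lag1, lag2) > tol:
            raise ReductionError(
                f"pair synchrony violated (rms mismatch {max(lag1, lag2):.3f} > {tol})",
                phase_lag=max(lag1, lag2),
            )
    return module


def ke_synaptic_input(
    v_ke: float,
    s_ep: float,
    s_er: float,
    module: ReducedModuleConfig,
):
    """Hybrid synaptic current onto KE in the reduced module.

    With ``e_syn_exc = 0`` (asserted) and the pair identifications, the
    four synapses collapse to::

        I_syn = s_ER [ (g_IP + g_ER) V - g_IP e_inh ]
              + s_EP [ (g_IR + g_EP) V - g_IR e_inh ]
    """
    p = module.params
    if p.e_syn_exc != 0.0:
        raise ConfigError("hybrid KE input formula assumes e_syn_exc = 0")
    e_inh = p.e_syn_inh
    return (
        s_er * ((module.g_ke_ip + module.g_ke_er) * v_ke - module.g_ke_ip * e_inh)
        + s_ep * ((module.g_ke_ir + module.g_ke_ep) * v_ke - module.g_ke_ir * e_inh)
    )
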