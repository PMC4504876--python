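"""Sufficient conditions for stable pocket and rostral rhythm selection.

All conditions are inequalities between slow-flow images of a few
landmark points of the slow phase plane (the saddle-node point, the
knee-curve endpoints and their forward/backward flows).  Margins are
reported in the condition's natural units: h for the flow comparisons,
s for the gate-interval condition.  A positive margin means satisfied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DriveSet, NetworkConfig, ReducedModuleConfig
from .simulate import InsufficientDataError, PhaseAnnotation, Trace, RhythmLabel
from .slowphase import (
    SlowLandscape,
    knee_curve,
    slow_flow,
)

__all__ = [
    "ConditionReport",
    "check_pocket",
    "check_rostral",
    "check_requirements",
    "key_differentiator",
]


@dataclass
class ConditionResult:
    name: str
    satisfied: bool
    margin: float
    units: str
    inputs: dict = field(default_factory=dict)


@dataclass
class ConditionReport:
    conditions: list[ConditionResult]
    ordering: dict[str, float]
    verdict: bool
    kind: str  # "pocket" | "rostral" | "requirements"

    def __getitem__(self, name: str) -> ConditionResult:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "verdict": self.verdict,
            "ordering": self.ordering,
            "conditions": [
                {"name": c.name, "satisfied": c.satisfied, "margin": c.margin,
                 "units": c.units, "inputs": c.inputs}
                for c in self.conditions
            ],
        }


def _flow_h(module, start, branch, context, duration,
            i_ext=0.0) -> tuple[float, bool]:
    """Terminal h of a slow flow and whether the branch was left early.

    A fold crossing before the requested duration means the trajectory
    jumped between phases prematurely; conditions that require the point
    to remain on its branch for the whole phase fail in that case.
    """
    from .slowphase import FoldCrossedError

    try:
        res = slow_flow(start, branch, context, module,
                        stop={"duration": duration}, i_ext=i_ext)
        return float(res.h[-1]), False
    except FoldCrossedError as e:
        return float(e.crossing[0]), True


def check_pocket(
    drives: DriveSet,
    landscape: SlowLandscape,
    module: ReducedModuleConfig,
    i_ext: float = 0.0,
) -> ConditionReport:
    """Evaluate the four pocket-sufficiency conditions.

    The conditions ensure that KE, activating on the jump-up segment
    while the rostral unit is active, (1) stays active into the
    pocket-unit phase, (2) can deactivate when that phase ends, and
    (3, 4) re-activates from the interior of the jump-up segment on the
    next cycle, sufficiently late in the rostral phase.
    """
    L = landscape
    conds: list[ConditionResult] = []

    # ordering precondition: rostral unit active shorter than pocket unit
    ordering = {"t_active_er": L.t_active_er, "t_active_ep": L.t_active_ep}
    order_ok = L.t_active_er < L.t_active_ep

    # P1: forward flow of the saddle-node point stays above h_max
    m1 = L.h_sn_plus - L.h_max
    conds.append(ConditionResult(
        "P1", m1 > 0, m1, "h",
        {"h_sn_plus": L.h_sn_plus, "h_max": L.h_max}))

    # P2/P3: highest re-activating trajectory after the pocket phase
    h2, x2 = _flow_h(module, (L.h_er_min, L.s_max), "R", "EP", L.t_active_ep, i_ext)
    m2 = L.h_max - h2
    conds.append(ConditionResult(
        "P2", m2 > 0 and not x2, m2, "h",
        {"h_end": h2, "h_max": L.h_max, "left_branch_early": x2}))
    m3 = L.h_sn_minus - h2
    conds.append(ConditionResult(
        "P3", m3 > 0 and not x2, m3, "h",
        {"h_end": h2, "h_sn_minus": L.h_sn_minus, "left_branch_early": x2}))

    # P4: lowest trajectory stays above the backward image of the
    # low-s endpoint of the activation segment
    h4, x4 = _flow_h(module, (L.h_sn_plus, L.s_max), "R", "EP", L.t_active_ep, i_ext)
    m4 = h4 - L.h_smin_minus
    conds.append(ConditionResult(
        "P4", m4 > 0 and not x4, m4, "h",
        {"h_end": h4, "h_smin_minus": L.h_smin_minus, "left_branch_early": x4}))

    verdict = order_ok and all(c.satisfied for c in conds)
    return ConditionReport(conds, ordering, verdict, "pocket")


def check_rostral(
    drives: DriveSet,
    landscape: SlowLandscape,
    module: ReducedModuleConfig,
    i_ext: float = 0.0,
) -> ConditionReport:
    """Evaluate the three rostral-sufficiency conditions.

    KE must activate at the saddle-node with the rostral unit active,
    reach the jump-down window by the end of that phase (R1), the gate
    must decay past the saddle-node value within the phase (R2, two
    printed forms), and even the lowest trajectory must return to the
    saddle-node point while the rostral unit is still active (R3).
    """
    L = landscape
    conds: list[ConditionResult] = []
    ordering = {"t_active_er": L.t_active_er, "t_active_ep": L.t_active_ep}
    order_ok = L.t_active_ep < L.t_active_er

    # R1: forward flow of the saddle-node point lands in I_h
    m1 = min(L.h_sn_plus - L.h_min, L.h_max - L.h_sn_plus)
    conds.append(ConditionResult(
        "R1", m1 > 0, m1, "h",
        {"h_sn_plus": L.h_sn_plus, "interval_h": L.interval_h}))

    # R2: s_sn > s_er_min  <=>  T_active_er > (1/beta) ln(s_max / s_sn)
    m2 = L.s_sn - L.s_er_min
    beta = module.params.beta
    t_needed = np.log(L.s_max / L.s_sn) / beta
    m2b = L.t_active_er - t_needed
    agree = (m2 > 0) == (m2b > 0)
    conds.append(ConditionResult(
        "R2", m2 > 0 and agree, m2, "s",
        {"s_sn": L.s_sn, "s_er_min": L.s_er_min,
         "t_form_margin_ms": float(m2b), "forms_agree": agree}))

    # R3: flow of (h_min, s_max) through the pocket phase (silent branch)
    # then compare with the backward image of the saddle-node point
    h_ep, x3 = _flow_h(module, (L.h_min, L.s_max), "L", "EP", L.t_active_ep, i_ext)
    m3 = h_ep - L.h_sn_minus
    conds.append(ConditionResult(
        "R3", m3 > 0 and not x3, m3, "h",
        {"h_ep": h_ep, "h_sn_minus": L.h_sn_minus, "left_branch_early": x3}))

    verdict = order_ok and all(c.satisfied for c in conds)
    return ConditionReport(conds, ordering, verdict, "rostral")


# --- trajectory requirements -------------------------------------------------

def check_requirements(
    trace: Trace,
    annotation: PhaseAnnotation,
    label: RhythmLabel,
    landscape: SlowLandscape,
    module: ReducedModuleConfig,
    sn_tol_frac: float = 0.02,
) -> ConditionReport:
    """Check the per-phase trajectory requirements of the classified rhythm.

    For a pocket rhythm: (i) KE deactivates only when the rostral unit
    takes over (never mid-phase while the gate decays), and (ii) the
    rostral unit has been active at least the minimal silent time
    ``t_star`` before each KE activation.  For a rostral rhythm:
    (iii) KE activates at the saddle-node (the dynamic gate is within
    ``sn_tol_frac * s_max`` of ``s_sn``) and deactivates with the
    rostral unit, and (iv) no KE activation occurs during the pocket
    unit's phase.
    """
    if label.label not in ("pocket", "rostral"):
        raise InsufficientDataError(
            f"requirements are defined for classified rhythms, got {label.label!r}"
        )
    L = landscape
    conds: list[ConditionResult] = []
    ivK = annotation.intervals["KE"]
    ivF = annotation.intervals["HF"]
    ivH = annotation.intervals["HE"]
    if len(ivK) < 3:
        raise InsufficientDataError("fewer than 3 KE activations")
    hf_ons = [a for a, _ in ivF]
    hf_offs = [b for _, b in ivF]

    if label.label == "pocket":
        # (i): each KE offset coincides with a rostral-unit onset
        errs = [abs(kf - min(hf_ons, key=lambda x: abs(x - kf)))
                for _, kf in ivK[1:-1]]
        m = 0.1 * label.period - max(errs)
        conds.append(ConditionResult(
            "i", m > 0, m, "ms", {"offset_vs_hf_onset_ms": errs}))
        # (ii): rostral unit active >= t_star before KE activates
        lead = [ko - max([a for a in hf_ons if a <= ko], default=-np.inf)
                for ko, _ in ivK[1:-1]]
        m2 = min(lead) - L.t_star
        conds.append(ConditionResult(
            "ii", m2 > 0, m2, "ms",
            {"er_lead_ms": lead, "t_star": L.t_star}))
    else:
        # (iii): activation at the saddle-node of the fast subsystem
        s_at_on = []
        for ko, _ in ivK[1:-1]:
            k = np.searchsorted(trace.t, ko)
            if k < len(trace.t):
                s_at_on.append(float(trace.s["EP"][k]))
        dev = max(abs(s - L.s_sn) for s in s_at_on)
        m = sn_tol_frac * L.s_max - dev
        conds.append(ConditionResult(
            "iii", m > 0, m, "s", {"s_at_onset": s_at_on, "s_sn": L.s_sn}))
        # offsets coincide with rostral-unit offsets
        errs = [abs(kf - min(hf_offs, key=lambda x: abs(x - kf)))
                for _, kf in ivK[1:-1]]
        m_off = 0.1 * label.period - max(errs)
        conds.append(ConditionResult(
            "iii-offset", m_off > 0, m_off, "ms", {"offset_vs_hf_offset_ms": errs}))
        # (iv): no KE onset during the pocket unit's active phase
        bad = 0
        for ko, _ in ivK[1:-1]:
            for a, b in ivH:
                if a <= ko <= b:
                    bad += 1
        conds.append(ConditionResult(
            "iv", bad == 0, float(-bad), "count", {"onsets_in_he_phase": bad}))

    verdict = all(c.satisfied for c in conds)
    return ConditionReport(conds, {}, verdict, "requirements")


def key_differentiator(
    drives: DriveSet,
    module: ReducedModuleConfig,
    config: NetworkConfig,
    landscape: SlowLandscape | None = None,
    i_ext: float = 0.0,
) -> tuple[str, float]:
    """Predict the selected rhythm from the slow phase plane alone.

    Flows the KE point from its activation on the jump-up segment
    through the remainder of the rostral unit's phase; if ``h_KE``
    exceeds ``h_max`` at the phase's end, KE has no jump-down knee
    available and remains active into the pocket phase (pocket-leaning);
    otherwise the rising gate pulls it below and KE shuts off with the
    rostral unit (rostral-leaning).  Returns ``(label, margin)`` with
    margin ``h_end - h_max``.
    """
    from .slowphase import compute_landscape

    L = landscape or compute_landscape(drives, module, config, i_ext=i_ext)
    margin = L.h_sn_plus - L.h_max
    return ("pocket-leaning" if margin > 0 else "rostral-leaning", float(margin))
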