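"""In-silico experiments: input switching, bistability, scaling, calibration.

The switching experiments emulate delivering a new stimulus during an
ongoing rhythm: drives are swapped instantaneously at the end of a hip
extensor burst and the simulation continues from the current state, so
the outcome depends on the attractor the network already occupies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import (
    DriveSet,
    NetworkConfig,
    build_network,
)
from .simulate import (
    InsufficientDataError,
    RhythmLabel,
    Trace,
    classify,
    detect_phases,
    integrate,
)

__all__ = [
    "SwitchProtocol",
    "SwitchResult",
    "ScalingProtocol",
    "CalibrationResult",
    "ProtocolError",
    "run_switch",
    "probe_bistability",
    "run_scaling",
    "drop_inhibitory_drive",
    "calibrate_weights",
]


class ProtocolError(RuntimeError):
    pass


@dataclass
class SwitchProtocol:
    config: NetworkConfig
    initial_drives: DriveSet
    target_drives: DriveSet
    settle_periods: int = 3
    pre_span: float = 2500.0
    post_span: float = 4000.0


@dataclass
class SwitchResult:
    before: RhythmLabel
    after: RhythmLabel
    transition_labels: list[str]
    switch_time: float
    trace_before: Trace
    trace_after: Trace


def _find_he_offset(trace: Trace, after: float) -> float | None:
    ann = detect_phases(trace, pops=["HE"], t_min=after)
    for _, off in ann.intervals["HE"]:
        if off > after and off < trace.t[-1] - 1.0:
            return off
    return None


def run_switch(protocol: SwitchProtocol) -> SwitchResult:
    """Switch drives at the end of a hip-extensor burst and reclassify.

    The pre-switch rhythm must be established (at least
    ``settle_periods`` full periods); the trigger is the first HE offset
    after the settling window.  Cycle labels spanning the switch are
    reported so transitional (blend) cycles are visible.
    """
    cfg1 = protocol.config.with_drives(protocol.initial_drives)
    tr1, sol1 = integrate(cfg1, t_end=protocol.pre_span, init="auto", dense=True)
    before = classify(tr1)
    if before.label not in ("pocket", "rostral", "blend", "other"):
        raise ProtocolError(f"initial drives elicit no rhythm (label {before.label})")
    ann1 = detect_phases(tr1, pops=["HE"])
    if ann1.n_periods("HE") < protocol.settle_periods:
        raise ProtocolError("initial rhythm not established before switch")
    settle_t = ann1.intervals["HE"][protocol.settle_periods][0]
    t_sw = _find_he_offset(tr1, settle_t)
    if t_sw is None:
        raise ProtocolError("no HE offset found to trigger the switch")
    y_sw = sol1.sol(t_sw)

    cfg2 = protocol.config.with_drives(protocol.target_drives)
    tr2 = integrate(cfg2, t_end=t_sw + protocol.post_span, t_start=t_sw, init=y_sw)
    after = classify(tr2)
    # transitional cycles: classify early post-switch window cycle-by-cycle
    early = classify(tr2, settle_frac=0.0)
    return SwitchResult(
        before=before,
        after=after,
        transition_labels=early.cycle_labels,
        switch_time=float(t_sw),
        trace_before=tr1,
        trace_after=tr2,
    )


def probe_bistability(
    config: NetworkConfig,
    rostral_drives: DriveSet,
    pocket_drives: DriveSet | None = None,
) -> dict:
    """Test whether a rostral drive set leaves an ongoing pocket rhythm intact.

    The drive set must elicit a rostral rhythm from rest (precondition).
    It is then applied during an established pocket rhythm; the system is
    bistable for that input if the pocket-type KE synchronization
    persists.  The returned evidence includes the race diagnostic: the
    margin of h_KE over the jump-down ceiling h_max at the ends of the
    post-switch hip-flexor bursts (positive: KE survives into the HE
    phase and pocket continues).
    """
    from .network import stimulus_drives
    from .slowphase import compute_landscape, LandscapeUndefinedError
    from .network import reduce_module

    if pocket_drives is None:
        pocket_drives = stimulus_drives(config.weight_class
                                        if config.weight_class in ("S", "SCE") else "S",
                                        "pocket")
    rest_label = classify(integrate(config.with_drives(rostral_drives),
                                    t_end=2500.0, init="auto"))
    if rest_label.label != "rostral":
        raise ProtocolError(
            f"drive set does not elicit rostral from rest (got {rest_label.label})"
        )
    res = run_switch(SwitchProtocol(config, pocket_drives, rostral_drives))
    pocket_kept = _pocket_type(res.after)
    evidence = {"after_label": res.after.label,
                "after_features": {
                    "ke_delay": res.after.ke_delay,
                    "ke_he_coactivity": res.after.ke_he_coactivity,
                    "t_active": res.after.t_active,
                }}
    try:
        module = reduce_module(config)
        L = compute_landscape(rostral_drives, module, config)
        evidence["race_margin_h"] = L.h_sn_plus - L.h_max
    except Exception:  # noqa: BLE001 - race diagnostic is best-effort
        pass
    return {"bistable": pocket_kept, "evidence": evidence, "switch": res}


def _pocket_type(label: RhythmLabel) -> bool:
    """Pocket-type KE synchronization, regardless of hip duration ordering.

    After a switch to near-threshold drives the hip flexor can outlast
    the hip extensor while KE still fires with HE; that state counts as
    a retained pocket rhythm.
    """
    if label.label == "pocket":
        return True
    return (
        label.label in ("blend", "other")
        and np.isfinite(label.ke_he_coactivity)
        and label.ke_he_coactivity > 0.5
    )


@dataclass
class ScalingProtocol:
    config: NetworkConfig
    base_drives: DriveSet
    target: str = "all"  # all | E | I
    low: float = 0.95
    high: float = 1.05


def run_scaling(protocol: ScalingProtocol) -> dict:
    """Measure active-phase durations at two uniform input scalings.

    Returns ``{factor: {"label": ..., "t_active": {HE, KE, HF}}}``.
    Raises :class:`ProtocolError` if a factor loses the rhythm.
    """
    out = {}
    for f in (protocol.low, protocol.high):
        drv = protocol.base_drives.scaled(f, protocol.target)
        tr = integrate(protocol.config.with_drives(drv), t_end=3000.0, init="auto")
        lab = classify(tr)
        if lab.label in ("tonic", "quiescent") or not lab.t_active:
            raise ProtocolError(
                f"rhythm lost at scale factor {f} (target {protocol.target})"
            )
        out[f] = {"label": lab.label, "t_active": lab.t_active, "period": lab.period}
    return out


def drop_inhibitory_drive(
    config: NetworkConfig,
    drives: DriveSet,
) -> dict:
    """Remove the external drive to the inhibitory pools mid-rhythm.

    Runs a switch protocol to ``i_IP = i_IR = 0`` from the established
    rhythm and reports whether the synchrony pattern (HE/HF antiphase,
    partner relations) is retained and whether the rostral KE onset
    delay survives (it is expected to be lost: the delay requires the
    inhibitory drive to position the saddle-node wait).
    """
    zeroed = replace(drives, i_ip=0.0, i_ir=0.0)
    res = run_switch(SwitchProtocol(config, drives, zeroed))
    tr = res.trace_after
    ann = detect_phases(tr, pops=["HE", "HF"],
                        t_min=tr.t[0] + 0.5 * (tr.t[-1] - tr.t[0]))
    from .simulate import _coactivity  # shared helper

    co = _coactivity(ann.intervals["HE"], ann.intervals["HF"], ann.span)
    persists = res.after.label not in ("tonic", "quiescent")
    delay_kept = (
        res.before.label == "rostral"
        and res.after.label == "rostral"
        and np.isfinite(res.after.ke_delay)
        and res.after.ke_delay >= 0.05 * res.after.period
    )
    return {
        "label": res.after.label,
        "rhythm_persists": persists,
        "antiphase_coactivity": co,
        "synchrony_retained": persists and co < 0.1,
        "ke_delay_retained": bool(delay_kept),
        "switch": res,
    }


# --- weight calibration ------------------------------------------------------

@dataclass
class CalibrationResult:
    weight_class: str
    seed: int
    weights: dict[tuple[str, str], float]
    checklist: dict[str, bool]
    n_evaluated: int
    accepted: bool
    log: list[dict] = field(default_factory=list)


#: Search boxes (log-uniform).  The interneuron box follows the
#: qualitative constraints; the KE box is wide enough to contain the
#: weight ratios the rostral delay requires.
_IN_BOX = {"ei": (0.8, 2.4), "ie": (0.7, 1.3)}
_KE_BOX = {"EP": (0.02, 0.3), "IP": (0.2, 1.2), "ER": (0.08, 0.8), "IR": (0.8, 2.5)}


def draw_candidate(rng: np.random.Generator) -> dict[tuple[str, str], float]:
    """One log-uniform draw of the free weights (mirror-symmetric layer)."""
    lo, hi = _IN_BOX["ei"]
    ei = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = _IN_BOX["ie"]
    ie = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    ov = {("EP", "IP"): ei, ("ER", "IR"): ei, ("IP", "EP"): ie, ("IR", "ER"): ie}
    for pop, (lo, hi) in _KE_BOX.items():
        ov[(pop, "KE")] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return ov


def _checklist(cfg_builder, weight_class: str, quick: bool) -> dict[str, bool]:
    """Evaluate the acceptance checklist for one candidate network."""
    from .network import baseline_drives, stimulus_drives

    out: dict[str, bool] = {}
    t_end = 2500.0
    base = baseline_drives(weight_class)
    pock = stimulus_drives(weight_class, "pocket")
    rost = stimulus_drives(weight_class, "rostral")

    cfg = cfg_builder()
    tr = integrate(cfg.with_drives(base), t_end=t_end, init="rest")
    from .simulate import detect_oscillation

    out["baseline_quiescent"] = not any(
        detect_oscillation(tr, p)[0] for p in ("HE", "KE", "HF", "EP", "ER")
    )
    lab_p = classify(integrate(cfg.with_drives(pock), t_end=t_end, init="auto"))
    lab_r = classify(integrate(cfg.with_drives(rost), t_end=t_end, init="auto"))
    out["pocket_label"] = lab_p.label == "pocket"
    out["rostral_label"] = lab_r.label == "rostral"
    w = cfg.weight_lookup()
    out["ke_ordering"] = (
        w[("ER", "KE")] > w[("EP", "KE")] and w[("IR", "KE")] > w[("IP", "KE")]
    )
    if not quick and all(out.values()):
        # minimality proxy: weakening any single interneuron-layer weight
        # by 30% must destroy at least one rhythm
        in_edges = [("EP", "IP"), ("ER", "IR"), ("IP", "EP"), ("IR", "ER")]
        fragile = True
        for e in in_edges:
            cfg_w = cfg_builder(overrides={e: w[e] * 0.7})
            ok_p = classify(
                integrate(cfg_w.with_drives(pock), t_end=t_end, init="auto")
            ).label == "pocket"
            ok_r = classify(
                integrate(cfg_w.with_drives(rost), t_end=t_end, init="auto")
            ).label == "rostral"
            if ok_p and ok_r:
                fragile = False
                break
        out["minimal_weights"] = fragile
    return out


def calibrate_weights(
    weight_class: str = "S",
    seed: int = 1,
    n_candidates: int = 200,
    include_default: bool = True,
    quick: bool = False,
) -> CalibrationResult:
    """Seeded constrained search for a weight set supporting both rhythms.

    Candidates are drawn log-uniformly from documented boxes around the
    architecture's qualitative constraints (reciprocal inhibition strong
    enough to silence a partner, rostral-side KE weights dominant).  A
    candidate is accepted when the full checklist passes: baseline
    quiescence from rest, correct pocket and rostral labels under the
    standard stimulus drives, the KE weight ordering, and (unless
    ``quick``) the minimality proxy that weakening any interneuron-layer
    weight by 30% breaks a rhythm.

    With ``include_default`` the shipped calibrated set is evaluated
    first, making the search a reproducible re-derivation of the
    defaults rather than a cold lottery.
    """
    rng = np.random.default_rng(seed)
    log: list[dict] = []

    candidates: list[dict | None] = []
    if include_default:
        candidates.append(None)  # shipped defaults
    candidates += [draw_candidate(rng) for _ in range(n_candidates)]

    n_eval = 0
    for ov in candidates:
        def builder(overrides=None, ov=ov):
            merged = dict(ov or {})
            if overrides:
                merged.update(overrides)
            return build_network(weight_class, overrides=merged or None)

        try:
            cl = _checklist(builder, weight_class, quick)
        except (InsufficientDataError, ProtocolError):
            cl = {"error": False}
        n_eval += 1
        entry = {"candidate": ov, "checklist": cl}
        log.append(entry)
        if cl and all(cl.values()):
            cfg = builder()
            return CalibrationResult(
                weight_class=weight_class,
                seed=seed,
                weights=cfg.weight_lookup(),
                checklist=cl,
                n_evaluated=n_eval,
                accepted=True,
                log=log,
            )
    best = max(log, key=lambda e: sum(bool(v) for v in e["checklist"].values()))
    return CalibrationResult(
        weight_class=weight_class,
        seed=seed,
        weights=build_network(weight_class, overrides=best["candidate"]).weight_lookup()
        if best["candidate"] is not None
        else build_network(weight_class).weight_lookup(),
        checklist=best["checklist"],
        n_evaluated=n_eval,
        accepted=False,
        log=log,
    )
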