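"""Network integration, phase detection and rhythm classification.

Protocol conventions
--------------------
Rhythms are *elicited*: a simulation models the onset of scratch
stimulation as a brief activation of the stimulated side's interneuron
pair on top of the tonic drive set.  With ``init="auto"`` the side whose
excitatory pool receives the stronger drive is kicked; with symmetric
(baseline) drives no side is stimulated and the network starts from
rest, where it settles into non-oscillating tonic activity.  The kick
determines which attractor is reached, not whether one exists: rhythm
attractors coexist with the tonic state over a range of drives, which is
what the input-switching and bistability experiments exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import pa_transform, sigmoid_gate, tau_h_rate
from .network import INTERNEURONS, MOTONEURONS, POPULATIONS, NetworkConfig

__all__ = [
    "Trace",
    "PhaseAnnotation",
    "RhythmLabel",
    "IntegrationError",
    "InsufficientDataError",
    "integrate",
    "detect_phases",
    "classify_rhythm",
    "detect_oscillation",
    "rest_state",
    "kick_state",
]

_IDX = {p: i for i, p in enumerate(POPULATIONS)}

#: Default simulation span (ms).
DEFAULT_T_END = 20_000.0
#: Silent-phase rest state per population (V, h, s).
_REST = (-60.0, 0.7, 0.0)
#: Transiently activated state for the stimulated pools.
_KICK = (-20.0, 0.6, 0.9)


class IntegrationError(RuntimeError):
    def __init__(self, msg: str, last_valid_time: float):
        super().__init__(f"{msg} (last valid time {last_valid_time:.3f} ms)")
        self.last_valid_time = last_valid_time


class InsufficientDataError(RuntimeError):
    """Too few periods to support the requested classification."""


@dataclass
class Trace:
    """Simulated time series of the full network."""

    t: np.ndarray
    v: dict[str, np.ndarray]
    h: dict[str, np.ndarray]
    s: dict[str, np.ndarray]
    config: NetworkConfig
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace time grid must be strictly increasing")
        for d in (self.v, self.h, self.s):
            for p, arr in d.items():
                if len(arr) != len(self.t):
                    raise ValueError(f"array length mismatch for {p}")

    def pa(self, pop: str) -> np.ndarray:
        return pa_transform(self.v[pop])

    def to_frame(self):
        """Long-format table (t plus V/h/s/PA per population)."""
        import pandas as pd

        cols = {"t": self.t}
        for p in self.v:
            cols[f"V_{p}"] = self.v[p]
            cols[f"h_{p}"] = self.h[p]
            cols[f"s_{p}"] = self.s[p]
            cols[f"PA_{p}"] = self.pa(p)
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df, config: NetworkConfig | None = None) -> "Trace":
        pops = [c[2:] for c in df.columns if c.startswith("V_")]
        return cls(
            t=df["t"].to_numpy(),
            v={p: df[f"V_{p}"].to_numpy() for p in pops},
            h={p: df[f"h_{p}"].to_numpy() for p in pops},
            s={p: df[f"s_{p}"].to_numpy() for p in pops},
            config=config,
        )


def rest_state() -> np.ndarray:
    return np.tile(_REST, len(POPULATIONS))


def kick_state(side: str) -> np.ndarray:
    """Rest state with the stimulated side's interneuron pair activated."""
    y0 = rest_state()
    pops = ("EP", "IR") if side == "pocket" else ("ER", "IP")
    for p in pops:
        k = 3 * _IDX[p]
        y0[k : k + 3] = _KICK
    return y0


def _rhs_factory(config: NetworkConfig) -> Callable:
    p = config.params
    w_inh, w_exc = config.weight_matrices()
    drv = config.drives.vector()
    e_inh, e_exc = p.e_syn_inh, p.e_syn_exc
    m, hg, sg = p.m_gate, p.h_gate, p.s_gate

    def rhs(t, y):
        v = y[0::3]
        h = y[1::3]
        s = y[2::3]
        i_syn = (w_inh @ s) * (v - e_inh) + (w_exc @ s) * (v - e_exc)
        i_nap = p.g_nap * sigmoid_gate(v, m) * h * (v - p.e_na)
        i_leak = p.g_leak * (v - p.e_leak)
        dv = (-i_nap - i_leak - i_syn - drv * (v - e_exc)) / p.c_m
        dh = (sigmoid_gate(v, hg) - h) * tau_h_rate(v, p)
        ds = p.alpha * (1.0 - s) * sigmoid_gate(v, sg) - p.beta * s
        out = np.empty_like(y)
        out[0::3] = dv
        out[1::3] = dh
        out[2::3] = ds
        return out

    return rhs


def integrate(
    config: NetworkConfig,
    t_end: float = DEFAULT_T_END,
    init: str | np.ndarray = "auto",
    t_start: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    max_step: float = 5.0,
    dense: bool = False,
):
    """Integrate the full network ODEs.

    ``init`` is ``"rest"``, ``"pocket"``/``"rostral"`` (stimulated-side
    kick), ``"auto"`` (kick the side with the stronger excitatory drive,
    rest if drives are symmetric) or an explicit state vector.  A stiff-
    capable scheme with tight tolerances is required; the near-Heaviside
    synaptic activation makes the system stiff.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if isinstance(init, str):
        if init == "auto":
            side = config.drives.stimulated_side
            y0 = kick_state(side) if side else rest_state()
        elif init == "rest":
            y0 = rest_state()
        elif init in ("pocket", "rostral"):
            y0 = kick_state(init)
        else:
            raise ValueError(f"unknown init {init!r}")
    else:
        y0 = np.asarray(init, dtype=float)

    sol = solve_ivp(
        _rhs_factory(config),
        (t_start, t_end),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
        dense_output=dense,
    )
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else t_start)
    trace = Trace(
        t=sol.t,
        v={p: sol.y[3 * _IDX[p]] for p in POPULATIONS},
        h={p: sol.y[3 * _IDX[p] + 1] for p in POPULATIONS},
        s={p: sol.y[3 * _IDX[p] + 2] for p in POPULATIONS},
        config=config,
        meta={"method": method, "rtol": rtol, "atol": atol},
    )
    return (trace, sol) if dense else trace


# --- phase detection ---------------------------------------------------------

@dataclass
class PhaseAnnotation:
    """Active intervals per population, from threshold crossings of PA."""

    intervals: dict[str, list[tuple[float, float]]]
    threshold: float
    span: tuple[float, float]

    def durations(self, pop: str) -> np.ndarray:
        return np.array([b - a for a, b in self.intervals[pop]])

    def t_active(self, pop: str) -> float:
        """Mean active-phase duration T_active of a population (ms)."""
        durs = self.durations(pop)
        if len(durs) == 0:
            return 0.0
        # drop first/last (possibly clipped by the window)
        core = durs[1:-1] if len(durs) > 2 else durs
        return float(np.mean(core))

    def period(self, pop: str = "HE") -> float:
        ons = [a for a, _ in self.intervals[pop]]
        if len(ons) < 2:
            raise InsufficientDataError(f"{pop} has fewer than 2 onsets")
        return float(np.mean(np.diff(ons)))

    def n_periods(self, pop: str = "HE") -> int:
        return max(0, len(self.intervals[pop]) - 1)


def _crossings(t: np.ndarray, x: np.ndarray, thr: float):
    above = x > thr
    idx = np.nonzero(np.diff(above.astype(int)))[0]
    times = []
    for i in idx:
        # linear interpolation of the crossing time
        t0, t1 = t[i], t[i + 1]
        x0, x1 = x[i], x[i + 1]
        tc = t0 + (thr - x0) * (t1 - t0) / (x1 - x0)
        times.append((tc, bool(above[i + 1])))
    return times


def detect_phases(
    trace: Trace,
    threshold: float = 0.5,
    pops: Sequence[str] | None = None,
    t_min: float | None = None,
) -> PhaseAnnotation:
    """Locate active intervals where PA(V) exceeds ``threshold``.

    Onsets/offsets are interpolated linearly between samples.  An
    interval open at either end of the analysis window is closed at the
    window edge.
    """
    pops = list(pops or trace.v.keys())
    t = trace.t
    lo = t[0] if t_min is None else t_min
    sel = t >= lo
    tt = t[sel]
    intervals: dict[str, list[tuple[float, float]]] = {}
    for p in pops:
        a = trace.pa(p)[sel]
        cr = _crossings(tt, a, threshold)
        iv: list[tuple[float, float]] = []
        open_on = tt[0] if a[0] > threshold else None
        for tc, rising in cr:
            if rising:
                open_on = tc
            elif open_on is not None:
                iv.append((open_on, tc))
                open_on = None
        if open_on is not None:
            iv.append((open_on, tt[-1]))
        intervals[p] = iv
    return PhaseAnnotation(intervals=intervals, threshold=threshold, span=(tt[0], tt[-1]))


# --- rhythm classification ---------------------------------------------------

@dataclass
class RhythmLabel:
    """Classification of a motoneuron rhythm.

    ``label`` is one of pocket / rostral / blend / tonic / quiescent /
    other.  Timing features are cycle averages in ms; the KE onset delay
    is measured from the preceding HF onset, and the terminal overlap is
    the co-active time between KE onset and the end of the HF phase
    (positive in pocket, where KE fires up during the last part of HF).
    """

    label: str
    period: float = float("nan")
    ke_delay: float = float("nan")
    ke_hf_overlap: float = float("nan")
    ke_he_coactivity: float = float("nan")
    t_active: dict[str, float] = field(default_factory=dict)
    cycle_labels: list[str] = field(default_factory=list)


def _nearest(value: float, candidates: Sequence[float]) -> float | None:
    if not candidates:
        return None
    return min(candidates, key=lambda c: abs(c - value))


def _coactivity(iv_a, iv_b, span) -> float:
    """Fraction of a's active time also covered by b."""
    grid = np.linspace(span[0], span[1], 4000)
    in_a = np.zeros_like(grid, dtype=bool)
    in_b = np.zeros_like(grid, dtype=bool)
    for a, b in iv_a:
        in_a |= (grid >= a) & (grid <= b)
    for a, b in iv_b:
        in_b |= (grid >= a) & (grid <= b)
    denom = in_a.mean()
    return float((in_a & in_b).mean() / denom) if denom > 0 else 0.0


def classify_rhythm(
    annotation: PhaseAnnotation,
    delta_min_frac: float = 0.05,
    offset_tol_frac: float = 0.15,
) -> RhythmLabel:
    """Label the motoneuron pattern of an annotated simulation.

    Cycle-wise rules (one cycle per KE activation, referenced to the
    surrounding HF/HE onsets):

    * ``pocket``: KE activates during the terminal part of HF activity
      (before the HE onset), stays active through the HE phase, and
      deactivates when HF takes over -- KE co-active with HE.
    * ``rostral``: KE onset is delayed at least ``delta_min_frac`` of a
      period after the HF onset, KE offset coincides with the HF offset
      (within ``offset_tol_frac`` of the HF phase), and KE is silent
      throughout HE activity.
    * ``blend``: both cycle types (or mixed-feature cycles) occur.
    * ``tonic`` / ``quiescent``: no oscillation, population pinned
      active / silent.
    """
    ivH = annotation.intervals.get("HE", [])
    ivF = annotation.intervals.get("HF", [])
    ivK = annotation.intervals.get("KE", [])
    span = annotation.span

    def pinned(iv):  # whole-window interval or nothing
        if not iv:
            return "quiescent"
        if len(iv) == 1 and np.isclose(iv[0][0], span[0]) and np.isclose(iv[0][1], span[1]):
            return "tonic"
        return None

    hip_state = pinned(ivH) or pinned(ivF)
    if len(ivH) < 3 or len(ivF) < 3:
        if hip_state:
            return RhythmLabel(label=hip_state)
        raise InsufficientDataError("fewer than 3 hip activation cycles in window")

    period = annotation.period("HE")
    t_act = {p: annotation.t_active(p) for p in ("HE", "HF", "KE") if p in annotation.intervals}
    co_ke_he = _coactivity(ivK, ivH, span)

    if len(ivK) < 3:
        lab = "quiescent" if not ivK else ("tonic" if pinned(ivK) == "tonic" else "other")
        return RhythmLabel(label=lab, period=period, t_active=t_act,
                           ke_he_coactivity=co_ke_he)

    hf_ons = [a for a, _ in ivF]
    hf_offs = [b for _, b in ivF]
    he_ons = [a for a, _ in ivH]

    # drop only intervals clipped by the analysis window
    eps = 1e-9
    ke_core = [(a, b) for a, b in ivK
               if a > span[0] + eps and b < span[1] - eps]
    cycle_labels: list[str] = []
    delays: list[float] = []
    overlaps: list[float] = []
    for ko, kf in ke_core:
        hf_on = _nearest(ko, hf_ons)
        hf_off = _nearest(kf, hf_offs)
        he_on = _nearest(ko, [h for h in he_ons])
        if hf_on is None or hf_off is None or he_on is None:
            cycle_labels.append("other")
            continue
        delay = ko - hf_on
        delays.append(delay)
        # terminal overlap: KE on before the HF phase containing/preceding it ends
        nxt_hf_off = min((b for _, b in ivF if b > ko), default=None)
        ovl = (nxt_hf_off - ko) if (nxt_hf_off is not None and nxt_hf_off < kf) else 0.0
        overlaps.append(ovl)
        # pocket onset happens during the *terminal* part of the HF
        # phase: the overlap must be small (< half the HF phase); an
        # activation near the middle of HF that then runs through HE is
        # a transitional (blend) cycle, not a pocket cycle
        t_hf = max(t_act.get("HF", 1.0), 1e-9)
        pocket_like = (
            (ko < he_on)
            and (kf > he_on)
            and abs(kf - hf_off) > offset_tol_frac * t_hf
            and 0.0 < ovl < 0.5 * t_hf
        )
        rostral_like = (
            delay >= delta_min_frac * period
            and abs(kf - hf_off) <= offset_tol_frac * max(t_act.get("HF", 1.0), 1e-9)
        )
        if pocket_like and not rostral_like:
            cycle_labels.append("pocket")
        elif rostral_like and not pocket_like:
            cycle_labels.append("rostral")
        else:
            cycle_labels.append("blend")

    kinds = set(cycle_labels)
    if kinds <= {"pocket"}:
        label = "pocket"
    elif kinds <= {"rostral"}:
        label = "rostral"
    elif kinds and kinds <= {"pocket", "rostral", "blend"}:
        label = "blend"
    else:
        label = "other"
    # a rostral label requires KE silence during HE activity
    if label == "rostral" and co_ke_he > 0.1:
        label = "other"
    return RhythmLabel(
        label=label,
        period=period,
        ke_delay=float(np.mean(delays)) if delays else float("nan"),
        ke_hf_overlap=float(np.mean(overlaps)) if overlaps else float("nan"),
        ke_he_coactivity=co_ke_he,
        t_active=t_act,
        cycle_labels=cycle_labels,
    )


def detect_oscillation(
    trace: Trace,
    pop: str,
    transient_frac: float = 0.25,
    threshold: float = 0.5,
    min_range: float = 0.5,
) -> tuple[bool, float]:
    """Decide whether a population oscillates after the initial transient.

    Oscillating means the post-transient PA range exceeds ``min_range``
    and at least two full threshold crossings occur.  Returns
    ``(oscillating, amplitude)``.
    """
    t = trace.t
    n0 = np.searchsorted(t, t[0] + (t[-1] - t[0]) * transient_frac)
    a = trace.pa(pop)[n0:]
    amp = float(a.max() - a.min())
    crossings = _crossings(t[n0:], a, threshold)
    return (amp > min_range and len(crossings) >= 2), amp


def classify(trace: Trace, settle_frac: float = 0.5, **kwargs) -> RhythmLabel:
    """Convenience: detect phases on the settled part of a trace and classify."""
    t0 = trace.t[0] + (trace.t[-1] - trace.t[0]) * settle_frac
    ann = detect_phases(trace, t_min=t0, pops=list(MOTONEURONS) + list(INTERNEURONS))
    return classify_rhythm(ann, **kwargs)
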