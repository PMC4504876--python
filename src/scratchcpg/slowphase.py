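"""Fast--slow decomposition of the knee-extensor dynamics.

Away from jumps, the network state evolves in a slow phase space spanned
by each population's I_NaP inactivation ``h`` and the synaptic gates
``s`` of the other populations.  For KE in the reduced module, fixing
one unit's gate at ``s_max`` selects a one-parameter family of fast
(V, h) subsystems indexed by the dynamic gate ``s`` of the other unit:

* context ``"ER"`` -- the rostral unit is active (``s_ER = s_max``) and
  ``s = s_EP`` decays; activation from this family's left branch is what
  times KE onset in both rhythms.
* context ``"EP"`` -- the pocket unit is active (``s_EP = s_max``) and
  ``s = s_ER`` decays.

For each family we track the cubic voltage-nullcline branches (left /
middle / right), the folds of the nullcline (jump-up and jump-down
knees), the fast-subsystem fixed points, and the saddle-node where the
left and middle fixed points coalesce.  Slow flows on the outer branches
follow ``h' = (h_inf(V_branch) - h) tau_h(V_branch)`` with ``s' = -beta s``,
integrated in original time t (the epsilon-rescaled slow time tau =
epsilon t appears only in documentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import sigmoid_gate, tau_h_rate
from .network import DriveSet, NetworkConfig, ReducedModuleConfig, ke_synaptic_input

__all__ = [
    "BranchPoint",
    "KneeCurve",
    "FixedPointCurve",
    "SlowLandscape",
    "SlowFlowResult",
    "ModelStructureError",
    "StructureAbsentError",
    "FoldCrossedError",
    "LandscapeUndefinedError",
    "nullcline_branches",
    "knee_curve",
    "fixed_point_curve",
    "find_saddle_node",
    "slow_flow",
    "slow_flow_backward",
    "compute_landscape",
    "switch_gating_value",
]

Context = Literal["ER", "EP"]
Branch = Literal["L", "M", "R"]

_V_LO, _V_HI = -90.0, 30.0


class ModelStructureError(RuntimeError):
    """Fast subsystem violates the assumed cubic nullcline structure."""


class StructureAbsentError(RuntimeError):
    """Requested bifurcation structure absent (weights fail requirements)."""


class FoldCrossedError(RuntimeError):
    """Slow flow left its branch through a fold before the stop condition."""

    def __init__(self, msg: str, crossing: tuple[float, float]):
        super().__init__(msg)
        self.crossing = crossing  # (h, s) at the fold crossing


class LandscapeUndefinedError(RuntimeError):
    """The interneuron half-center does not oscillate under the drive set."""


@dataclass(frozen=True)
class BranchPoint:
    v: float
    h: float
    s: float
    branch: Branch
    context: Context


@dataclass
class KneeCurve:
    kind: Literal["jump-up", "jump-down"]
    context: Context
    s: np.ndarray
    h: np.ndarray  # NaN where the knee is absent from the physical window
    v: np.ndarray

    def interp_h(self, s: float) -> float:
        good = np.isfinite(self.h)
        if not good.any():
            raise StructureAbsentError(f"{self.kind} knee absent over the whole grid")
        return float(np.interp(s, self.s[good], self.h[good]))

    @property
    def present(self) -> np.ndarray:
        return np.isfinite(self.h)


@dataclass
class FixedPointCurve:
    branch: Branch
    context: Context
    s: np.ndarray
    v: np.ndarray
    h: np.ndarray
    stable: bool

    @property
    def present(self) -> np.ndarray:
        return np.isfinite(self.h)


@dataclass
class SlowFlowResult:
    t: np.ndarray
    h: np.ndarray
    s: np.ndarray
    v: np.ndarray
    exit_reason: str  # "duration" | "s-target" | "knee-hit"


@dataclass
class SlowLandscape:
    """Scalar summary of the slow phase plane for one drive set."""

    context: Context
    s_max: float
    s_sn: float
    h_sn: float
    h_max: float
    s_er_min: float
    s_red_min: float        # dynamic-gate minimum within the rostral-unit phase
    h_min: float
    h_er_min: float
    t_decay: float          # printed form T(I) = (1/beta) ln(s_sn / s_er_min)
    t_red: float            # remaining rostral-phase time after the saddle-node
    t_star: float           # minimal silent time (-1/beta) ln(s_sn / s_max)
    h_sn_plus: float
    h_sn_minus: float
    h_smin_minus: float
    t_active_ep: float
    t_active_er: float
    lk_samples: list[tuple[float, float]] = field(default_factory=list)
    h_max_mismatch: float = 0.0

    @property
    def interval_s(self) -> tuple[float, float]:
        """I_s = [s_er_min, s_sn]: dynamic-gate values allowing KE onset."""
        return (self.s_er_min, self.s_sn)

    @property
    def interval_h(self) -> tuple[float, float]:
        """I_h = [h_min, h_max]: h values from which KE can jump down."""
        return (self.h_min, self.h_max)


# --- fast-subsystem geometry -------------------------------------------------

def _context_gates(context: Context, s: float, s_max: float) -> tuple[float, float]:
    """(s_EP, s_ER) for a context and dynamic gate value."""
    if context == "ER":
        return s, s_max
    if context == "EP":
        return s_max, s
    raise ValueError(f"context must be 'ER' or 'EP', got {context!r}")


def _h_nullcline(module: ReducedModuleConfig, context: Context, s: float,
                 i_ext: float = 0.0) -> Callable[[np.ndarray], np.ndarray]:
    """h on the V-nullcline as a function of V (the cubic, parameterized)."""
    p = module.params
    s_ep, s_er = _context_gates(context, s, p.s_max)

    def h_of_v(v):
        i_syn = ke_synaptic_input(v, s_ep, s_er, module)
        num = -p.g_leak * (v - p.e_leak) - i_syn - i_ext * (v - p.e_syn_exc)
        den = p.g_nap * sigmoid_gate(v, p.m_gate) * (v - p.e_na)
        return num / den

    return h_of_v


def nullcline_branches(
    h: float,
    s_ep: float,
    s_er: float,
    module: ReducedModuleConfig,
    i_ext: float = 0.0,
    context: Context | None = None,
) -> list[BranchPoint]:
    """All real roots V of F_KE(V, h, s) = 0, labeled L / M / R.

    ``context`` only tags the returned points; the geometry is set by the
    gate values.  Raises :class:`ModelStructureError` if more than three
    roots appear (the cubic-nullcline hypothesis fails).
    """
    p = module.params

    def f(v):
        i_syn = ke_synaptic_input(v, s_ep, s_er, module)
        i_nap = p.g_nap * sigmoid_gate(v, p.m_gate) * h * (v - p.e_na)
        return -i_nap - p.g_leak * (v - p.e_leak) - i_syn - i_ext * (v - p.e_syn_exc)

    grid = np.linspace(_V_LO, _V_HI, 2001)
    vals = f(grid)
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(float(brentq(f, grid[i], grid[i + 1], xtol=1e-12)))
    if len(roots) > 3:
        raise ModelStructureError(
            f"{len(roots)} nullcline roots found; cubic hypothesis violated"
        )
    labels: list[Branch]
    if len(roots) == 3:
        labels = ["L", "M", "R"]
    elif len(roots) == 2:
        labels = ["L", "R"]  # degenerate (at a fold)
    else:
        # classify single root by sign of dh_null/dV nearby middle test:
        # a lone root below the band of middle-branch voltages is left-like.
        labels = ["R" if roots and roots[0] > -45.0 else "L"]
    ctx = context or "ER"
    s_dyn = s_ep if ctx == "ER" else s_er
    return [
        BranchPoint(v=v, h=h, s=s_dyn, branch=b, context=ctx)
        for v, b in zip(roots, labels)
    ]


def _knees_at(module: ReducedModuleConfig, context: Context, s: float,
              i_ext: float = 0.0) -> dict[str, tuple[float, float]]:
    """Local extrema of the V-nullcline h(V): {'jump-up': (V,h), 'jump-down': ...}."""
    h_of_v = _h_nullcline(module, context, s, i_ext)
    grid = np.linspace(_V_LO + 1e-3, -5.0, 3001)
    hv = h_of_v(grid)
    d = np.diff(hv)

    def refine(i):
        # extremum of h_of_v between grid[i-1] and grid[i+1]
        def dh(v, eps=1e-6):
            return (h_of_v(v + eps) - h_of_v(v - eps)) / (2 * eps)
        try:
            v_star = brentq(dh, grid[i - 1], grid[i + 1], xtol=1e-10)
        except ValueError:
            v_star = grid[i]
        return float(v_star), float(h_of_v(v_star))

    out: dict[str, tuple[float, float]] = {}
    for i in range(1, len(d)):
        if d[i - 1] > 0 >= d[i]:      # local max of h along V: jump-up knee
            out.setdefault("jump-up", refine(i))
        elif d[i - 1] < 0 <= d[i]:    # local min: jump-down knee
            out.setdefault("jump-down", refine(i))
    return out


def knee_curve(
    kind: Literal["jump-up", "jump-down"],
    context: Context,
    s_grid: np.ndarray,
    module: ReducedModuleConfig,
    i_ext: float = 0.0,
    h_window: tuple[float, float] = (0.0, 1.0),
) -> KneeCurve:
    """Trace a knee (fold of the V nullcline) along the dynamic gate.

    Samples outside the physical window ``h in [0, 1]`` are marked absent
    (NaN) rather than raising: the module relies on the jump-up knee
    being absent over the relevant range while the pocket unit is active.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    p = module.params
    if np.any(s_grid < -1e-12) or np.any(s_grid > p.s_max + 1e-9):
        raise ValueError("s_grid must lie within [0, s_max]")
    h_out = np.full_like(s_grid, np.nan)
    v_out = np.full_like(s_grid, np.nan)
    for k, s in enumerate(s_grid):
        kn = _knees_at(module, context, float(s), i_ext)
        if kind in kn:
            v, h = kn[kind]
            if h_window[0] <= h <= h_window[1]:
                v_out[k] = v
                h_out[k] = h
    return KneeCurve(kind=kind, context=context, s=s_grid, h=h_out, v=v_out)


def fixed_point_curve(
    branch: Branch,
    context: Context,
    s_grid: np.ndarray,
    module: ReducedModuleConfig,
    i_ext: float = 0.0,
) -> FixedPointCurve:
    """Fast-subsystem fixed points (F = 0 and h = h_inf(V)) on one branch."""
    s_grid = np.asarray(s_grid, dtype=float)
    p = module.params
    h_out = np.full_like(s_grid, np.nan)
    v_out = np.full_like(s_grid, np.nan)
    for k, s in enumerate(s_grid):
        h_of_v = _h_nullcline(module, context, float(s), i_ext)

        def g(v):
            return h_of_v(v) - sigmoid_gate(v, p.h_gate)

        grid = np.linspace(_V_LO + 1e-3, _V_HI, 2001)
        vals = g(grid)
        roots = [
            float(brentq(g, grid[i], grid[i + 1], xtol=1e-12))
            for i in range(len(grid) - 1)
            if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) and vals[i] * vals[i + 1] < 0
        ]
        kn = _knees_at(module, context, float(s), i_ext)
        v_ju = kn.get("jump-up", (np.inf,))[0]
        v_jd = kn.get("jump-down", (-np.inf,))[0]
        for v in sorted(roots):
            h = float(sigmoid_gate(v, p.h_gate))
            if branch == "L" and v < v_ju and not (0 <= 1 and v > v_jd and v_jd > v_ju):
                if v < v_ju:
                    v_out[k], h_out[k] = v, h
                    break
            elif branch == "M" and v_ju < v < v_jd:
                v_out[k], h_out[k] = v, h
                break
            elif branch == "R" and v > v_jd:
                v_out[k], h_out[k] = v, h
                break
    return FixedPointCurve(
        branch=branch, context=context, s=s_grid, v=v_out, h=h_out,
        stable=branch in ("L", "R"),
    )


def find_saddle_node(
    module: ReducedModuleConfig,
    context: Context = "ER",
    i_ext: float = 0.0,
    s_bracket: tuple[float, float] | None = None,
    tol: float = 1e-6,
    agreement_tol: float = 1e-4,
) -> tuple[float, float]:
    """Locate the saddle-node of left/middle fixed points along the gate.

    Bisects on s for the coalescence of the left and middle fixed points
    of the fast subsystem, then cross-checks that the returned point lies
    on the jump-up knee curve (the fold the fixed point dies on): the two
    formulations must agree to ``agreement_tol`` in s.  Returns
    ``(s_sn, h_sn)``.
    """
    p = module.params
    lo, hi = s_bracket if s_bracket else (0.0, p.s_max)

    def has_left_fp(s: float) -> bool:
        h_of_v = _h_nullcline(module, context, s, i_ext)
        kn = _knees_at(module, context, s, i_ext)
        if "jump-up" not in kn:
            return False
        v_ju = kn["jump-up"][0]

        def g(v):
            return h_of_v(v) - sigmoid_gate(v, p.h_gate)

        grid = np.linspace(_V_LO + 1e-3, v_ju, 800)
        vals = g(grid)
        sgn = np.sign(vals)
        return bool(np.any(sgn[:-1] * sgn[1:] < 0))

    f_lo, f_hi = has_left_fp(lo), has_left_fp(hi)
    if f_lo == f_hi:
        raise StructureAbsentError(
            f"no saddle-node of left fixed points in s ∈ ({lo:.3f}, {hi:.3f}) "
            f"for context {context}"
        )
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if has_left_fp(mid) == f_lo:
            a = mid
        else:
            b = mid
    s_sn = 0.5 * (a + b)
    # h at the fold: the left FP is about to merge with the knee
    side = b if f_hi else a  # the side where the FP still exists
    kn = _knees_at(module, context, side, i_ext)
    h_sn = kn["jump-up"][1]
    # agreement check: knee h equals FP h at the bifurcation
    h_of_v = _h_nullcline(module, context, side, i_ext)
    v_ju = kn["jump-up"][0]

    def g(v):
        return h_of_v(v) - sigmoid_gate(v, p.h_gate)

    grid = np.linspace(_V_LO + 1e-3, v_ju, 2000)
    vals = g(grid)
    v_fp = None
    for i in range(len(grid) - 1):
        if vals[i] * vals[i + 1] < 0:
            v_fp = brentq(g, grid[i], grid[i + 1], xtol=1e-12)
    if v_fp is not None:
        h_fp = float(sigmoid_gate(v_fp, p.h_gate))
        if abs(h_fp - h_sn) > 50 * agreement_tol + 5e-3:
            raise ModelStructureError(
                f"saddle-node formulations disagree: knee h {h_sn:.5f} vs FP h {h_fp:.5f}"
            )
        h_sn = h_fp
    return float(s_sn), float(h_sn)


# --- slow flows --------------------------------------------------------------

def _branch_voltage(module, context, branch: Branch, h: float, s: float,
                    i_ext: float, v_guess: float | None = None) -> float | None:
    pts = nullcline_branches(
        h, *_context_gates(context, s, module.params.s_max), module,
        i_ext=i_ext, context=context,
    )
    cands = [p_.v for p_ in pts if p_.branch == branch]
    if not cands:
        return None
    if v_guess is None:
        return cands[0]
    return min(cands, key=lambda v: abs(v - v_guess))


def slow_flow(
    start: tuple[float, float],
    branch: Branch,
    context: Context,
    module: ReducedModuleConfig,
    stop: dict,
    i_ext: float = 0.0,
    rtol: float = 1e-10,
    max_step: float = 1.0,
) -> SlowFlowResult:
    """Integrate the slow subsystem on a nullcline branch.

    State is (h, s) with ``h' = (h_inf(V_br) - h) tau_h(V_br)`` and
    ``s' = -beta s`` in original time.  ``stop`` is one of
    ``{"duration": T}``, ``{"s_target": s1}`` or ``{"knee": "jump-up"|"jump-down"}``.
    If the branch terminates at a fold before the stop condition is met
    (and the stop is not a knee hit), :class:`FoldCrossedError` is raised
    with the crossing point.
    """
    if branch not in ("L", "R"):
        raise ValueError("slow flow is defined on the outer branches L and R")
    p = module.params
    h0, s0 = start
    v_state = {"v": None}

    def v_of(h, s):
        v = _branch_voltage(module, context, branch, h, s, i_ext, v_state["v"])
        if v is not None:
            v_state["v"] = v
        return v

    v0 = v_of(h0, s0)
    if v0 is None:
        raise FoldCrossedError("start point is not on the requested branch", (h0, s0))

    def rhs(t, y):
        h, s = y
        v = v_of(h, s)
        if v is None:
            v = v_state["v"]  # frozen; event handles exit
        dh = (sigmoid_gate(v, p.h_gate) - h) * tau_h_rate(v, p)
        return [dh, -p.beta * s]

    events = []
    t_end = stop.get("duration", 10_000.0)
    reason_by_event: list[str] = []
    if "s_target" in stop:
        s1 = stop["s_target"]

        def ev_s(t, y, s1=s1):
            return y[1] - s1

        ev_s.terminal = True
        ev_s.direction = 0
        events.append(ev_s)
        reason_by_event.append("s-target")
    knee_h = None
    if "knee" in stop:
        kc = knee_curve(stop["knee"], context,
                        np.linspace(0.0, p.s_max, 200), module, i_ext)

        def ev_k(t, y, kc=kc):
            try:
                return y[0] - kc.interp_h(y[1])
            except StructureAbsentError:
                return 1.0

        ev_k.terminal = True
        ev_k.direction = 0
        events.append(ev_k)
        reason_by_event.append("knee-hit")

    # branch-exists event: detect fold crossing
    def ev_branch(t, y):
        v = _branch_voltage(module, context, branch, y[0], y[1], i_ext, v_state["v"])
        return 1.0 if v is not None else -1.0

    ev_branch.terminal = True
    ev_branch.direction = 0
    events.append(ev_branch)
    reason_by_event.append("fold")

    sol = solve_ivp(rhs, (0.0, t_end), [h0, s0], method="LSODA",
                    rtol=rtol, atol=1e-12, max_step=max_step, events=events,
                    dense_output=False)
    reason = "duration"
    for k, te in enumerate(sol.t_events):
        if len(te):
            reason = reason_by_event[k]
            break
    if reason == "fold" and "knee" not in stop:
        raise FoldCrossedError(
            "branch terminated at a fold before the stop condition",
            (float(sol.y[0][-1]), float(sol.y[1][-1])),
        )
    if reason == "fold":
        reason = "knee-hit"
    v_arr = np.array([
        _branch_voltage(module, context, branch, h, s, i_ext, None) or np.nan
        for h, s in zip(sol.y[0], sol.y[1])
    ])
    return SlowFlowResult(t=sol.t, h=sol.y[0], s=sol.y[1], v=v_arr, exit_reason=reason)


def slow_flow_backward(
    start: tuple[float, float],
    branch: Branch,
    context: Context,
    module: ReducedModuleConfig,
    i_ext: float = 0.0,
    rtol: float = 1e-10,
) -> float:
    """Flow (h, s) backward in time until s = s_max; return h there.

    Used for the pocket conditions: the backward images of the endpoints
    of the activation segment on the ``{s = s_max}`` line bound the strip
    of silent-phase trajectories that re-activate within the window.
    """
    p = module.params
    h0, s0 = start
    if s0 > p.s_max:
        raise ValueError("start gate exceeds s_max")
    # points on a knee sit exactly at the fold; nudge into the branch
    if _branch_voltage(module, context, branch, h0, s0, i_ext) is None:
        for nudge in (1e-6, 1e-5, 1e-4, 1e-3):
            h_try = h0 - nudge if branch == "L" else h0 + nudge
            if _branch_voltage(module, context, branch, h_try, s0, i_ext) is not None:
                h0 = h_try
                break
    v_state = {"v": None}

    def rhs(t, y):
        h, s = y
        v = _branch_voltage(module, context, branch, h, s, i_ext, v_state["v"])
        if v is None:
            raise FoldCrossedError("branch lost during backward flow", (h, s))
        v_state["v"] = v
        dh = (sigmoid_gate(v, p.h_gate) - h) * tau_h_rate(v, p)
        return [-dh, p.beta * s]  # reversed time

    t_reach = np.log(p.s_max / s0) / p.beta if s0 > 0 else np.inf

    def ev(t, y):
        return y[1] - p.s_max

    ev.terminal = True

    def ev_floor(t, y):
        # backward image left the physical window: no silent-phase
        # trajectory from {s = s_max} reaches the start point
        return y[0]

    ev_floor.terminal = True
    sol = solve_ivp(rhs, (0.0, t_reach * 1.01 + 1e-9), [h0, s0], method="LSODA",
                    rtol=rtol, atol=1e-12, max_step=1.0, events=[ev, ev_floor])
    return max(float(sol.y[0][-1]), 0.0)


# --- switch-level correction and landscape -----------------------------------

def switch_gating_value(s_min: float, params) -> float:
    """Off-singular gate level s* at a phase switch.

    At a unit switch the newly active gate rises from ``s_min`` toward 1
    at rate alpha + beta while the previously active gate decays from
    ``s_max`` at rate beta; s* is the common value where they cross,
    obtained from ``s_max e^{-beta t} = (s_min - s_max) e^{-(alpha+beta) t} + s_max``.
    As alpha -> infinity, t -> 0 and s* -> s_max (full time-scale separation).
    """
    a, b = params.alpha, params.beta
    s_max = params.s_max
    if not (0.0 <= s_min <= s_max):
        raise ValueError("s_min must lie in [0, s_max]")
    if s_min == s_max:
        return s_max

    def f(t):
        return s_max * np.exp(-b * t) - ((s_min - s_max) * np.exp(-(a + b) * t) + s_max)

    # f(0) = -(s_min - s_max) > 0; decays to negative as the rising branch wins
    hi = 1.0
    while f(hi) > 0 and hi < 1e4:
        hi *= 2.0
    t_cross = brentq(f, 0.0 if f(0.0) > 0 else 1e-12, hi, xtol=1e-12)
    return float(s_max * np.exp(-b * t_cross))


def measure_halfcenter(
    config: NetworkConfig,
    t_end: float = 3000.0,
    settle_frac: float = 0.4,
):
    """Simulate the interneuron half-center and read off phase quantities.

    Returns ``(t_active_ep, t_active_er, s_er_min, s_ep_min)`` where the
    gate minima are taken at the end of the opposite unit's active phase.
    Raises :class:`LandscapeUndefinedError` if the half-center does not
    oscillate under the configured drives.
    """
    from .simulate import detect_phases, integrate

    trace = integrate(config, t_end=t_end, init="auto")
    t0 = trace.t[0] + (trace.t[-1] - trace.t[0]) * settle_frac
    ann = detect_phases(trace, t_min=t0, pops=["EP", "ER"])
    iv_ep = ann.intervals["EP"]
    iv_er = ann.intervals["ER"]
    if len(iv_ep) < 3 or len(iv_er) < 3:
        raise LandscapeUndefinedError(
            "interneuron half-center does not oscillate under these drives"
        )
    t_ep = ann.t_active("EP")
    t_er = ann.t_active("ER")

    def gate_min_in_phase(gate_pop: str, phase_iv):
        # minimum of the decaying gate over the opposite unit's active
        # phase; the gate re-activates a couple of ms before the phase's
        # detected offset, so the minimum (not the endpoint value) is
        # the meaningful quantity
        vals = []
        for on, off in phase_iv[1:-1]:
            sel = (trace.t >= on) & (trace.t <= off)
            if sel.any():
                vals.append(float(np.min(trace.s[gate_pop][sel])))
        if not vals:
            raise LandscapeUndefinedError("no complete phases to measure gate minima")
        return float(np.mean(vals))

    s_er_min = gate_min_in_phase("ER", iv_ep)  # while the pocket unit is active
    s_ep_min = gate_min_in_phase("EP", iv_er)
    return t_ep, t_er, s_er_min, s_ep_min


def compute_landscape(
    drives: DriveSet,
    module: ReducedModuleConfig,
    config: NetworkConfig,
    i_ext: float = 0.0,
    n_lk: int = 9,
    h_max_tol: float = 1e-2,
    measured: tuple[float, float, float, float] | None = None,
) -> SlowLandscape:
    """Assemble the full slow-phase-plane summary for a drive set.

    The phase durations and the gate minimum ``s_er_min`` are measured
    from a simulation of the interneuron half-center; all other
    quantities are computed from the reduced module's fast-subsystem
    geometry and slow flows.
    """
    p = module.params
    if measured is None:
        measured = measure_halfcenter(config.with_drives(drives))
    t_ep, t_er, s_er_min, s_ep_min = measured

    s_sn, h_sn = find_saddle_node(module, "ER", i_ext)
    grid = np.linspace(0.0, p.s_max, 200)
    jd_er = knee_curve("jump-down", "ER", grid, module, i_ext)
    ju_er = knee_curve("jump-up", "ER", grid, module, i_ext)
    jd_ep = knee_curve("jump-down", "EP", grid, module, i_ext)

    h_max_er = jd_er.interp_h(p.s_max)
    h_max_ep = jd_ep.interp_h(p.s_max)
    mismatch = abs(h_max_er - h_max_ep)
    if mismatch > h_max_tol:
        raise ModelStructureError(
            f"jump-down knees at s_max disagree between contexts by {mismatch:.4f} "
            f"(> {h_max_tol}); h_max ill-defined"
        )
    h_max = h_max_er

    h_min = jd_er.interp_h(s_er_min)
    h_er_min = ju_er.interp_h(s_er_min)

    t_decay = np.log(s_sn / s_er_min) / p.beta
    t_star = -np.log(s_sn / p.s_max) / p.beta

    # Remaining rostral-unit phase after KE activates at the saddle-node.
    # The compressed-plane notation uses one gate minimum for both phase
    # planes; with unequal phase durations the minima differ, and the
    # forward flow must use the minimum of the gate that actually decays
    # during the rostral unit's phase (s_EP), or the flow overshoots the
    # phase end.
    s_red_min = s_ep_min
    t_red = np.log(s_sn / s_red_min) / p.beta

    fwd = slow_flow((h_sn, s_sn), "R", "ER", module,
                    stop={"duration": t_red, "knee": "jump-down"}, i_ext=i_ext)
    h_sn_plus = float(fwd.h[-1])
    h_sn_minus = slow_flow_backward((h_sn, s_sn), "L", "ER", module, i_ext=i_ext)
    h_smin_minus = slow_flow_backward((h_er_min, s_er_min), "L", "ER", module,
                                      i_ext=i_ext)

    lk = []
    for s in np.linspace(s_er_min, s_sn, n_lk):
        try:
            lk.append((float(ju_er.interp_h(s)), float(s)))
        except StructureAbsentError:
            pass

    return SlowLandscape(
        context="ER",
        s_max=p.s_max,
        s_sn=s_sn,
        h_sn=h_sn,
        h_max=h_max,
        s_er_min=s_er_min,
        s_red_min=float(s_red_min),
        h_min=h_min,
        h_er_min=h_er_min,
        t_decay=float(t_decay),
        t_red=float(t_red),
        t_star=float(t_star),
        h_sn_plus=h_sn_plus,
        h_sn_minus=h_sn_minus,
        h_smin_minus=h_smin_minus,
        t_active_ep=t_ep,
        t_active_er=t_er,
        lk_samples=lk,
        h_max_mismatch=float(mismatch),
    )
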