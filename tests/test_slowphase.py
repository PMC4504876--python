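"""Slow phase-plane machinery: branches, knees, saddle-node, slow flows."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from scratchcpg import (
    DEFAULT_PARAMS,
    find_saddle_node,
    knee_curve,
    nullcline_branches,
    slow_flow,
    slow_flow_backward,
    switch_gating_value,
)
from scratchcpg.core import sigmoid_gate
from scratchcpg.network import ke_synaptic_input
from scratchcpg.slowphase import _context_gates, fixed_point_curve

P = DEFAULT_PARAMS


def _residual(point, module):
    p = module.params
    s_ep, s_er = _context_gates(point.context, point.s, p.s_max)
    i_syn = ke_synaptic_input(point.v, s_ep, s_er, module)
    i_nap = p.g_nap * sigmoid_gate(point.v, p.m_gate) * point.h * (point.v - p.e_na)
    return -i_nap - p.g_leak * (point.v - p.e_leak) - i_syn


def test_branch_ordering_and_residuals(s_module):
    """Roots are ordered V_L < V_M < V_R with tiny defect at each root."""
    pts = nullcline_branches(0.6, 0.5, P.s_max, s_module, context="ER")
    assert len(pts) == 3
    vs = {p.branch: p.v for p in pts}
    assert vs["L"] < vs["M"] < vs["R"]
    for p in pts:
        assert abs(_residual(p, s_module)) < 1e-9


def test_uncoupled_branches(s_module):
    pts = nullcline_branches(0.45, 0.0, 0.0, s_module)
    assert 1 <= len(pts) <= 3
    if len(pts) == 3:
        assert pts[0].v < pts[1].v < pts[2].v


def test_fold_root_count_change(s_module):
    """Crossing a knee in h changes the root count by two."""
    grid = np.linspace(0.05, P.s_max, 12)
    kc = knee_curve("jump-up", "ER", grid, s_module)
    good = np.flatnonzero(kc.present)
    assert len(good) >= 3
    for k in good[[0, len(good) // 2, -1]]:
        s, h = float(kc.s[k]), float(kc.h[k])
        lo = nullcline_branches(h - 1e-3, *_context_gates("ER", s, P.s_max), s_module)
        hi = nullcline_branches(h + 1e-3, *_context_gates("ER", s, P.s_max), s_module)
        assert abs(len(lo) - len(hi)) == 2


def test_jump_down_below_jump_up(s_module):
    """Jump-down knees lie at smaller h than jump-up knees at equal gate."""
    grid = np.linspace(0.0, P.s_max, 20)
    ju = knee_curve("jump-up", "ER", grid, s_module)
    jd = knee_curve("jump-down", "ER", grid, s_module)
    both = ju.present & jd.present
    assert both.any()
    assert np.all(jd.h[both] < ju.h[both])


def test_pocket_context_jump_up_absent(s_module):
    """While the pocket unit is active there is no jump-up knee in range:
    the silent KE cannot escape during that phase (rostral requirement)."""
    grid = np.linspace(0.0, P.s_max, 30)
    ju = knee_curve("jump-up", "EP", grid, s_module)
    assert not ju.present.any()


def test_saddle_node_location(s_module):
    s_sn, h_sn = find_saddle_node(s_module, "ER")
    assert 0.0 < s_sn < P.s_max
    # lies on the jump-up knee curve
    grid = np.linspace(max(s_sn - 0.05, 1e-3), min(s_sn + 0.05, P.s_max), 21)
    ju = knee_curve("jump-up", "ER", grid, s_module)
    assert abs(ju.interp_h(s_sn) - h_sn) < 5e-3
    # left fixed point exists just above, none just below
    for ds, expect in ((+0.02, True), (-0.02, False)):
        fp = fixed_point_curve("L", "ER", np.array([s_sn + ds]), s_module)
        assert bool(np.isfinite(fp.h[0]) and fp.h[0] <= 1.0) is expect


def test_slow_flow_gate_decay_closed_form(s_module):
    res = slow_flow((0.2, 0.5), "L", "ER", s_module, stop={"duration": 8.0})
    expected = 0.5 * np.exp(-P.beta * res.t)
    assert np.allclose(res.s, expected, rtol=1e-8)
    assert res.exit_reason == "duration"


def test_slow_flow_escape_at_knee(s_module):
    """A silent-phase flow started high eventually reaches the jump-up
    knee and reports the crossing instead of continuing past the fold."""
    from scratchcpg.slowphase import FoldCrossedError

    with pytest.raises(FoldCrossedError):
        slow_flow((0.4, 0.5), "L", "ER", s_module, stop={"duration": 40.0})
    res = slow_flow((0.4, 0.5), "L", "ER", s_module,
                    stop={"duration": 40.0, "knee": "jump-up"})
    assert res.exit_reason == "knee-hit"
    assert res.t[-1] < 40.0


def test_decay_time_formula():
    """T = (1/beta) ln(s1/s0): ratio 2 at beta = 0.08 gives 8.664 ms."""
    assert np.log(2.0) / P.beta == pytest.approx(8.664, abs=1e-3)
    # and the minimal-silent-time form with s_sn/s_max = 0.5
    assert -np.log(0.5) / P.beta == pytest.approx(8.664, abs=1e-3)


def test_slow_flow_s_target_stop(s_module):
    res = slow_flow((0.4, 0.5), "L", "ER", s_module, stop={"s_target": 0.25})
    assert res.exit_reason == "s-target"
    assert res.s[-1] == pytest.approx(0.25, abs=1e-6)
    assert res.t[-1] == pytest.approx(np.log(0.5 / 0.25) / P.beta, rel=1e-6)


def test_backward_forward_reversibility(s_module):
    """Backward to s_max then forward the same time returns the start."""
    start = (0.85, 0.6)
    h_back = slow_flow_backward(start, "L", "ER", s_module)
    t_back = np.log(P.s_max / start[1]) / P.beta
    fwd = slow_flow((h_back, P.s_max), "L", "ER", s_module,
                    stop={"duration": t_back})
    assert fwd.h[-1] == pytest.approx(start[0], abs=1e-6)
    assert fwd.s[-1] == pytest.approx(start[1], abs=1e-6)


def test_backward_endpoint_ordering(pocket_landscape):
    """The low-gate endpoint's backward image sits below the saddle-node's."""
    L = pocket_landscape
    assert L.h_smin_minus < L.h_sn_minus


def test_lk_trajectory_ordering(s_module, pocket_landscape):
    """Silent-phase flows preserve the h-ordering of jump-up knee points."""
    L = pocket_landscape
    pts = sorted(L.lk_samples, key=lambda hs: hs[0])
    assert len(pts) >= 5
    pairs = [(pts[i], pts[j]) for i, j in [(0, 2), (1, 3), (2, 4),
                                           (0, len(pts) - 1), (1, len(pts) - 2)]]
    s_end = max(pocket_landscape.s_er_min, 1e-3)
    for (h_lo, s_lo), (h_hi, s_hi) in pairs:
        if s_hi <= s_lo or s_lo <= s_end:
            continue
        # after activating at the knee both points flow on the active-
        # phase (right) branch; whichever vertical order holds when the
        # upper trajectory reaches the lower one's gate value persists
        # down to the end of the phase
        up = slow_flow((h_hi, s_hi), "R", "ER", s_module,
                       stop={"s_target": s_lo})
        sign0 = np.sign(up.h[-1] - h_lo)
        up2 = slow_flow((up.h[-1], s_lo), "R", "ER", s_module,
                        stop={"s_target": s_end})
        lo2 = slow_flow((h_lo, s_lo), "R", "ER", s_module,
                        stop={"s_target": s_end})
        assert np.sign(up2.h[-1] - lo2.h[-1]) == sign0


def test_switch_gate_limits():
    assert switch_gating_value(P.s_max, P) == pytest.approx(P.s_max)
    from dataclasses import replace

    fast = replace(P, alpha=1e6)
    assert switch_gating_value(0.3, fast) == pytest.approx(fast.s_max, rel=1e-3)


def test_switch_gate_vs_ode_oracle():
    """s* agrees with dense time-stepping of the two-gate switch ODEs."""
    s_min = 0.3
    a, b = P.alpha, P.beta

    def odes(t, y):
        rise, fall = y
        return [a * (1 - rise) - b * rise, -b * fall]

    sol = solve_ivp(odes, (0, 20.0), [s_min, P.s_max], rtol=1e-12, atol=1e-14,
                    dense_output=True)
    tt = np.linspace(0, 20, 200001)
    rise, fall = sol.sol(tt)
    k = np.argmax(rise >= fall)
    s_star_ode = fall[k]
    assert switch_gating_value(s_min, P) == pytest.approx(s_star_ode, abs=1e-4)


def test_landscape_intervals_nonempty(pocket_landscape, rostral_landscape):
    """I_s and I_h are nonempty for rhythm-supporting drive sets."""
    for L in (pocket_landscape, rostral_landscape):
        assert L.interval_s[0] < L.interval_s[1]
        assert L.interval_h[0] < L.interval_h[1]
        assert L.h_max_mismatch < 1e-2
        assert L.t_star > 0


def test_s_er_min_decreases_with_longer_pocket_phase(
        pocket_landscape, rostral_landscape):
    """The gate decays further the longer the opposing phase lasts."""
    # pocket: EP phase ~50 ms; rostral: EP phase ~37 ms
    assert pocket_landscape.t_active_ep > rostral_landscape.t_active_ep
    assert pocket_landscape.s_er_min < rostral_landscape.s_er_min
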