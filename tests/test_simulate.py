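"""Integration, phase detection, oscillation detection and classification."""

import numpy as np
import pytest

from scratchcpg import (
    PhaseAnnotation,
    Trace,
    build_network,
    classify,
    classify_rhythm,
    detect_oscillation,
    detect_phases,
    integrate,
)
from scratchcpg.simulate import InsufficientDataError, _coactivity


def _synthetic_trace(t, v_by_pop):
    n = len(t)
    pops = list(v_by_pop)
    return Trace(
        t=t,
        v={p: np.asarray(v_by_pop[p], dtype=float) for p in pops},
        h={p: np.full(n, 0.5) for p in pops},
        s={p: np.zeros(n) for p in pops},
        config=None,
    )


def test_detect_phases_constant_levels():
    t = np.linspace(0, 100, 501)
    tr = _synthetic_trace(t, {"A": np.zeros_like(t), "B": np.full_like(t, -65.0)})
    ann = detect_phases(tr, pops=["A", "B"])
    assert len(ann.intervals["A"]) == 1
    a, b = ann.intervals["A"][0]
    assert a == t[0] and b == t[-1]
    assert ann.intervals["B"] == []


def test_detect_phases_square_wave_edges():
    """Square-wave activity with known edges is recovered within a step."""
    dt = 0.5
    t = np.arange(0, 200 + dt, dt)
    v = np.where((t % 50) < 20, 0.0, -65.0)  # on for 20 ms every 50 ms
    tr = _synthetic_trace(t, {"X": v})
    ann = detect_phases(tr, pops=["X"])
    onsets = [a for a, _ in ann.intervals["X"]]
    offsets = [b for _, b in ann.intervals["X"]]
    for on in onsets[1:]:
        assert min(abs(on - k * 50.0) for k in range(5)) <= dt
    for off in offsets[:-1]:
        assert min(abs(off - (k * 50.0 + 20.0)) for k in range(5)) <= dt


def test_detect_oscillation_on_fixed_point_and_ringing():
    t = np.linspace(0, 1000, 2001)
    flat = np.full_like(t, -21.0)
    tr = _synthetic_trace(t, {"A": flat})
    assert detect_oscillation(tr, "A")[0] is False
    # damped ringing toward a plateau: transient removal must reject it
    ring = -30.0 + 25.0 * np.exp(-t / 60.0) * np.cos(2 * np.pi * t / 40.0) + 9.0
    tr = _synthetic_trace(t, {"A": ring})
    osc, amp = detect_oscillation(tr, "A")
    assert osc is False


def test_uncoupled_population_is_tonically_active():
    """Without synapses, drive in the working range gives a stable active
    state (the right-branch fixed point), not oscillation."""
    cfg = build_network("S", overrides={k: 0.0 for k in
                                        build_network("S").weight_lookup()})
    tr = integrate(cfg, t_end=1500.0, init="rest", rtol=1e-7)
    for p in ("EP", "ER", "IP", "IR"):
        osc, _ = detect_oscillation(tr, p)
        assert not osc
        assert tr.pa(p)[-1] > 0.95  # settled active


def test_classify_synthetic_quiescent():
    ann = PhaseAnnotation(
        intervals={"HE": [], "HF": [], "KE": []},
        threshold=0.5, span=(0.0, 1000.0),
    )
    assert classify_rhythm(ann).label == "quiescent"


def test_classify_insufficient_data():
    ann = PhaseAnnotation(
        intervals={"HE": [(0, 10), (50, 60)], "HF": [(20, 30)], "KE": []},
        threshold=0.5, span=(0.0, 100.0),
    )
    with pytest.raises(InsufficientDataError):
        classify_rhythm(ann)


def test_classify_synthetic_pocket_and_rostral():
    """Hand-built annotations with the two canonical timing patterns."""
    per, n = 100.0, 6
    he = [(k * per, k * per + 55) for k in range(n)]
    hf = [(k * per + 60, k * per + 95) for k in range(n)]
    # pocket: KE on just before HE onset (terminal HF overlap), off at HF onset
    ke_p = [(k * per - 12, k * per + 58) for k in range(1, n)]
    ann = PhaseAnnotation({"HE": he, "HF": hf, "KE": ke_p},
                          0.5, (0.0, n * per))
    lab = classify_rhythm(ann)
    assert lab.label == "pocket"
    # rostral: KE on 20 ms after HF onset, off with HF, silent during HE
    ke_r = [(k * per + 80, k * per + 95) for k in range(n)]
    ann = PhaseAnnotation({"HE": he, "HF": hf, "KE": ke_r},
                          0.5, (0.0, n * per))
    lab = classify_rhythm(ann)
    assert lab.label == "rostral"
    assert lab.ke_delay == pytest.approx(20.0, abs=1.0)


def test_simulated_rhythm_labels(pocket_trace, rostral_trace):
    lp = classify(pocket_trace)
    lr = classify(rostral_trace)
    assert lp.label == "pocket"
    assert lr.label == "rostral"
    # pocket: hip extensor dominant; KE onset precedes HE onset
    assert lp.t_active["HE"] > lp.t_active["HF"]
    assert lr.t_active["HF"] > lr.t_active["HE"]
    # rostral: delayed KE onset after HF onset
    assert lr.ke_delay >= 0.05 * lr.period


def test_hip_antiphase_invariant(pocket_trace, rostral_trace):
    """HE and HF active intervals overlap less than 5% in both rhythms."""
    for tr in (pocket_trace, rostral_trace):
        t0 = tr.t[-1] * 0.5
        ann = detect_phases(tr, pops=["HE", "HF"], t_min=t0)
        co = _coactivity(ann.intervals["HE"], ann.intervals["HF"], ann.span)
        assert co < 0.05


def test_pair_synchrony_invariant(pocket_trace):
    """EP/IR and ER/IP onset lags stay below 5% of the period."""
    tr = pocket_trace
    ann = detect_phases(tr, pops=["EP", "IR", "ER", "IP"], t_min=tr.t[-1] * 0.5)
    per = ann.period("EP")
    for a, b in (("EP", "IR"), ("ER", "IP")):
        ons_a = [x for x, _ in ann.intervals[a]][1:-1]
        ons_b = [x for x, _ in ann.intervals[b]]
        lags = [min(abs(x - y) for y in ons_b) for x in ons_a]
        assert max(lags) < 0.05 * per


def test_grid_refinement_stability(s_config, pocket_drives_s):
    """Halving the integration tolerances moves durations < 0.5%."""
    cfg = s_config.with_drives(pocket_drives_s)
    t1 = integrate(cfg, t_end=1500.0, rtol=1e-8, atol=1e-10)
    t2 = integrate(cfg, t_end=1500.0, rtol=5e-9, atol=5e-11)
    for tr in (t1, t2):
        assert tr.meta["rtol"] <= 1e-8
    a1 = detect_phases(t1, pops=["HE"], t_min=750.0).t_active("HE")
    a2 = detect_phases(t2, pops=["HE"], t_min=750.0).t_active("HE")
    assert abs(a1 - a2) / a2 < 0.005


def test_trace_roundtrip(tmp_path, baseline_rest_trace):
    from scratchcpg.io import load_trace, save_trace

    f = tmp_path / "trace.csv"
    save_trace(baseline_rest_trace, f)
    tr = load_trace(f)
    assert np.allclose(tr.t, baseline_rest_trace.t)
    assert np.allclose(tr.v["KE"], baseline_rest_trace.v["KE"])


def test_integrate_rejects_bad_span(s_config):
    with pytest.raises(ValueError):
        integrate(s_config, t_end=0.0)
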