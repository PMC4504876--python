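"""Network wiring, weight-class invariants and the reduced KE module."""

import numpy as np
import pytest

from scratchcpg import (
    POCKET_DRIVES,
    ROSTRAL_DRIVES,
    ROSTRAL_DRIVES_1,
    ROSTRAL_DRIVES_2,
    baseline_drives,
    build_network,
    ke_synaptic_input,
    reduce_module,
    stimulus_drives,
)
from scratchcpg.network import ConfigError, MOTONEURONS, ReductionError


def test_cross_excitation_class_difference():
    ws = build_network("S").weight_lookup()
    wsce = build_network("SCE").weight_lookup()
    assert ws[("EP", "IR")] == ws[("ER", "IP")] == 0.5
    assert wsce[("EP", "IR")] == wsce[("ER", "IP")] == 0.8


def test_baseline_drive_defaults():
    assert all(v == 0.17 for k, v in baseline_drives("S").as_dict().items()
               if k in ("IP", "EP", "ER", "IR"))
    assert all(v == 0.16 for k, v in baseline_drives("SCE").as_dict().items()
               if k in ("IP", "EP", "ER", "IR"))
    # motoneurons receive no drive by default
    assert baseline_drives("S").i_ke == 0.0


def test_printed_drive_fixtures():
    assert POCKET_DRIVES.as_dict()["IP"] == 0.17
    assert POCKET_DRIVES.as_dict()["EP"] == 0.19
    assert ROSTRAL_DRIVES.as_dict() == {
        "IP": 0.19, "EP": 0.17, "ER": 0.19, "IR": 0.17,
        "HE": 0.0, "KE": 0.0, "HF": 0.0,
    }
    assert ROSTRAL_DRIVES_1.as_dict()["EP"] == 0.18
    assert ROSTRAL_DRIVES_2.as_dict() == ROSTRAL_DRIVES.as_dict()
    assert stimulus_drives("S", "pocket").as_dict() == POCKET_DRIVES.as_dict()
    assert stimulus_drives("S", "rostral").as_dict() == ROSTRAL_DRIVES.as_dict()


def test_motoneurons_have_no_outgoing_synapses():
    for cls in ("S", "SCE"):
        for syn in build_network(cls).synapses:
            assert syn.source not in MOTONEURONS


def test_motoneuron_weights_shared_across_classes():
    ws = build_network("S").weight_lookup()
    wsce = build_network("SCE").weight_lookup()
    mn_edges = [(s, t) for (s, t) in ws if t in MOTONEURONS]
    assert mn_edges
    for e in mn_edges:
        assert ws[e] == wsce[e]


def test_hip_symmetry_and_ke_dominance():
    for cls in ("S", "SCE"):
        w = build_network(cls).weight_lookup()
        assert w[("EP", "HE")] == w[("ER", "HF")]
        assert w[("IP", "HE")] == w[("IR", "HF")]
        assert w[("ER", "KE")] > w[("EP", "KE")]
        assert w[("IR", "KE")] > w[("IP", "KE")]


def test_override_violating_hip_symmetry_rejected():
    with pytest.raises(ConfigError):
        build_network("S", overrides={("EP", "HE"): 1.0})


def test_unknown_override_rejected():
    with pytest.raises(ConfigError):
        build_network("S", overrides={("HE", "EP"): 1.0})


def test_negative_drive_rejected():
    from scratchcpg import DriveSet

    with pytest.raises(ConfigError):
        DriveSet(i_ip=-0.1, i_ep=0.17, i_er=0.17, i_ir=0.17)


def test_drive_scaling_targets():
    d = POCKET_DRIVES.scaled(2.0, "E")
    assert d.i_ep == pytest.approx(0.38) and d.i_ip == pytest.approx(0.17)
    d = POCKET_DRIVES.scaled(0.5, "I")
    assert d.i_ip == pytest.approx(0.085) and d.i_ep == pytest.approx(0.19)
    d = POCKET_DRIVES.scaled(1.1, "all")
    assert d.i_ir == pytest.approx(0.19 * 1.1)


# --- reduced module ----------------------------------------------------------

def test_ke_input_trivial_zeros(s_module):
    assert ke_synaptic_input(-50.0, 0.0, 0.0, s_module) == 0.0


def test_ke_input_bracket_root(s_module):
    m = s_module
    v_root = m.g_ke_ip * m.params.e_syn_inh / (m.g_ke_ip + m.g_ke_er)
    assert ke_synaptic_input(v_root, 0.0, 0.4, m) == pytest.approx(0.0, abs=1e-12)


def test_ke_input_equals_four_synapse_sum(s_module, rng):
    """The hybrid formula is the four-synapse sum under the pair identities."""
    m = s_module
    p = m.params
    for _ in range(100):
        v = rng.uniform(-80, 10)
        s_ep = rng.uniform(0, p.s_max)
        s_er = rng.uniform(0, p.s_max)
        s_ip, s_ir = s_er, s_ep  # pair identifications
        direct = (
            m.g_ke_ep * s_ep * (v - p.e_syn_exc)
            + m.g_ke_er * s_er * (v - p.e_syn_exc)
            + m.g_ke_ip * s_ip * (v - p.e_syn_inh)
            + m.g_ke_ir * s_ir * (v - p.e_syn_inh)
        )
        assert ke_synaptic_input(v, s_ep, s_er, m) == pytest.approx(direct, rel=1e-12)


def test_ke_input_requires_zero_excitatory_reversal(s_module):
    from dataclasses import replace

    from scratchcpg import PopulationParams

    bad = replace(s_module, params=PopulationParams(e_syn_exc=10.0))
    with pytest.raises(ConfigError):
        ke_synaptic_input(-50.0, 0.1, 0.1, bad)


def test_reduction_synchrony_guard(s_config):
    t = np.linspace(0, 100, 201)
    s_good = {
        "ER": np.sin(t) ** 2, "IP": np.sin(t) ** 2,
        "EP": np.cos(t) ** 2, "IR": np.cos(t) ** 2,
    }
    reduce_module(s_config, synchrony_check=(t, s_good))
    s_bad = dict(s_good)
    s_bad["IP"] = np.cos(t) ** 2  # forced desynchronization
    with pytest.raises(ReductionError) as e:
        reduce_module(s_config, synchrony_check=(t, s_bad))
    assert e.value.phase_lag > 0.05


def test_reduction_synchrony_holds_in_simulation(s_config, pocket_trace):
    """The lumping identities hold on the simulated pocket rhythm."""
    tr = pocket_trace
    sel = tr.t > tr.t[-1] * 0.5
    s = {p: tr.s[p][sel] for p in ("EP", "ER", "IP", "IR")}
    # gate waveforms of co-active partners agree to ~15% rms; onset-level
    # synchrony is checked separately on the phase annotations
    reduce_module(s_config, synchrony_check=(tr.t[sel], s), tol=0.2)


def test_config_roundtrip(tmp_path, s_config):
    from scratchcpg.io import load_config, save_config

    f = tmp_path / "net.yaml"
    save_config(s_config, f)
    cfg2 = load_config(f)
    assert cfg2.weight_lookup() == s_config.weight_lookup()
    assert cfg2.drives.as_dict() == s_config.drives.as_dict()
    assert cfg2.params == s_config.params
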