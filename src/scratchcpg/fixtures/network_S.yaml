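weight_class: S
params:
  c_m: 0.21
  g_nap: 10.0
  e_na: 50.0
  g_leak: 2.8
  e_leak: -65.0
  m_gate:
    half: -37.0
    theta: -6.0
  h_gate:
    half: -30.0
    theta: 6.0
  s_gate:
    half: -43.0
    theta: -0.1
  epsilon: 0.01
  alpha: 1.0
  beta: 0.08
  e_syn_exc: 0.0
  e_syn_inh: -80.0
drives:
  IP: 0.17
  EP: 0.17
  ER: 0.17
  IR: 0.17
  HE: 0.0
  KE: 0.0
  HF: 0.0
synapses:
- source: EP
  target: HE
  g: 0.6
  reversal: excitatory
- source: EP
  target: IP
  g: 1.4
  reversal: inhibitory
- source: EP
  target: IR
  g: 0.5
  reversal: excitatory
- source: EP
  target: KE
  g: 0.05
  reversal: excitatory
- source: ER
  target: HF
  g: 0.6
  reversal: excitatory
- source: ER
  target: IP
  g: 0.5
  reversal: excitatory
- source: ER
  target: IR
  g: 1.4
  reversal: inhibitory
- source: ER
  target: KE
  g: 0.2
  reversal: excitatory
- source: IP
  target: EP
  g: 1.0
  reversal: inhibitory
- source: IP
  target: HE
  g: 2.0
  reversal: inhibitory
- source: IP
  target: KE
  g: 0.7
  reversal: inhibitory
- source: IR
  target: ER
  g: 1.0
  reversal: inhibitory
- source: IR
  target: HF
  g: 2.0
  reversal: inhibitory
- source: IR
  target: KE
  g: 1.48
  reversal: inhibitory
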