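# scratchcpg

A computational model of the spinal central pattern generator (CPG)
thought to underlie two turtle scratch behaviors.  Intact and
spinalized turtles produce distinct rhythmic motor patterns — pocket
scratch and rostral scratch — in response to non-rhythmic stimulation of
different body regions.  Both patterns are carried by the same three
motoneuron pools (hip extensor HE, hip flexor HF, knee extensor KE) and
differ only in timing: pocket is hip-extensor dominant with KE active
together with HE (switching on just before it), rostral is hip-flexor
dominant with KE switching on after a clear delay from HF onset and off
together with HF.

The package implements, as a tested simulator plus analysis library:

* a conductance-based network of four hip-related interneuron pools
  (two reciprocally inhibitory unit generators coupled by
  cross-excitation) feeding forward to the three motoneuron pools, each
  population a persistent-sodium (I_NaP) relaxation unit

      C_m V̇ = −I_NaP(V,h) − I_L(V) − Σ g_ij s_j (V−e_syn) − i_ext V
      ḣ     = (h_∞(V) − h) · ε cosh((V−h_half)/2θ_h)
      ṡ     = α (1−s) s_∞(V) − β s

  with both rhythms selected purely by the tonic drive strengths
  (pocket {i_IP 0.17, i_EP 0.19, i_ER 0.17, i_IR 0.19} nS versus the
  mirrored rostral set, over a fixed synaptic weight set);
* the fast–slow decomposition of the KE dynamics: cubic nullcline
  branches V_L < V_M < V_R, jump-up/jump-down knee (fold) curves
  (V^JU(s), h^JU(s)), fixed-point curves, the saddle-node (s_SN, h_SN)
  of fast-subsystem equilibria that imposes the rostral onset delay,
  and slow flows h′ = g(V_branch(h,s), h), s′ = −βs;
* the sufficient conditions for stable pocket ((P1)–(P4)) and rostral
  ((R1)–(R3)) rhythm selection, with signed margins, plus the key
  differentiator (is h_KE above or below the jump-down ceiling h_max
  when the rostral unit's phase ends?);
* the in-silico experiments: input switching during ongoing rhythms,
  bistability probing, input scaling, and the seeded weight calibration
  that recovers the shipped synaptic weights from the architecture's
  qualitative constraints.

See `docs/methods.md` for the model account, parameter tables and
numerical choices.

## Worked example

```python
from scratchcpg import (build_network, stimulus_drives, integrate,
                        classify, reduce_module, compute_landscape,
                        check_rostral)

cfg = build_network("S")                       # calibrated standard weights
drv = stimulus_drives("S", "rostral")          # {IP .19, EP .17, ER .19, IR .17} nS
trace = integrate(cfg.with_drives(drv), t_end=3000.0)   # stiff LSODA, rtol 1e-8
label = classify(trace)
print(label.label, round(label.period, 1), round(label.ke_delay, 1))

module = reduce_module(cfg)
land = compute_landscape(drv, module, cfg)
print(round(land.s_sn, 3), round(land.h_max, 3), round(land.t_star, 1))
rep = check_rostral(drv, land, module)
print(rep.verdict, [(c.name, round(c.margin, 3)) for c in rep.conditions])
```

prints

```
rostral 88.9 16.3
0.265 0.315 15.6
True [('R1', 0.05), ('R2', 0.211), ('R3', 0.006)]
```

i.e. the rostral drive set elicits a rostral rhythm with an 88.9 ms
period and a 16.3 ms KE onset delay after HF onset; the slow phase
plane puts the saddle-node at gate value s_SN = 0.265 with jump-down
ceiling h_max = 0.315 and a minimal KE silent time t* = 15.6 ms; and
all three rostral sufficiency conditions hold with positive margins
(R1, R3 in units of h, R2 in units of s).

The same network under the pocket drive set classifies as pocket with
HE active longer than HF and KE switching on during terminal HF
activity, and the pocket conditions (P1)–(P4) hold instead.

## Command line

```
scratchcpg simulate --weight-class S --t-end 20000 --out trace.csv
scratchcpg classify --trace trace.csv
scratchcpg landscape --weight-class S --side rostral --out landscape.json
scratchcpg conditions --weight-class S --side pocket --out report.json
scratchcpg switch --from-drives drives_rostral.yaml --to-drives drives_pocket.yaml
scratchcpg scale --target E --low 0.99 --high 1.03
scratchcpg calibrate --weight-class S --seed 1
```

Shipped drive-set and network fixtures live in
`src/scratchcpg/fixtures/`.

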