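name: XV
model_type: Migrations, divergence, expansion, and bottlenecks
topology: ((A,B),C)
provenance: inferred
tie_ancestral_ne: Ne_C
events:
- kind: split
  time: tdiv_AB
  derived: A
  ancestral: AB
- kind: split
  time: tdiv_AB
  derived: B
  ancestral: AB
- kind: split
  time: tdiv_ABC
  derived: AB
  ancestral: ABC
- kind: split
  time: tdiv_ABC
  derived: C
  ancestral: ABC
- kind: pulse
  time: tmig_A_B
  source: A
  dest: B
  fraction: p_A_B
- kind: pulse
  time: tmig_B_A
  source: B
  dest: A
  fraction: p_B_A
- kind: pulse
  time: tmig_AB_C
  source: AB
  dest: C
  fraction: p_AB_C
- kind: pulse
  time: tmig_C_AB
  source: C
  dest: AB
  fraction: p_C_AB
- kind: growth
  pop: A
  rate: growth_A
- kind: growth
  pop: C
  rate: growth_C
- kind: bottleneck
  time: t_bot_A
  pop: A
  strength: s_bot_A
- kind: bottleneck
  time: t_bot_C
  pop: C
  strength: s_bot_C
bounds:
  Ne_A: &id001
  - 20000.0
  - 2000000.0
  Ne_B: *id001
  Ne_C: *id001
  tdiv_AB:
  - 10000.0
  - 3000000.0
  tdiv_ABC:
  - 50000.0
  - 3600000.0
  tmig_A_B: &id002
  - 0.0
  - 3600000.0
  p_A_B: &id003
  - 0.0
  - 0.6
  tmig_B_A: *id002
  p_B_A: *id003
  tmig_AB_C: *id002
  p_AB_C: *id003
  tmig_C_AB: *id002
  p_C_AB: *id003
  growth_A: &id004
  - 1.0e-08
  - 0.001
  growth_C: *id004
  t_bot_A:
  - 0.0
  - 3000000.0
  s_bot_A: &id005
  - 0.01
  - 0.9
  t_bot_C:
  - 0.0
  - 3600000.0
  s_bot_C: *id005
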