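name: X
model_type: Migrations, divergence, and expansion
topology: ((A,B),C)
provenance: transcribed
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
  pop: C
  rate: growth_C
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
  growth_C:
  - 1.0e-08
  - 0.001
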