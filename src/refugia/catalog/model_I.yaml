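name: I
model_type: Divergences
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
bounds:
  Ne_A: &id001
  - 20000.0
  - 2000000.0
  Ne_B: *id001
  Ne_C: *id001
  tdiv_AB: &id002
  - 10000.0
  - 10000000.0
  tdiv_ABC: *id002
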