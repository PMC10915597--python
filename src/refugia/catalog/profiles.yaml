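mentalis:
  models:
  - I
  - II
  - III
  - IV
  - V
  - VI
  - VII
  - VIII
  - IX
  - X
  - XI
  - XII
  - XIII
caerulescens:
  models:
  - I
  - II
  - III
  - IV
  - V
  - VI
  - VII
  - VIII
  - IX
  - X
  - XI
  - XII
  - XIII
  - XIV
  - XV
palliatus:
  models:
  - I
  - II
  - III
  - IV
  - V
  - VI
  - VII
  - VIII
  - IX
  - X
  - XI
  - XII
  - XIII
  - XIV
  - XV
ruficapillus:
  models:
  - I
  - II
  - III
  - IV
  - V
  - VI
  - VII
  - VIII
  - IX
  - X
  - XI
  - XII
full:
  models:
  - I
  - II
  - III
  - IV
  - V
  - VI
  - VII
  - VIII
  - IX
  - X
  - XI
  - XII
  - XIII
  - XIV
  - XV
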