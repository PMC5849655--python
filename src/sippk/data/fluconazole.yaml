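# Fluconazole perpetrator model.  Disposition values are the package's
# documented defaults (renally-cleared azole with low clearance, small
# volume, fast absorption, weak plasma binding); the CYP2C9 Ki of 20.4 uM is
# the literature-derived competitive inhibition constant, the CYP3A4 Ki a
# literature-informed config default.
name: fluconazole
mw: 306.3
parameters:
  ka: 2.0
  v: 0.7
  cl: 0.8
  fu: 0.9
  fa: 1.0
  fg: 1.0
  body_weight: 70.0
units:
  ka: 1/h
  v: L/kg
  cl: L/h
  body_weight: kg
  mw: g/mol
fm: {}
ki:
  CYP2C9: 20.4
  CYP3A4: 10.0
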