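# Siponimod victim model.  Absorption is complete (fa = 1) with first-order
# Ka from early clinical data; fu is very low and fu,gut is set equal to it,
# giving fg = 1.  CL/F is the wild-type (CYP2C9*1/*1) apparent oral clearance.
name: siponimod
mw: 516.6
parameters:
  ka: 0.98
  v: 2.12
  cl: 4.01
  fu: 0.0002
  fa: 1.0
  fg: 1.0
  body_weight: 70.0
units:
  ka: 1/h
  v: L/kg
  cl: L/h
  body_weight: kg
  mw: g/mol
fm:
  CYP2B6: 0.0024
  CYP2C8: 0.0154
  CYP2C9: 0.8084
  CYP2C19: 0.0015
  CYP3A4: 0.1723
ki: {}
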