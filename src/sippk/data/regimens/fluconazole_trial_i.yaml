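# Trial i perpetrator arm: fluconazole 200 mg once daily, day 1 to day 20.
doses:
  - {pattern: qd, amount_mg: 200, n_days: 20, start_h: 0}
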