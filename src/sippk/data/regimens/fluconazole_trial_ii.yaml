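# Trial ii perpetrator arm: fluconazole 200 mg twice daily on day 1,
# then 200 mg once daily from day 2 to day 21.
doses:
  - {pattern: bid, amount_mg: 200, n_days: 1, start_h: 0}
  - {pattern: qd, amount_mg: 200, n_days: 20, start_h: 24}
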