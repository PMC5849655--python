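# Trial iii perpetrator arm: fluconazole 400 mg twice daily on day 1,
# then 400 mg once daily from day 2 to day 19.
doses:
  - {pattern: bid, amount_mg: 400, n_days: 1, start_h: 0}
  - {pattern: qd, amount_mg: 400, n_days: 18, start_h: 24}
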