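# Trial i victim arm: siponimod 5 mg single dose on day 4 (72 h).
doses:
  - {pattern: single, amount_mg: 5, time_h: 72}
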