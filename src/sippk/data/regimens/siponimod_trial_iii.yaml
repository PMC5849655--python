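# Trial iii victim arm: siponimod 4 mg single dose on day 3 (48 h).
doses:
  - {pattern: single, amount_mg: 4, time_h: 48}
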