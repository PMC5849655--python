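# Wild-type single-dose reference run: siponimod 0.25 mg, CYP2C9*1/*1
# clearance, deterministic base subject.
name: table5_wt
drug: siponimod
regimen: {pattern: single, amount_mg: 0.25, time_h: 0}
seed: 0
grid: {dt_h: 0.25, n_half_lives: 10}
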