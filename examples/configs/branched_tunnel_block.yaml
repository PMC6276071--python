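# Fixed-site branched model with one external tunnel blocked
# (GLUT1-deficiency T295M-style lesion); compare against the same file
# with block_right_branch: false.
model:
  type: branched
  block_right_branch: true
protocols:
  - type: zero_trans_influx
    grid: {start: 0.03, stop: 300.0, num: 12}
  - type: zero_trans_efflux
    grid: {start: 0.03, stop: 300.0, num: 12}
audit:
  bath_conc: 10.0
seed: 0
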