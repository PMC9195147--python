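# Full synthetic demo study: melting curves for every sample at its
# reported melting temperature, the two-component XANES mixture for the
# long fragment, and the octahedral Co-O EXAFS refinement.
seed: 0
stages:
- simulate
- melt
- xanes
- exafs
- report
melting:
  noise_sd: 0.0
  grid:
    start: 20.0
    stop: 95.0
    step: 0.5
  samples:
  - name: wt_81_none
    fragment: 81-210
    equivalents: none
    tms:
    - 65
    dh:
    - 300
  - name: wt_81_0.3
    fragment: 81-210
    equivalents: '0.3'
    tms:
    - 65
    dh:
    - 300
  - name: wt_81_0.8
    fragment: 81-210
    equivalents: '0.8'
    tms:
    - 65
    dh:
    - 300
  - name: wt_90_none
    fragment: 90-210
    equivalents: none
    tms:
    - 66
    dh:
    - 300
  - name: wt_90_0.8
    fragment: 90-210
    equivalents: '0.8'
    tms:
    - 60
    dh:
    - 300
  - name: wt_90_1.6
    fragment: 90-210
    equivalents: '1.6'
    tms:
    - 60
    dh:
    - 300
  - name: D104G_90_none
    fragment: 90-210
    equivalents: none
    tms:
    - 68
    dh:
    - 300
  - name: D104G_90_0.8
    fragment: 90-210
    equivalents: '0.8'
    tms:
    - 63
    dh:
    - 300
  - name: Y123S_90_none
    fragment: 90-210
    equivalents: none
    tms:
    - 53
    dh:
    - 300
  - name: Y123S_90_0.8
    fragment: 90-210
    equivalents: '0.8'
    tms:
    - 43
    - 59
    dh:
    - 300
    - 300
  - name: S161I_90_none
    fragment: 90-210
    equivalents: none
    tms:
    - 56
    dh:
    - 300
  - name: S161I_90_0.8
    fragment: 90-210
    equivalents: '0.8'
    tms:
    - 46
    - 54
    dh:
    - 400
    - 400
xanes:
  target_sample: wt_81_0.8
  bound_fraction: 0.43
  noise_sd: 0.0
exafs:
  shells:
  - - 4
    - 2.02
  - - 1
    - 2.21
  - - 1
    - 1.85
  shell_res_names:
  - MIX
  - GLU
  - HOH
  delta_ef: 3.0
  s02: 0.9
  rbkg: 1.0
  k_range:
  - 3.0
  - 12.0
  k_weight: 2
  start_radius_offset: 0.1
  noise_sd: 0.0
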