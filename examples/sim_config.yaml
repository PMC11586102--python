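groups:
  - name: lact
    n_bats: 20
    sex: F
    repro_condition: lactating
    n_cycles_mean: 1.0
    bout_scale_h: 1.4
  - name: preg
    n_bats: 20
    sex: F
    repro_condition: pregnant
    n_cycles_mean: 2.0
    bout_scale_h: 0.8
  - name: nonrep
    n_bats: 20
    sex: F
    repro_condition: nonreproductive
    n_cycles_mean: 1.5
nights_per_bat: 10
start_date: 2017-04-01
seed: 42
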