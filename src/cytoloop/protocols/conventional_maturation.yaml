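# Conventional (open-loop) maturation experiment: media changed at fixed
# operator-chosen times — 60 min raffinose acclimation, 30 min galactose
# induction, 240 min translation-blocked chase.
phases:
  - name: growth
    medium: raffinose
    criterion: {name: elapsed, threshold: 60}
    timeout_min: 1000
  - name: induction
    medium: galactose
    criterion: {name: elapsed, threshold: 30}
    timeout_min: 1000
  - name: chase
    medium: galactose+CHX
    criterion: {name: elapsed, threshold: 240}
    timeout_min: 1000
channels:
  - {name: phase, filter_slot: 0, exposure_ms: 10}
  - {name: yfp, filter_slot: 1, exposure_ms: 75}
n_af: 1
period_min: 5.0
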