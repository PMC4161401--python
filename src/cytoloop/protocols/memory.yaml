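# Transcriptional-memory experiment: glucose growth, first galactose
# induction (dropping under-responding FOVs and re-planning the period),
# glucose repression for two population doublings, then re-induction.
phases:
  - name: growth
    medium: glucose
    criterion: {name: count, threshold: 0.25}
    reference: phase_start
    timeout_min: 600
  - name: induction1
    medium: galactose
    criterion: {name: fluorescence, fraction: 0.5, threshold: 0.5}
    reference: phase_start
    timeout_min: 900
    fov_policy: drop_failing_and_rescale
  - name: repression
    medium: glucose
    criterion: {name: doublings, threshold: 2}
    reference: phase_start
    timeout_min: 1800
  - name: induction2
    medium: galactose
    criterion: {name: fluorescence, fraction: 0.5, threshold: 0.5}
    reference: phase_start
    timeout_min: 900
channels:
  - {name: phase, filter_slot: 0, exposure_ms: 10}
  - {name: yfp, filter_slot: 1, exposure_ms: 75}
n_af: all
period_min: 5.0
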