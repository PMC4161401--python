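# Fluorescent-protein maturation-rate experiment (cycloheximide chase).
# Grow in raffinose until the count rises 25%, induce in galactose until 25%
# of cells exceed background autofluorescence by 25%, then block translation
# and image until 60% of cells' fluorescence is steady.
phases:
  - name: growth
    medium: raffinose
    criterion: {name: count, threshold: 0.25}
    reference: phase_start
    timeout_min: 600
  - name: induction
    medium: galactose
    criterion: {name: fluorescence_over_background, fraction: 0.25, threshold: 0.25}
    reference: phase_start
    timeout_min: 600
  - name: chase
    medium: galactose+CHX
    criterion: {name: steadiness, fraction: 0.60}
    reference: previous
    timeout_min: 600
channels:
  - {name: phase, filter_slot: 0, exposure_ms: 10}
  - {name: yfp, filter_slot: 1, exposure_ms: 75}
n_af: all
# floor on the acquisition period: match the ~5 min/frame cadence the assay
# was designed around and keep light exposure (and the steadiness window)
# consistent across setups with few FOVs
period_min: 5.0
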