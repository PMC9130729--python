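# Standard condition battery for `nscdyn run-battery --config`.
# Training windows are half-open [start, end) day intervals; the learning
# factor multiplies the division/differentiation rates k1, k3..k6 inside a
# window and the rescue factor divides the checkpoint death probability for
# neurons whose checkpoint day falls inside a window.
- name: control
  horizon: 30
  replicates: 20
  p0: 1000
- name: trained_3_14
  horizon: 30
  replicates: 20
  p0: 1000
  schedule:
    windows: [[3, 14]]
    learning_factor: 3
    rescue_factor: 10
- name: trained_12_30
  horizon: 30
  replicates: 20
  p0: 1000
  schedule:
    windows: [[12, 30]]
    learning_factor: 3
    rescue_factor: 10
- name: control_death
  horizon: 30
  replicates: 20
  p0: 1000
  death:
    checkpoint_age: 15
    p_death: 0.45
    enabled: true
- name: trained_3_14_death
  horizon: 30
  replicates: 20
  p0: 1000
  schedule:
    windows: [[3, 14]]
    learning_factor: 3
    rescue_factor: 10
  death:
    checkpoint_age: 15
    p_death: 0.45
    enabled: true
- name: trained_12_30_death
  horizon: 30
  replicates: 20
  p0: 1000
  schedule:
    windows: [[12, 30]]
    learning_factor: 3
    rescue_factor: 10
  death:
    checkpoint_age: 15
    p_death: 0.45
    enabled: true
- name: control_death_500d
  horizon: 500
  replicates: 20
  p0: 1000
  death:
    checkpoint_age: 15
    p_death: 0.45
    enabled: true
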