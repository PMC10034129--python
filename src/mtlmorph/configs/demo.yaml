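# Desk-scale demonstration pipeline: a tiny synthetic cohort through the
# longitudinal arm, and a small section phantom through detection.
output_dir: mtlmorph_output
log_level: INFO
stages:
  - name: simulate-cohort
    params:
      structure: amygdala
      seed: 7
      n_per_group: 2
      noise_level: 0.03
      scans: 3
      period: 2.0
      mesh_subdivisions: 1
  - name: fit-longitudinal
    params:
      structure: amygdala
      max_iter: 15
  - name: roc
    params:
      group_negative: CU-CU
  - name: simulate-histology
    params:
      seed: 7
      n_sections: 3
  - name: detect
    params: {}
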