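# Perinatal fluoxetine model (one-compartment oral, milk-to-plasma scaling).
# Typical values: CL/F 8.42 L/h, V/F 690 L, ka 0.3 /h fixed, MPR 0.59.
name: M1
structure: parent_milk
typical_values:
  cl_parent: 8.42     # L/h
  v_parent: 690.0     # L
  ka: 0.3             # 1/h, fixed
  mpr: 0.59           # milk-to-plasma ratio
fixed_parameters: [ka]
covariate_effects: []
random_effects:
  iiv_sd:             # log-scale SD, printed %CV / 100
    cl_parent: 0.38
    mpr: 0.32
  ruv_prop_sd:        # proportional residual SD (fraction), per analyte
    parent: 0.08
    milk: 0.37
  ruv_add_sd: {}
covariate_defaults: {}
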