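# Pediatric fluoxetine model (one-compartment oral, weight-linear CL/F and V/F).
# Typical values: CL/F = 0.181 x BW L/h, V/F = 37.4 x BW L, ka 0.666 /h fixed.
name: M2
structure: parent_only
typical_values:
  cl_parent: 0.181    # L/h per kg body weight
  v_parent: 37.4      # L per kg body weight
  ka: 0.666           # 1/h, fixed
fixed_parameters: [ka]
covariate_effects:
  - {parameter: cl_parent, covariate: WT, form: linear, theta: 1.0}
  - {parameter: v_parent, covariate: WT, form: linear, theta: 1.0}
random_effects:
  iiv_sd:
    cl_parent: 0.52
    v_parent: 0.205
  ruv_prop_sd:
    parent: 0.18
  ruv_add_sd: {}
covariate_defaults:
  WT: 53.6            # pooled mean of the source study's child/adolescent means
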