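# Joint fluoxetine-norfluoxetine model: two connected one-compartment models,
# 16.5% higher parent clearance in males (SEX coded female=0, male=1),
# combined additive + proportional residual error per analyte.
name: FINAL
structure: parent_metabolite
typical_values:
  cl_parent: 2.91     # L/h, female reference
  v_parent: 24.9      # L
  ka: 0.3             # 1/h, fixed
  cl_metab: 3.24      # L/h
  v_metab: 1.52       # L
  fm: 1.0             # fraction metabolized, fixed
fixed_parameters: [ka, fm]
covariate_effects:
  - {parameter: cl_parent, covariate: SEX, form: fractional_shift, theta: 0.165}
random_effects:
  iiv_sd:
    cl_parent: 0.316
    cl_metab: 0.209
  ruv_prop_sd:
    parent: 0.341
    metabolite: 0.305
  ruv_add_sd:         # ng/mL
    parent: 14.9
    metabolite: 22.9
covariate_defaults:
  SEX: 0              # female reference (study majority)
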