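# Versioned model coefficients for ensemble-insulation summation and
# clothing-area-factor estimation. Coefficients are data, not code: users can
# refit (clotherm refit / clotherm.models.fit_linear) and swap this file.
#
# input_unit declares the unit of the model's predictor:
#   clo — basic insulation in clo (1 clo = 0.155 m2K/W)
#   si  — basic insulation in m2K/W
version: 1

icl_summation:
  # Conventional single-ensemble summation (slope 0.835, intercept 0.161 clo)
  # from the widely used workwear summation formula; the intercept is the
  # literature convention, not fitted on this wardrobe.
  standard:
    slope: 0.835
    intercept: 0.161
    input_unit: clo
    fitted_on: literature convention (not fitted on this wardrobe)
  # Incident (turnout) ensembles: standard slope kept, intercept re-adjusted.
  incident:
    slope: 0.835
    intercept: 0.311
    input_unit: clo
    fitted_on: incident ensembles, fixed conventional slope
  # Operational-uniform (station wear) ensembles: fully refitted line.
  operational_uniform:
    slope: 0.975
    intercept: -0.194
    input_unit: clo
    fitted_on: operational uniform ensembles, free fit

fcl_estimation:
  # Estimation line derived on a modern Western clothing database (I_cl in SI).
  modern_western:
    slope: 1.599
    intercept: 1.01
    input_unit: si
    fitted_on: modern Western clothing database
  # Firefighter-specific line (I_cl in clo), fitted on this wardrobe's ensembles.
  firefighter:
    slope: 0.2314
    intercept: 1.02
    input_unit: clo
    fitted_on: firefighter ensembles
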