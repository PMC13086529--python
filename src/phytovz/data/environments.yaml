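# Idealised epipelagic environments.  Nutrients μmolN·L⁻¹, mixing rate d⁻¹,
# temperatures K.  The Eppley factor γT = eppley_scale ×
# exp(−eppley_slope·(1/T − 1/eppley_ref_temp)) multiplies the growth rate and
# all mortality parameters.  All values are PLACEHOLDER magnitudes chosen
# once at realistic open-ocean values; a single edit here reconciles them
# with any preferred parameterisation.

environments:
  oligotrophic:
    deep_nutrient: 2.0
    surface_nutrient: 0.1
    mixing_rate: 0.1
    temperature: 298.15
    eppley_scale: 0.8
    eppley_slope: 4000.0
    eppley_ref_temp: 293.15
    error_weight: 1.0
  mesotrophic:
    deep_nutrient: 8.0
    surface_nutrient: 0.5
    mixing_rate: 0.15
    temperature: 291.15
    eppley_scale: 0.8
    eppley_slope: 4000.0
    eppley_ref_temp: 293.15
    error_weight: 1.0
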