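# Four-year maize-soybean rotation with annual 5 kg m-2 basalt
# applications to a 30 cm biogeochemically active layer; F_D = 1.
# Mineralogy follows the SEM-EDS characterisation: 19.6% albite,
# 11.6% ferroactinolite, 25.6% epidote, 36.3% chlorite, 5.2% quartz.
# Requires user-supplied hourly forcing for the site.
site:
  latitude: 40.06
  z_a: 0.30
  texture_class: silt_loam
  cec: 60.0
schedule:
  start: 2016-11-01
  end: 2020-12-31
feedstock:
  f_d: 1.0
  events:
    - date: 2016-11-15
      rate: 5.0
      specific_surface_area: 3000.0
      mineral_fractions: &semeds
        albite: 0.196
        ferroactinolite: 0.116
        epidote: 0.256
        chlorite: 0.363
        quartz: 0.052
    - date: 2017-11-15
      rate: 5.0
      specific_surface_area: 3000.0
      mineral_fractions: *semeds
    - date: 2018-11-15
      rate: 5.0
      specific_surface_area: 3000.0
      mineral_fractions: *semeds
    - date: 2019-11-15
      rate: 5.0
      specific_surface_area: 3000.0
      mineral_fractions: *semeds
vegetation:
  pft: maize
  rotation:
    1: maize
    2: maize
    3: soybean
    4: maize
initial:
  s_eff: 0.60
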