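# As illinois_maize_soy, but with the alternative XRD feedstock
# characterisation: 23.3% albite, 11.9% ferroactinolite, 17.8% epidote
# (standing in for piemontite, an epidote-group endmember), 34% chlorite,
# 9% quartz, 2.6% calcite.
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
      mineral_fractions: &xrd
        albite: 0.233
        ferroactinolite: 0.119
        epidote: 0.178
        chlorite: 0.340
        quartz: 0.090
        calcite: 0.026
    - date: 2017-11-15
      rate: 5.0
      specific_surface_area: 3000.0
      mineral_fractions: *xrd
    - date: 2018-11-15
      rate: 5.0
      specific_surface_area: 3000.0
      mineral_fractions: *xrd
    - date: 2019-11-15
      rate: 5.0
      specific_surface_area: 3000.0
      mineral_fractions: *xrd
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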