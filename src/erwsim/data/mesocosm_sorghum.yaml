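# 121-day controlled mesocosm: sorghum columns amended with a crushed
# Oregon-basalt-like assemblage; dissolution factor F_D = 0.5.
site:
  latitude: 51.4
  z_a: 0.30
  texture_class: loam
  cec: 40.0
schedule:
  start: 2017-05-01
  end: 2017-08-29
feedstock:
  f_d: 0.5
  events:
    - date: 2017-05-02
      rate: 5.0            # kg rock m-2 (mesocosm-scale dosing)
      specific_surface_area: 1200.0
      mineral_fractions:   # plagioclase/pyroxene-dominated effusive basalt
        albite: 0.45       # plagioclase represented by albite kinetics
        diopside: 0.30
        chlorite: 0.15
        quartz: 0.10
vegetation:
  pft: sorghum
  seed_carbon: 10.0
chemistry:
  soil_co2_init_ppm: 4000.0
initial:
  s_eff: 0.60
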