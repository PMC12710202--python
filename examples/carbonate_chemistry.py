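"""Solve the open-system carbonate equilibrium for soil porewater.

Given alkalinity and the soil-air CO2 partial pressure, the charge
balance ALK = [HCO3-] + 2[CO3--] + [OH-] - [H+] fixes the pH; dissolved
inorganic carbon follows from Henry's law and the carbonic-acid ladder.
"""

from erwsim import solve_carbonate_system

print(f"{'ALK mol/m3':>10} {'pCO2 atm':>10} {'pH':>6} {'HCO3- mol/m3':>13}")
for alk, pco2 in [(0.0, 3.95e-4), (0.0, 4e-3), (1.0, 4e-3), (5.0, 4e-3)]:
    ph, co2aq, hco3, co3 = solve_carbonate_system(alk, pco2, temp_c=25.0)
    print(f"{alk:10.2f} {pco2:10.2e} {ph:6.2f} {hco3:13.4f}")

# Rainwater in equilibrium with 400 ppm CO2 sits at pH 5.61; raising the
# soil CO2 tenfold acidifies by ~0.5 units, while each unit of alkalinity
# (weathering-released cation charge) buffers the porewater back up and
# stores carbon as bicarbonate.
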