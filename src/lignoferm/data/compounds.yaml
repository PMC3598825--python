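# Compound registry: elemental formulas and molar masses used throughout.
# Atom counts are per molecule; the biomass entry is a per-carbon-mol
# pseudo-formula (CH2N0.25O0.5), hence the fractional counts.
# Acetate and lactate are carried as their free acids.
glucose:        {carbon: 6, hydrogen: 12, oxygen: 6, nitrogen: 0, molar_mass: 180.16}
galactose:      {carbon: 6, hydrogen: 12, oxygen: 6, nitrogen: 0, molar_mass: 180.16}
mannose:        {carbon: 6, hydrogen: 12, oxygen: 6, nitrogen: 0, molar_mass: 180.16}
xylose:         {carbon: 5, hydrogen: 10, oxygen: 5, nitrogen: 0, molar_mass: 150.13}
arabinose:      {carbon: 5, hydrogen: 10, oxygen: 5, nitrogen: 0, molar_mass: 150.13}
anhydrohexose:  {carbon: 6, hydrogen: 10, oxygen: 5, nitrogen: 0, molar_mass: 162.14}
anhydropentose: {carbon: 5, hydrogen: 8,  oxygen: 4, nitrogen: 0, molar_mass: 132.11}
ethanol:        {carbon: 2, hydrogen: 6,  oxygen: 1, nitrogen: 0, molar_mass: 46.07}
acetate:        {carbon: 2, hydrogen: 4,  oxygen: 2, nitrogen: 0, molar_mass: 60.05}
lactate:        {carbon: 3, hydrogen: 6,  oxygen: 3, nitrogen: 0, molar_mass: 90.08}
co2:            {carbon: 1, hydrogen: 0,  oxygen: 2, nitrogen: 0, molar_mass: 44.01}
h2:             {carbon: 0, hydrogen: 2,  oxygen: 0, nitrogen: 0, molar_mass: 2.016}
water:          {carbon: 0, hydrogen: 2,  oxygen: 1, nitrogen: 0, molar_mass: 18.015}
biomass:        {carbon: 1, hydrogen: 2,  oxygen: 0.5, nitrogen: 0.25, molar_mass: 25.53}
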