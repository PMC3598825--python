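# Example simulation scenario: a cellulolytic, lactate-leaning strain paired
# with a saccharolytic ethanologen on 10 g/l microcrystalline cellulose in
# unbuffered flasks.
strains:
  - name: cellulolytic
    product_split: [0.08, 0.65, 0.27]
    biomass_fraction: 0.05
    consumption_extent: 0.9
    scope: cellulolytic
  - name: ethanologenic
    product_split: [0.68, 0.06, 0.26]
    biomass_fraction: 0.05
    consumption_extent: 0.9
    scope: saccharolytic
substrate:
  name: avicel
  loading: 10.0
  composition:
    glucan: 1.0
ph_mode: uncontrolled-flask
relative_sd: 0.05
n_replicates: 3
sugar_share: 0.5
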