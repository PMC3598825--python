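id,strains,substrate,loading_g_l,ph_mode,substrate_final_g_l,ethanol_mM,acetate_mM,lactate_mM,co2_mM,h2_mM,cdw_g_l,replicate
glc-004c,DIB004C,glucose,10,uncontrolled-flask,4.4871,5.5,21.9,35.3,8.8,20.8,0.2476,1
glc-097x,DIB097X,glucose,10,uncontrolled-flask,0.0191,53.1,5.3,55.6,9.5,2.4,0.3676,1
av-004c,DIB004C,avicel,10,uncontrolled-flask,5.88,4.8,11.6,30.4,9.1,10.0,0.2374,1
av-co,DIB004C+DIB097X,avicel,10,uncontrolled-flask,6.34,6.2,10.3,25.7,12.6,9.2,0.1915,1
wp-004c,DIB004C,washed_poplar,6.05,uncontrolled-flask,4.57,0.2,13.3,7.5,5.1,8.1,0.2961,1
wp-co,DIB004C+DIB097X,washed_poplar,6.05,uncontrolled-flask,4.21,3.2,13.2,6.3,5.7,11.0,0.2604,1
wm-004c,DIB004C,washed_miscanthus,6.09,uncontrolled-flask,4.14,2.7,11.6,6.3,4.4,7.2,0.2272,1
wm-co,DIB004C+DIB097X,washed_miscanthus,6.09,uncontrolled-flask,4.08,5.2,13.0,5.5,4.0,9.8,0.2145,1
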