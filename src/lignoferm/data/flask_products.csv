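id,strains,substrate,loading_g_l,ph_mode,substrate_final_g_l,ethanol_mM,acetate_mM,lactate_mM,co2_mM,h2_mM,cdw_g_l,replicate
av-mono,DIB004C,avicel,10,uncontrolled-flask,,2.7,21.4,9.0,,,,1
av-co-g,DIB004C+DIB004G,avicel,10,uncontrolled-flask,,8.8,19.9,11.0,,,,1
av-co-x,DIB004C+DIB097X,avicel,10,uncontrolled-flask,,10.3,18.6,11.8,,,,1
wp-mono,DIB004C,washed_poplar,2.9,uncontrolled-flask,,1.5,10.9,6.2,,,,1
wp-co-g,DIB004C+DIB004G,washed_poplar,2.9,uncontrolled-flask,,5.7,14.0,6.6,,,,1
wp-co-x,DIB004C+DIB097X,washed_poplar,2.9,uncontrolled-flask,,3.7,14.1,8.3,,,,1
up-mono-c,DIB004C,unwashed_poplar,10,uncontrolled-flask,,2.6,12.0,6.1,,,,1
up-mono-g,DIB004G,unwashed_poplar,10,uncontrolled-flask,,4.3,4.4,3.0,,,,1
up-mono-x,DIB097X,unwashed_poplar,10,uncontrolled-flask,,5.1,4.3,0.0,,,,1
up-co-g,DIB004C+DIB004G,unwashed_poplar,10,uncontrolled-flask,,5.7,11.6,3.1,,,,1
up-co-x,DIB004C+DIB097X,unwashed_poplar,10,uncontrolled-flask,,7.0,11.4,3.5,,,,1
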