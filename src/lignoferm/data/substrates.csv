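substrate,polymer,percent
washed_poplar,glucan,58.1
washed_poplar,xylan,0.1
washed_poplar,galactan,0.2
washed_poplar,lignin_acid_soluble,2.7
washed_poplar,lignin_acid_insoluble,34.8
washed_poplar,ash,0.1
raw_poplar,glucan,42.4
raw_poplar,xylan,11.6
raw_poplar,galactan,1.8
raw_poplar,arabinan,2.2
raw_poplar,mannan,2.6
raw_poplar,lignin_acid_soluble,5.4
raw_poplar,lignin_acid_insoluble,25.0
raw_poplar,ash,0.5
avicel,glucan,100.0
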