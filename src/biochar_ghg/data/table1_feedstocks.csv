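feedstock,ash_pct,ash_sd_pct,ash_n,c_daf_pct,c_daf_sd_pct,c_daf_n,lignin_pct,lignin_sd_pct,lignin_n
bagasse,5.8,4.4,20,49.0,2.2,18,17.7,2.7,13
bamboo,3.9,2.6,6,48.3,1.2,6,23.3,2.1,6
herbaceous,7.0,5.4,495,48.9,2.4,390,11.8,7.1,294
maize stover,5.2,3.9,29,47.7,2.4,18,9.5,4.8,28
manure,28.5,15.2,30,45.2,9.9,36,11.3,11.3,5
paper sludge,32.7,14.1,16,48.4,9.2,12,23.5,6.4,4
pits/shells/stones,3.8,3.2,119,50.6,4.3,119,33.2,14.8,53
rice residues,17.9,3.9,42,48.3,3.2,33,17.9,9.6,13
sewage sludge,39.4,9.9,54,51.1,5.6,56,6.0,9.7,13
wheat straw,7.2,3.8,104,48.8,1.5,69,12.3,7.0,42
wood,2.2,3.9,507,50.7,2.1,488,24.7,6.8,136
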