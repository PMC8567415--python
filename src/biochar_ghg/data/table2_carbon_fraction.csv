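feedstock,fc_low,fc_low_sd,fc_medium,fc_medium_sd,fc_high,fc_high_sd,fc_mean,fc_mean_sd,fc_gasification,fc_gasification_sd
bagasse,0.57,0.16,0.62,0.18,0.64,0.20,0.61,0.18,0.43,0.11
bamboo,0.66,0.04,0.72,0.05,0.75,0.06,0.71,0.05,0.51,0.14
herbaceous,0.60,0.09,0.65,0.11,0.66,0.13,0.64,0.11,0.38,0.10
maize stover,0.63,0.06,0.68,0.08,0.70,0.09,0.67,0.08,0.45,0.12
manure,0.39,0.09,0.39,0.11,0.39,0.11,0.39,0.10,0.14,0.04
paper sludge,0.39,0.26,0.41,0.29,0.42,0.31,0.41,0.29,0.12,0.03
pits/shells/stones,0.67,0.06,0.73,0.08,0.76,0.09,0.72,0.08,0.52,0.14
rice residues,0.46,0.05,0.48,0.06,0.48,0.07,0.47,0.06,0.20,0.05
sewage sludge,0.35,0.25,0.37,0.28,0.38,0.29,0.37,0.27,0.10,0.03
wheat straw,0.59,0.06,0.64,0.08,0.65,0.09,0.63,0.08,0.38,0.10
wood,0.70,0.05,0.77,0.06,0.81,0.07,0.76,0.06,0.63,0.17
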