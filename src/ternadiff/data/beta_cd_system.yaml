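# 5-fluorouracil + beta-cyclodextrin in water, 298.15 K
# diffusivities in 1e-9 m^2 s^-1, concentrations in mol dm^-3, K in mol^-1 dm^3
d_free_drug: 1.050
d_free_carrier: 0.399
d_complex: 0.390
d_drug_infinite_dilution: 1.168
k_assoc: 10.0
cmc: null
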