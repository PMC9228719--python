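# 5-fluorouracil + sodium dodecyl sulfate in water, 298.15 K
# complex diffusivity set to the micelle value; CMC of aqueous SDS
d_free_drug: 1.050
d_free_carrier: 0.378
d_complex: 0.100
d_drug_infinite_dilution: 1.168
k_assoc: 20.0
cmc: 0.0083
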