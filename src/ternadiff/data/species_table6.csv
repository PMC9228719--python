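species,role,d
5-FU,drug,1.050
SDS,carrier,0.378
5-FU-SDS,complex,0.100
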