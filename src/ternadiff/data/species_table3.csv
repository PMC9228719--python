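species,role,d
5-FU,drug,1.050
beta-CD,carrier,0.399
5-FU-beta-CD,complex,0.390
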