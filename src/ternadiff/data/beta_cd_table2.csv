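c1,c2,x1,d11,sd11,d12,sd12,d21,sd21,d22,sd22
0.000,0.007,0.000,1.011,0.020,0.013,0.085,-0.030,0.019,0.399,0.012
0.0035,0.0035,0.500,1.008,0.010,0.030,0.085,-0.020,0.029,0.405,0.010
0.007,0.000,1.000,1.010,0.020,-0.090,0.015,-0.008,0.019,0.427,0.012
0.000,0.010,0.000,1.023,0.002,0.040,0.030,-0.020,0.010,0.398,0.010
0.012,0.008,0.600,1.015,0.010,0.007,0.001,-0.025,0.009,0.431,0.001
0.018,0.002,0.900,1.055,0.020,-0.003,0.001,-0.020,0.046,0.462,0.001
0.020,0.000,1.000,1.050,0.029,-0.045,0.007,-0.012,0.010,0.465,0.007
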