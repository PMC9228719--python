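c1,c2,x1,d11,sd11,d12,sd12,d21,sd21,d22,sd22
0.000,0.004,0.000,1.160,0.020,0.050,0.015,-0.030,0.069,0.789,0.012
0.004,0.000,1.000,1.085,0.020,0.010,0.015,-0.008,0.019,0.830,0.012
0.018,0.002,0.900,1.090,0.020,-0.016,0.015,-0.040,0.019,0.693,0.012
0.010,0.000,1.000,1.051,0.004,-0.012,0.015,-0.002,0.019,0.870,0.012
0.000,0.020,0.000,1.001,0.010,0.010,0.014,-0.050,0.009,0.378,0.003
0.011,0.009,0.550,1.005,0.010,-0.078,0.014,-0.028,0.009,0.367,0.003
0.000,0.050,0.000,0.965,0.012,0.025,0.018,-0.101,0.010,0.504,0.001
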