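row,m12,m22,m23,m32,m33
F/P1_0,0.030,0.536,0.013,0.008,0.039
F/P1_1,0.029,0.504,0.036,0.030,0.043
F/P1_2,0.028,0.492,-0.003,-0.005,0.042
F/P1_3,0.029,0.526,0.009,0.002,0.048
F/P1_4,0.030,0.510,0.029,0.023,0.045
F/P1_5,0.029,0.524,0.015,0.009,0.048
F/P1_6,0.024,0.485,-0.012,-0.030,0.042
F/P2_0,0.011,0.022,0.018,0.022,0.016
F/P2_1,0.012,0.021,0.019,0.023,0.016
F/P2_2,0.011,0.022,0.019,0.022,0.016
F/P2_3,0.012,0.023,0.020,0.023,0.017
F/P2_4,0.011,0.022,0.019,0.023,0.017
F/P2_5,0.012,0.022,0.019,0.024,0.017
F/P2_6,0.011,0.022,0.018,0.022,0.016
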