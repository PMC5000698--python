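row,m12,m22,m23,m32,m33
L/P1_0,0.032,0.528,0.075,0.071,0.049
L/P1_1,0.029,0.552,0.019,0.010,0.046
L/P1_2,0.027,0.534,0.037,0.036,0.051
L/P1_3,0.030,0.515,0.044,0.038,0.053
L/P1_4,0.032,0.512,0.056,0.050,0.056
L/P1_5,0.034,0.522,0.019,0.013,0.049
L/P1_6,0.032,0.482,0.004,-0.002,0.044
L/P2_0,0.012,0.019,0.023,0.027,0.018
L/P2_1,0.012,0.018,0.023,0.027,0.018
L/P2_2,0.012,0.018,0.022,0.026,0.018
L/P2_3,0.012,0.018,0.022,0.026,0.019
L/P2_4,0.012,0.019,0.022,0.026,0.019
L/P2_5,0.013,0.019,0.023,0.027,0.019
L/P2_6,0.012,0.019,0.022,0.026,0.018
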