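row,m12,m22,m23,m32,m33
T/P1_0,0.033,0.560,0.001,-0.006,0.039
T/P1_1,0.039,0.492,0.006,-0.001,0.047
T/P1_2,0.039,0.453,-0.016,-0.023,0.052
T/P1_3,0.037,0.418,-0.004,-0.006,0.061
T/P1_4,0.033,0.379,0.003,-0.002,0.057
T/P1_5,0.031,0.367,0.004,-0.003,0.061
T/P1_6,0.026,0.307,-0.016,-0.021,0.061
T/P2_0,0.013,0.024,0.020,0.023,0.019
T/P2_1,0.013,0.025,0.021,0.023,0.019
T/P2_2,0.013,0.029,0.019,0.021,0.019
T/P2_3,0.013,0.028,0.020,0.021,0.019
T/P2_4,0.012,0.031,0.019,0.020,0.019
T/P2_5,0.012,0.027,0.019,0.020,0.019
T/P2_6,0.011,0.027,0.018,0.018,0.018
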