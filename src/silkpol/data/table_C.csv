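row,m12,m22,m23,m32,m33
C/P1_0,0.034,0.555,0.009,0.002,0.034
C/P1_1,0.036,0.582,0.134,0.131,0.060
C/P1_2,0.039,0.636,0.073,0.067,0.042
C/P1_3,0.032,0.607,0.074,0.067,0.047
C/P1_4,0.030,0.585,0.017,0.006,0.061
C/P1_5,0.025,0.560,-0.010,-0.019,0.113
C/P1_6,0.010,0.441,0.003,-0.009,0.182
C/P2_0,0.013,0.024,0.020,0.022,0.018
C/P2_1,0.014,0.024,0.021,0.025,0.022
C/P2_2,0.017,0.029,0.027,0.029,0.027
C/P2_3,0.018,0.032,0.029,0.030,0.030
C/P2_4,0.019,0.040,0.031,0.034,0.036
C/P2_5,0.029,0.073,0.061,0.066,0.079
C/P2_6,0.032,0.107,0.073,0.078,0.119
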