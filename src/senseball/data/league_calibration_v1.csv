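# Published stage-1 league calibration, version 1.
# alpha_cell is on the scale the calibration is reported on: the probability
# scale (inverse-logit of the posterior mean) for the binomial statistics
# OBP/BB%/K%, and the natural response scale for SLG/FIP.
statistic,league,alpha_cell,gamma_mean
OBP,Rookie,0.358,0.110
OBP,A,0.327,0.118
OBP,AdvA,0.327,0.109
OBP,AA,0.322,0.101
OBP,AAA,0.329,0.103
OBP,MLB,0.292,0.060
BB%,Rookie,0.108,0.316
BB%,A,0.093,0.304
BB%,AdvA,0.096,0.300
BB%,AA,0.093,0.320
BB%,AAA,0.089,0.305
BB%,MLB,0.071,0.275
K%,Rookie,0.170,0.327
K%,A,0.188,0.356
K%,AdvA,0.184,0.335
K%,AA,0.192,0.346
K%,AAA,0.195,0.345
K%,MLB,0.232,0.341
SLG,Rookie,0.432,0.059
SLG,A,0.384,0.050
SLG,AdvA,0.379,0.045
SLG,AA,0.376,0.041
SLG,AAA,0.397,0.047
SLG,MLB,0.351,0.027
FIP,Rookie,3.013,0.356
FIP,A,3.517,0.405
FIP,AdvA,3.377,0.383
FIP,AA,3.613,0.343
FIP,AAA,3.782,0.442
FIP,MLB,4.279,0.556
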