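group,vowel,feature,mean,sd
T2DM,a,meanF0,155.3,33.32
T2DM,o,meanF0,160.09,32.92
T2DM,e,meanF0,166.67,33.55
T2DM,i,meanF0,174.34,37.99
T2DM,u,meanF0,177.14,37.97
T2DM,ü,meanF0,176.97,36.19
T2DM,a,stdevF0,19.65,19.47
T2DM,o,stdevF0,18.08,17.37
T2DM,e,stdevF0,16.56,19.63
T2DM,i,stdevF0,21.05,20.45
T2DM,u,stdevF0,21.4,22.67
T2DM,ü,stdevF0,16.3,15.49
T2DM,a,meanInten,64.41,12.65
T2DM,o,meanInten,67.27,10.53
T2DM,e,meanInten,68.42,9.84
T2DM,i,meanInten,65.78,8.53
T2DM,u,meanInten,68.01,9.73
T2DM,ü,meanInten,66.82,8.91
T2DM,a,stdevInten,16.23,5.29
T2DM,o,stdevInten,16.34,5.35
T2DM,e,stdevInten,16.36,5.73
T2DM,i,stdevInten,14.75,4.56
T2DM,u,stdevInten,15.195,6.348
T2DM,ü,stdevInten,14.32,5.73
T2DM,a,HNR,14.469,4.03
T2DM,o,HNR,18.52,4.59
T2DM,e,HNR,19.29,4.34
T2DM,i,HNR,17.7,4.46
T2DM,u,HNR,21.797,5.075
T2DM,ü,HNR,19.7,4.706
T2DM,a,localShimmer,0.062,0.033
T2DM,o,localShimmer,0.05,0.04
T2DM,e,localShimmer,0.036,0.03
T2DM,i,localShimmer,0.052,0.036
T2DM,u,localShimmer,0.043,0.032
T2DM,ü,localShimmer,0.053,0.037
T2DM,a,localdbShimmer,0.686,0.37
T2DM,o,localdbShimmer,0.53,0.36
T2DM,e,localdbShimmer,0.438,0.325
T2DM,i,localdbShimmer,0.563,0.346
T2DM,u,localdbShimmer,0.455,0.309
T2DM,ü,localdbShimmer,0.54,0.336
T2DM,a,apq3Shimmer,0.029,0.015
T2DM,o,apq3Shimmer,0.02,0.02
T2DM,e,apq3Shimmer,0.018,0.016
T2DM,i,apq3Shimmer,0.025,0.017
T2DM,u,apq3Shimmer,0.022,0.017
T2DM,ü,apq3Shimmer,0.026,0.018
T2DM,a,apq5Shimmer,0.038,0.022
T2DM,o,apq5Shimmer,0.03,0.02
T2DM,e,apq5Shimmer,0.022,0.024
T2DM,i,apq5Shimmer,0.032,0.023
T2DM,u,apq5Shimmer,0.027,0.022
T2DM,ü,apq5Shimmer,0.033,0.024
T2DM,a,apq11Shimmer,0.057,0.042
T2DM,o,apq11Shimmer,0.04,0.06
T2DM,e,apq11Shimmer,0.03,0.032
T2DM,i,apq11Shimmer,0.047,0.053
T2DM,u,apq11Shimmer,0.035,0.028
T2DM,ü,apq11Shimmer,0.043,0.034
T2DM,a,localJitter,0.011,0.008
T2DM,o,localJitter,0.009,0.007
T2DM,e,localJitter,0.009,0.007
T2DM,i,localJitter,0.009,0.007
T2DM,u,localJitter,0.008,0.006
T2DM,ü,localJitter,0.009,0.007
T2DM,a,localabsJitter,0.0,0.0
T2DM,o,localabsJitter,0.0,0.0
T2DM,e,localabsJitter,0.0,0.0
T2DM,i,localabsJitter,0.0,0.0
T2DM,u,localabsJitter,0.0,0.0
T2DM,ü,localabsJitter,0.0,0.0
T2DM,a,rapJitter,0.005,0.004
T2DM,o,rapJitter,0.004,0.004
T2DM,e,rapJitter,0.004,0.004
T2DM,i,rapJitter,0.004,0.004
T2DM,u,rapJitter,0.004,0.003
T2DM,ü,rapJitter,0.004,0.004
T2DM,a,ppq5Jitter,0.006,0.004
T2DM,o,ppq5Jitter,0.005,0.004
T2DM,e,ppq5Jitter,0.005,0.004
T2DM,i,ppq5Jitter,0.004,0.004
T2DM,u,ppq5Jitter,0.004,0.003
T2DM,ü,ppq5Jitter,0.004,0.004
ND,a,meanF0,180.13,44.486
ND,o,meanF0,188.92,41.44
ND,e,meanF0,191.54,43.19
ND,i,meanF0,174.34,37.99
ND,u,meanF0,199.13,45.58
ND,ü,meanF0,194.41,44.05
ND,a,stdevF0,14.979,15.883
ND,o,stdevF0,16.926,17.746
ND,e,stdevF0,19.19,18.172
ND,i,stdevF0,21.05,20.45
ND,u,stdevF0,21.359,19.429
ND,ü,stdevF0,23.583,19.634
ND,a,meanInten,68.749,12.29
ND,o,meanInten,71.217,9.13
ND,e,meanInten,69.494,9.392
ND,i,meanInten,65.78,8.53
ND,u,meanInten,69.126,8.754
ND,ü,meanInten,68.144,9.622
ND,a,stdevInten,14.709,6.247
ND,o,stdevInten,16.349,6.862
ND,e,stdevInten,16.959,5.867
ND,i,stdevInten,14.75,4.56
ND,u,stdevInten,16.068,7.203
ND,ü,stdevInten,14.684,6.257
ND,a,HNR,17.18,3.248
ND,o,HNR,20.507,3.34
ND,e,HNR,20.509,2.936
ND,i,HNR,17.7,4.46
ND,u,HNR,23.511,5.042
ND,ü,HNR,19.889,6.099
ND,a,localShimmer,0.051,0.032
ND,o,localShimmer,0.036,0.02
ND,e,localShimmer,0.036,0.02
ND,i,localShimmer,0.052,0.036
ND,u,localShimmer,0.039,0.032
ND,ü,localShimmer,0.057,0.047
ND,a,localdbShimmer,0.526,0.321
ND,o,localdbShimmer,0.425,0.254
ND,e,localdbShimmer,0.417,0.238
ND,i,localdbShimmer,0.563,0.346
ND,u,localdbShimmer,0.427,0.305
ND,ü,localdbShimmer,0.576,0.415
ND,a,apq3Shimmer,0.025,0.016
ND,o,apq3Shimmer,0.017,0.009
ND,e,apq3Shimmer,0.017,0.01
ND,i,apq3Shimmer,0.025,0.017
ND,u,apq3Shimmer,0.019,0.017
ND,ü,apq3Shimmer,0.029,0.025
ND,a,apq5Shimmer,0.031,0.02
ND,o,apq5Shimmer,0.021,0.011
ND,e,apq5Shimmer,0.021,0.012
ND,i,apq5Shimmer,0.032,0.023
ND,u,apq5Shimmer,0.024,0.021
ND,ü,apq5Shimmer,0.037,0.033
ND,a,apq11Shimmer,0.044,0.029
ND,o,apq11Shimmer,0.031,0.019
ND,e,apq11Shimmer,0.031,0.021
ND,i,apq11Shimmer,0.047,0.053
ND,u,apq11Shimmer,0.031,0.027
ND,ü,apq11Shimmer,0.046,0.044
ND,a,localJitter,0.007,0.006
ND,o,localJitter,0.007,0.005
ND,e,localJitter,0.006,0.004
ND,i,localJitter,0.009,0.007
ND,u,localJitter,0.006,0.003
ND,ü,localJitter,0.009,0.007
ND,a,localabsJitter,0.0,0.0
ND,o,localabsJitter,0.0,0.0
ND,e,localabsJitter,0.0,0.0
ND,i,localabsJitter,0.0,0.0
ND,u,localabsJitter,0.0,0.0
ND,ü,localabsJitter,0.0,0.0
ND,a,rapJitter,0.004,0.003
ND,o,rapJitter,0.004,0.003
ND,e,rapJitter,0.003,0.002
ND,i,rapJitter,0.004,0.004
ND,u,rapJitter,0.003,0.002
ND,ü,rapJitter,0.005,0.004
ND,a,ppq5Jitter,0.004,0.003
ND,o,ppq5Jitter,0.004,0.003
ND,e,ppq5Jitter,0.003,0.002
ND,i,ppq5Jitter,0.004,0.004
ND,u,ppq5Jitter,0.003,0.002
ND,ü,ppq5Jitter,0.005,0.004
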