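method,ratio,mae,rmse,r2
L2R,0.1,83.61,115.79,0.8537
IRAST,0.1,60.50,88.00,0.9222
PAL,0.1,90.97,121.59,0.8167
S2FPR,0.1,,,
CDMENet,0.1,30.57,40.21,0.9787
L2R,0.2,72.47,89.86,0.9021
IRAST,0.2,51.52,72.02,0.9389
PAL,0.2,80.37,102.33,0.8503
S2FPR,0.2,102.76,121.77,0.7829
CDMENet,0.2,28.01,37.65,0.9817
L2R,0.3,63.81,89.64,0.9148
IRAST,0.3,41.81,60.84,0.9508
PAL,0.3,83.16,106.32,0.8464
S2FPR,0.3,108.42,138.50,0.7753
CDMENet,0.3,27.58,37.22,0.9823
L2R,0.4,67.67,94.98,0.8996
IRAST,0.4,44.43,64.51,0.9509
PAL,0.4,85.62,118.13,0.8115
S2FPR,0.4,95.97,135.45,0.8112
CDMENet,0.4,27.12,36.12,0.9829
L2R,0.5,60.71,87.99,0.9257
IRAST,0.5,39.11,58.66,0.9612
PAL,0.5,76.04,92.91,0.8868
S2FPR,0.5,90.74,126.71,0.8172
CDMENet,0.5,26.47,36.32,0.9839
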