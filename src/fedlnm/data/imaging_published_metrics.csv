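group,sensitivity,specificity,ppv,npv,accuracy,auc,auc_ci_low,auc_ci_high
CT,32.63,92.15,53.45,83.20,79.27,0.624,0.555,0.693
MRI,35.9,93.37,53.85,87.11,83.18,0.646,0.571,0.721
PET/CT,57.69,85.71,50.0,89.11,80.15,0.717,0.647,0.787
C-M,37.5,90.53,51.92,84.15,79.17,0.640,0.561,0.719
C-P,59.15,79.32,46.15,86.64,74.68,0.692,0.618,0.767
M-P,55.0,81.47,43.42,87.1,76.03,0.682,0.601,0.764
C-M-P,56.36,77.14,43.06,85.44,72.17,0.668,0.582,0.753
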