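label,vmax,initial_ratio,recovery_time,amount_of_change
Patient 1,1.1,209.04,,0.07
Patient 2,36.7,666.76,279.21,0.19
Patient 3,0.8,692.25,254.31,0.20
Patient 4,0.8,388.00,552.41,0.12
Patient 5,37.1,680.83,289.74,0.19
Patient 6,14.5,675.73,272.29,0.19
Patient 7,8.9,642.44,286.27,0.19
Patient 8,0.8,515.93,398.94,0.16
Patient 9,0.6,585.01,314.17,0.17
Patient 10,18.9,696.04,275.23,0.20
Control,64,700.38,235.52,0.20
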