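stage,temperature_C,mean_duration_d,se_d,n,survival
egg,16,9.75,0.07,150,0.6571
egg,20,6.52,0.04,112,0.7038
egg,24,4.76,0.04,107,0.8353
egg,28,3.71,0.05,80,0.8750
egg,30,3.00,0.00,106,0.7736
egg,32,3.00,0.00,84,0.6190
larva_I,16,8.92,0.18,97,0.9175
larva_I,20,4.97,0.09,78,0.8590
larva_I,24,3.15,0.07,89,1.0
larva_I,28,2.38,0.10,59,1.0
larva_I,30,2.00,0.00,82,1.0
larva_I,32,2.45,0.10,52,1.0
larva_II,16,6.48,0.14,89,0.9438
larva_II,20,3.68,0.10,67,0.9851
larva_II,24,2.41,0.06,89,0.9775
larva_II,28,2.00,0.04,59,0.9492
larva_II,30,1.04,0.03,82,1.0
larva_II,32,1.84,0.10,52,1.0
larva_III,16,6.18,0.13,84,0.9048
larva_III,20,4.00,0.12,66,0.9394
larva_III,24,2.15,0.05,87,0.9770
larva_III,28,2.06,0.03,56,1.0
larva_III,30,1.76,0.06,82,0.9512
larva_III,32,1.95,0.10,52,0.9808
larva_IV,16,6.72,0.17,76,0.8553
larva_IV,20,5.53,0.15,62,0.9677
larva_IV,24,2.64,0.07,85,0.9882
larva_IV,28,2.44,0.07,56,0.9464
larva_IV,30,1.88,0.05,78,0.9487
larva_IV,32,2.00,0.08,51,1.0
larva_V,16,8.22,0.16,65,0.8308
larva_V,20,6.18,0.13,60,1.0
larva_V,24,3.72,0.08,84,0.9643
larva_V,28,2.87,0.09,53,0.9811
larva_V,30,3.07,0.07,74,0.9324
larva_V,32,2.74,0.16,51,0.8627
larva_VI,16,8.33,1.33,54,0.9259
larva_VI,30,4.50,1.15,69,0.9855
larva_VI,32,2.67,0.19,44,0.8636
larvae_total,16,37.02,0.34,97,0.5155
larvae_total,20,24.37,0.31,78,0.7692
larvae_total,24,14.06,0.12,89,0.9101
larvae_total,28,11.75,0.13,59,0.8814
larvae_total,30,10.16,0.18,82,0.8293
larvae_total,32,11.89,0.28,52,0.7308
prepupa,16,101.68,11.03,50,0.38
prepupa,20,4.64,0.11,60,0.8333
prepupa,24,2.28,0.05,81,0.9630
prepupa,28,1.94,0.03,52,1.0
prepupa,30,2.11,0.06,68,0.9265
prepupa,32,2.25,0.19,38,0.8421
pupa,16,24.67,1.61,19,0.3157
pupa,20,12.32,0.14,50,0.94
pupa,24,8.62,0.07,78,0.8718
pupa,28,7.08,0.05,52,0.9808
pupa,30,6.80,0.09,63,0.8571
pupa,32,6.14,0.08,32,0.6563
immature_total,16,134.33,25.19,6,0.04
immature_total,20,46.62,0.23,47,0.4241
immature_total,24,29.34,0.17,68,0.6382
immature_total,28,24.47,0.17,51,0.7564
immature_total,30,22.04,0.20,54,0.5095
immature_total,32,22.43,0.25,21,0.2500
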