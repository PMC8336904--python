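sector,cbpa_output,cbpa_value_added,cbic_output,cbic_value_added,in_kind_output,in_kind_value_added,global_output,global_value_added
S1,1.41,0.74,73.92,38.90,23.66,12.45,98.99,52.09
S2,5.42,1.86,259.07,89.11,89.22,30.69,353.71,121.66
S3,8.05,1.76,288.53,62.98,125.11,27.31,421.68,92.04
S4,27.33,6.66,301.24,73.40,372.55,90.78,701.12,170.84
S5,2.72,1.20,97.54,43.07,42.27,18.67,142.54,62.94
S6,8.22,4.79,659.58,383.80,155.83,90.68,823.63,479.27
S7,5.60,2.26,201.93,81.56,87.17,35.21,294.70,119.03
S8,5.56,3.21,444.68,256.76,105.26,60.78,555.50,320.75
S9,4.43,2.15,162.72,78.97,69.18,33.57,236.33,114.69
S10,3.18,1.83,215.01,123.96,57.21,32.98,275.40,158.77
S11,-24.96,-21.43,732.72,629.08,-262.80,-225.63,444.96,382.03
S12,12.56,7.13,200.06,113.49,176.00,99.84,388.62,220.46
S13,3.52,2.75,106.68,83.40,53.17,41.57,163.37,127.72
S14,12.48,7.98,99.66,63.68,167.27,106.87,279.42,178.53
S15,348.36,226.00,52.90,34.32,4458.22,2892.28,4859.47,3152.60
S16,0.32,0.21,207.11,133.59,20.01,12.91,227.44,146.70
Total,424.21,249.10,4103.35,2290.05,5739.31,3360.95,10266.88,5900.09
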