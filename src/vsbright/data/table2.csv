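# Alpha-opic equivalent daylight (D65) illuminances of the 25 experimental
# stimuli, in lux: melanopic, rhodopic, L-cone-opic, M-cone-opic, S-cone-opic.
id,Ev_lux,mel_edi,rh_edi,lc_edi,mc_edi,sc_edi
SPD_1,1000,431,528,1018,784,265
SPD_2,470,234,278,474,386,157
SPD_3,90,104,102,89,94,120
SPD_4,90,45,54,91,74,33
SPD_5,45,36,38,45,42,35
SPD_6,2000,863,1055,2035,1569,537
SPD_7,90,38,47,92,70,25
SPD_8,470,203,248,479,368,124
SPD_9,90,61,67,90,80,54
SPD_10,2000,1581,1691,1985,1875,1473
SPD_11,45,22,26,45,37,17
SPD_12,45,19,23,46,35,13
SPD_13,45,52,51,45,47,61
SPD_14,2000,2290,2261,1983,2088,2671
SPD_15,45,31,33,45,40,28
SPD_16,2000,1348,1486,1997,1783,1175
SPD_17,2000,1010,1190,2018,1645,718
SPD_18,90,71,75,89,84,67
SPD_19,1000,1146,1132,991,1045,1332
SPD_20,470,372,396,467,439,359
SPD_21,470,539,532,466,491,629
SPD_22,1000,502,594,1009,822,351
SPD_23,470,318,350,469,419,276
SPD_24,1000,677,746,999,893,589
SPD_25,1000,791,847,992,938,731
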