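# Photometric and colorimetric parameters of the 25 experimental stimuli
# (correlated colour temperature, Duv, horizontal illuminance, CIE 1931 x, y).
id,cct_K,duv,Ev_lux,x,y
SPD_1,2693,8.68e-4,1000,0.4619,0.4134
SPD_2,3096,2.87e-3,470,0.4343,0.4103
SPD_3,10021,4.43e-3,90,0.2778,0.2935
SPD_4,3107,9.83e-4,90,0.4308,0.4043
SPD_5,5008,4.42e-4,45,0.3450,0.3524
SPD_6,2705,8.28e-4,2000,0.4609,0.4131
SPD_7,2693,-5.24e-5,90,0.4604,0.4106
SPD_8,2691,8.87e-4,470,0.4621,0.4135
SPD_9,4100,-2.84e-5,90,0.3761,0.3740
SPD_10,5008,3.89e-3,2000,0.3456,0.3599
SPD_11,3104,-2.79e-4,45,0.4294,0.4007
SPD_12,2698,-4.11e-4,45,0.4593,0.4094
SPD_13,10029,1.32e-3,45,0.2797,0.2897
SPD_14,10012,3.57e-3,2000,0.2784,0.2925
SPD_15,4097,-2.70e-3,45,0.3746,0.3674
SPD_16,4092,9.11e-4,2000,0.3771,0.3766
SPD_17,3103,1.15e-3,2000,0.4314,0.4049
SPD_18,5011,2.99e-3,90,0.3454,0.3579
SPD_19,10003,3.99e-3,1000,0.2782,0.2931
SPD_20,5006,1.50e-3,470,0.3452,0.3547
SPD_21,10004,3.26e-3,470,0.2787,0.2922
SPD_22,3099,1.68e-3,1000,0.4324,0.4066
SPD_23,4101,1.10e-3,470,0.3768,0.3768
SPD_24,4109,1.10e-3,1000,0.3765,0.3766
SPD_25,5007,4.36e-3,1000,0.3458,0.3609
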