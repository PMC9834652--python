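ingredient_id,GE_MJ_kgDM,DM_pct,CP_pctDM,EE_pctDM,starch_pctDM,NDF_pctDM,ADF_pctDM,IDF_pctDM,SDF_pctDM,TDF_pctDM,ash_pctDM
wheat bran 1,18.72,87.95,17.32,2.13,12.81,51.01,14.47,46.88,3.56,50.45,6.66
wheat bran 2,19.15,87.79,18.84,1.97,17.04,39.63,10.44,37.86,3.79,41.65,5.78
wheat bran 3,19.07,86.92,19.84,2.87,20.81,34.23,9.01,29.73,6.01,35.75,4.82
wheat bran 4,19.00,87.88,17.06,2.70,18.71,42.39,11.28,39.64,3.56,43.21,5.66
wheat bran 5,19.02,87.58,17.09,1.82,15.92,45.44,11.95,45.88,2.17,48.05,5.62
wheat bran 6,19.24,88.32,19.03,2.15,18.15,40.06,10.74,42.20,2.45,44.65,5.24
wheat shorts,19.20,89.80,20.02,2.67,31.85,23.25,3.73,16.93,4.57,21.49,3.20
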