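ingredient_id,ATTD_GE_pct,ATTD_CP_pct,ATTD_NDF_pct,ATTD_ADF_pct,ATTD_OM_pct,ME_DE_pct,NE_ME_pct,DE_MJ_kgDM,ME_MJ_kgDM,NE_MJ_kgDM,predicted_NE1_MJ_kgDM,predicted_NE2_MJ_kgDM,relative_error_pct
wheat bran 1,57.2,52.0,48.6,34.5,65.1,93.0,68.2,10.71,9.96,6.79,6.71,6.61,2.0
wheat bran 2,62.6,65.7,53.9,39.8,68.4,92.5,71.7,11.98,11.08,7.94,7.76,7.58,3.5
wheat bran 3,70.8,64.1,59.5,41.0,74.6,91.4,66.0,13.50,12.34,8.15,8.98,8.63,-7.4
wheat bran 4,57.1,70.7,55.0,35.7,67.9,93.0,68.1,10.85,10.09,6.87,7.09,6.95,-2.1
wheat bran 5,60.4,63.5,53.6,39.7,63.6,91.9,69.4,11.49,10.56,7.33,7.40,7.17,0.6
wheat bran 6,63.8,73.2,64.7,48.1,72.3,91.4,70.7,12.27,11.22,7.93,7.98,7.69,1.2
wheat shorts,83.1,76.2,63.4,41.8,86.3,93.4,83.7,15.95,14.89,12.47,10.56,10.35,19.3
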