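diet_id,GE_MJ_kgDM,DM_pct,CP_pctDM,EE_pctDM,NDF_pctDM,ADF_pctDM,ash_pctDM
basal,18.41,88.45,18.76,2.25,13.43,4.18,4.95
wheat bran diet 1,18.36,88.31,19.05,2.00,21.83,6.39,6.41
wheat bran diet 2,18.54,87.85,19.54,2.23,21.59,6.26,5.90
wheat bran diet 3,18.70,88.23,19.89,2.09,18.83,5.34,5.78
wheat bran diet 4,18.43,88.07,19.90,2.30,23.05,6.39,6.08
wheat bran diet 5,18.46,88.78,18.43,1.23,23.91,6.90,5.93
wheat bran diet 6,18.62,88.38,19.52,2.10,24.26,6.70,5.93
wheat shorts diet,18.55,88.67,19.84,2.25,14.56,3.85,5.44
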