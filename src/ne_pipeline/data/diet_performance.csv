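diet_id,BW_kg,DMI_kg_d,ATTD_DM_pct,ATTD_GE_pct,ATTD_CP_pct,ATTD_NDF_pct,ATTD_ADF_pct,ATTD_OM_pct,UE_DE_pct,CH4E_DE_pct,N_intake_g_d,N_fecal_g_d,N_urinary_g_d,N_retention_g_d
basal,41.5,1.37,87.82,88.02,83.21,62.86,53.87,89.19,1.56,0.43,41.2,5.4,7.7,28.2
wheat bran diet 1,43.0,1.54,80.00,79.12,72.80,54.59,39.14,81.81,2.71,0.40,47.0,11.6,9.5,26.0
wheat bran diet 2,43.5,1.45,80.88,80.00,77.29,57.69,43.16,82.80,3.15,0.49,44.4,9.2,9.1,26.2
wheat bran diet 3,39.7,1.39,78.87,78.99,72.82,49.23,43.22,81.11,3.66,0.49,44.2,10.3,9.1,24.9
wheat bran diet 4,41.1,1.48,80.80,79.12,78.93,58.30,40.08,82.65,3.05,0.41,46.5,9.6,8.7,28.2
wheat bran diet 5,39.1,1.48,79.24,80.01,76.59,57.51,43.09,81.33,3.37,0.48,43.6,11.1,7.6,24.9
wheat bran diet 6,42.8,1.54,82.40,80.11,79.76,63.92,49.50,84.01,3.41,0.31,47.0,11.7,7.9,27.4
wheat shorts diet,39.0,1.39,86.63,86.21,80.76,63.15,44.67,88.30,3.15,0.37,44.1,8.1,7.5,28.4
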