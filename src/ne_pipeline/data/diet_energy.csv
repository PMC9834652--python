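diet_id,MEI_kJ_mbw_d,THP_kJ_mbw_d,adjTHP_kJ_mbw_d,FHP_kJ_mbw_d,REP_kJ_mbw_d,REL_kJ_mbw_d,RE_kJ_mbw_d,RQ_fed,RQ_fasted,ME_DE_pct,NE_ME_pct,DE_MJ_kgDM,ME_MJ_kgDM,NE_MJ_kgDM
basal,2311,1196,1182,805,448,668,1115,1.07,0.82,97.8,83.2,16.05,15.71,13.08
wheat bran diet 1,2228,1213,1222,765,405,610,1015,1.09,0.84,96.8,80.0,14.27,13.80,11.03
wheat bran diet 2,2133,1195,1230,788,406,532,938,1.09,0.84,96.5,80.5,14.69,14.18,11.41
wheat bran diet 3,2138,1191,1224,805,403,545,948,1.09,0.83,95.8,82.5,14.59,14.00,11.45
wheat bran diet 4,2240,1278,1284,815,453,509,962,1.07,0.82,96.5,79.7,14.55,14.06,11.21
wheat bran diet 5,2320,1311,1295,786,411,598,1009,1.07,0.81,96.2,77.5,14.74,14.21,10.99
wheat bran diet 6,2306,1279,1267,812,431,596,1027,1.09,0.81,96.2,80.2,14.81,14.25,11.43
wheat shorts diet,2355,1209,1183,816,503,643,1147,1.08,0.82,96.8,83.3,15.82,15.27,12.74
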