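diet_id,ingredient_id,inclusion_pct_asfed,is_mixture_component,is_test_ingredient
basal,corn,71.61,1,0
basal,soybean meal,24.95,1,0
basal,dicalcium phosphate,0.90,0,0
basal,limestone,0.90,0,0
basal,salt,0.35,0,0
basal,premix,0.50,0,0
basal,L-Lys HCl,0.50,1,0
basal,DL-Met,0.07,1,0
basal,L-Thr,0.16,1,0
basal,L-Val,0.06,1,0
wheat bran diet 1,corn,49.54,1,0
wheat bran diet 1,soybean meal,17.26,1,0
wheat bran diet 1,dicalcium phosphate,0.90,0,0
wheat bran diet 1,limestone,0.90,0,0
wheat bran diet 1,salt,0.35,0,0
wheat bran diet 1,premix,0.50,0,0
wheat bran diet 1,L-Lys HCl,0.35,1,0
wheat bran diet 1,DL-Met,0.05,1,0
wheat bran diet 1,L-Thr,0.11,1,0
wheat bran diet 1,L-Val,0.04,1,0
wheat bran diet 1,wheat bran 1,30.00,0,1
wheat bran diet 2,corn,49.54,1,0
wheat bran diet 2,soybean meal,17.26,1,0
wheat bran diet 2,dicalcium phosphate,0.90,0,0
wheat bran diet 2,limestone,0.90,0,0
wheat bran diet 2,salt,0.35,0,0
wheat bran diet 2,premix,0.50,0,0
wheat bran diet 2,L-Lys HCl,0.35,1,0
wheat bran diet 2,DL-Met,0.05,1,0
wheat bran diet 2,L-Thr,0.11,1,0
wheat bran diet 2,L-Val,0.04,1,0
wheat bran diet 2,wheat bran 2,30.00,0,1
wheat bran diet 3,corn,49.54,1,0
wheat bran diet 3,soybean meal,17.26,1,0
wheat bran diet 3,dicalcium phosphate,0.90,0,0
wheat bran diet 3,limestone,0.90,0,0
wheat bran diet 3,salt,0.35,0,0
wheat bran diet 3,premix,0.50,0,0
wheat bran diet 3,L-Lys HCl,0.35,1,0
wheat bran diet 3,DL-Met,0.05,1,0
wheat bran diet 3,L-Thr,0.11,1,0
wheat bran diet 3,L-Val,0.04,1,0
wheat bran diet 3,wheat bran 3,30.00,0,1
wheat bran diet 4,corn,49.54,1,0
wheat bran diet 4,soybean meal,17.26,1,0
wheat bran diet 4,dicalcium phosphate,0.90,0,0
wheat bran diet 4,limestone,0.90,0,0
wheat bran diet 4,salt,0.35,0,0
wheat bran diet 4,premix,0.50,0,0
wheat bran diet 4,L-Lys HCl,0.35,1,0
wheat bran diet 4,DL-Met,0.05,1,0
wheat bran diet 4,L-Thr,0.11,1,0
wheat bran diet 4,L-Val,0.04,1,0
wheat bran diet 4,wheat bran 4,30.00,0,1
wheat bran diet 5,corn,49.54,1,0
wheat bran diet 5,soybean meal,17.26,1,0
wheat bran diet 5,dicalcium phosphate,0.90,0,0
wheat bran diet 5,limestone,0.90,0,0
wheat bran diet 5,salt,0.35,0,0
wheat bran diet 5,premix,0.50,0,0
wheat bran diet 5,L-Lys HCl,0.35,1,0
wheat bran diet 5,DL-Met,0.05,1,0
wheat bran diet 5,L-Thr,0.11,1,0
wheat bran diet 5,L-Val,0.04,1,0
wheat bran diet 5,wheat bran 5,30.00,0,1
wheat bran diet 6,corn,49.54,1,0
wheat bran diet 6,soybean meal,17.26,1,0
wheat bran diet 6,dicalcium phosphate,0.90,0,0
wheat bran diet 6,limestone,0.90,0,0
wheat bran diet 6,salt,0.35,0,0
wheat bran diet 6,premix,0.50,0,0
wheat bran diet 6,L-Lys HCl,0.35,1,0
wheat bran diet 6,DL-Met,0.05,1,0
wheat bran diet 6,L-Thr,0.11,1,0
wheat bran diet 6,L-Val,0.04,1,0
wheat bran diet 6,wheat bran 6,30.00,0,1
wheat shorts diet,corn,49.54,1,0
wheat shorts diet,soybean meal,17.26,1,0
wheat shorts diet,dicalcium phosphate,0.90,0,0
wheat shorts diet,limestone,0.90,0,0
wheat shorts diet,salt,0.35,0,0
wheat shorts diet,premix,0.50,0,0
wheat shorts diet,L-Lys HCl,0.35,1,0
wheat shorts diet,DL-Met,0.05,1,0
wheat shorts diet,L-Thr,0.11,1,0
wheat shorts diet,L-Val,0.04,1,0
wheat shorts diet,wheat shorts,30.00,0,1
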