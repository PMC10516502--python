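region,region_name,nai_mode,nai_hpd68_young,nai_hpd68_old,nai_hpd95_young,nai_hpd95_old,sai_mode,sai_hpd68_young,sai_hpd68_old,sai_hpd95_young,sai_hpd95_old
R_1,Lower Danube Basin,39.54,37.94,40.75,33.88,42.72,45.68,44.95,47.24,44.73,54.07
R_2,Carpathian region,45.93,45.68,45.50,47.20,48.86,42.15,41.87,42.40,41.63,42.61
R_3,Balkan Mediterranean region,44.85,42.62,46.87,38.25,49.60,39.28,38.85,39.85,38.15,41.95
R_4,Upper Danube Basin,39.97,39.20,40.70,36.74,41.47,43.29,42.55,44.24,41.79,47.67
R_5,Northern Europe,42.22,41.05,42.81,36.94,43.29,39.98,38.47,41.72,37.08,46.21
R_6,Adriatic region,43.40,42.85,44.19,41.76,45.39,,,,,
R_7,Prealpine region,42.19,40.33,43.07,34.12,43.41,44.35,43.16,45.97,42.09,49.97
R_8,Italian Mediterranean region,39.72,39.12,40.45,36.49,41.51,44.1,43.57,45.21,42.09,48.77
R_9,Ligurian region,40.49,40.82,42.15,37.75,41.25,41.37,44.92,47.82,40.43,45.90
R_10,Rhone basin,40.53,39.47,41.33,33.44,42.01,42.97,42.00,44.44,41.31,50.14
R_11,Aquitaine region,39.59,37.29,40.83,30.36,30.36,41.87,41.15,43.35,40.83,49.58
R_12,Cantabrian region,41.32,40.33,42.02,35.28,42.35,43.53,42.33,42.33,41.53,52.92
R_13,Northern Meseta,42.92,42.23,44.02,40.54,45.54,,,,,
R_14,Iberian Medomediterranean region,40.98,40.03,41.67,35.56,42.02,42.52,41.75,43.78,41.43,48.90
R_15,Iberian Mediterranean region,36.66,36.18,37.23,32.92,37.99,42.63,41.93,43.38,40.75,48.41
R_16,Britain,43.39,41.90,45.15,39.02,48.24,36.16,35.77,36.60,35.28,37.61
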