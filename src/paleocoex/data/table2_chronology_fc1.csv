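region,region_name,nai_mode,nai_hpd68_young,nai_hpd68_old,nai_hpd95_young,nai_hpd95_old,sai_mode,sai_hpd68_young,sai_hpd68_old,sai_hpd95_young,sai_hpd95_old
R_1,Lower Danube Basin,37.79,35.65,39.25,29.28,39.94,45.73,44.99,47.48,44.75,54.92
R_2,Carpathian region,44.54,43.36,45.36,38.97,45.93,42.16,42.00,42.30,41.64,42.58
R_3,Balkan Mediterranean region,44.85,42.62,46.87,38.25,49.60,39.28,38.85,39.85,38.15,41.95
R_4,Upper Danube Basin,38.02,36.85,39.10,34.01,40.40,45.02,44.09,46.07,42.97,49.33
R_5,Northern Europe,41.75,40.50,42.51,35.13,43.07,39.93,38.49,41.74,37.02,46.42
R_6,Adriatic region,42.88,42.22,43.43,41.33,44.06,42.98,42.26,44.31,41.46,46.66
R_7,Prealpine region,41.86,39.87,42.82,33.14,43.21,44.30,43.14,45.97,42.08,49.99
R_8,Italian Mediterranean region,39.68,38.93,40.51,34.51,41.51,44.1,43.57,45.21,42.09,48.77
R_9,Ligurian region,40.48,40.11,40.84,37.85,41.24,41.45,40.91,42.33,40.59,46.30
R_10,Rhone basin,36.74,35.65,37.59,30.68,38.45,46.23,44.42,48.94,43.02,55.17
R_11,Aquitaine region,38.26,34.81,39.99,27.43,40.85,43.03,41.69,46.49,41.40,57.27
R_12,Cantabrian region,40.78,39.31,41.74,33.57,42.47,43.67,42.37,46.24,41.53,53.85
R_13,Northern Meseta,42.09,39.87,42.75,33.67,43.06,,,,,
R_14,Iberian Medomediterranean region,40.88,39.82,41.51,35.07,41.86,42.53,41.76,43.86,41.48,49.23
R_15,Iberian Mediterranean region,36.65,36.13,37.21,32.15,37.98,42.63,41.92,43.38,40.71,48.23
R_16,Britain,43.31,41.93,44.19,37.21,45.20,42.16,41.94,42.41,41.48,42.88
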