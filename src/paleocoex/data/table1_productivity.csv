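region,region_name,npp_mean,npp_class,npp_sd,npp_cv,npp_cv_class,small_mean,small_class,small_ll,small_ul,medium_mean,medium_class,medium_ll,medium_ul,large_mean,large_class,large_ll,large_ul
R_1,Lower Danube Basin,0.357,H,0.02,5.13,L,65.39,H,50.23,85.14,321.66,H,247.06,418.78,462.86,H,355.51,602.62
R_2,Carpathian region,0.262,L,0.05,17.74,H,20.29,M,16.2,25.41,176.3,M,140.76,220.83,363.6,H,290.29,455.42
R_3,Balkan Mediterranean region,0.162,L,0.02,10.38,M,11.16,L,8.87,14.04,168.28,L,133.77,211.7,106.24,L,84.45,133.65
R_4,Upper Danube Basin,0.316,H,0.03,10.52,M,59.73,H,46.73,76.35,271.66,M,212.53,347.23,396.5,H,310.2,506.81
R_5,Northern Europe,0.273,M,0.04,15.17,M,21.24,M,16.91,26.7,231.79,M,184.46,291.27,337.61,H,268.68,424.24
R_6,Adriatic region,0.331,H,0.02,7.22,L,62.08,H,48.26,79.86,256.32,M,199.26,329.73,457.02,H,355.27,587.9
R_7,Prealpine region,0.268,M,0.06,22.63,H,40.34,M,32.15,50.61,186.82,M,148.91,234.39,348.95,H,278.14,437.8
R_8,Italian Mediterranean region,0.292,M,0.02,7.69,L,54.64,H,43.18,69.14,289.4,M,228.69,366.21,306.08,M,241.88,387.32
R_9,Ligurian region,0.334,H,0.02,7.45,L,32.54,M,25.25,41.92,327.7,H,254.33,422.22,427.03,H,331.43,550.22
R_10,Rhone basin,0.312,H,0.04,11.73,M,37.63,M,29.5,48.01,364.79,H,285.96,465.34,310.35,H,243.29,395.9
R_11,Aquitaine region,0.304,M,0.07,23.61,H,53.77,H,42.28,68.39,278.69,M,219.14,354.43,357.02,H,280.72,454.04
R_12,Cantabrian region,0.306,M,0.07,23.25,H,51.21,H,40.24,65.18,260.3,M,204.52,331.28,383.7,H,301.48,488.34
R_13,Northern Meseta,0.264,M,0.04,17.02,M,50.92,H,40.63,63.81,241.63,M,192.8,302.83,273.34,M,218.11,342.57
R_14,Iberian Medomediterranean region,0.307,H,0.03,9.24,L,31.25,M,24.54,39.8,321.25,H,252.26,409.1,347.16,H,272.62,442.1
R_15,Iberian Mediterranean region,0.263,L,0.02,9.02,L,48.4,H,38.63,60.63,405.91,H,323.99,508.53,108.29,M,86.44,135.67
R_16,Britain,0.196,L,0.08,41.7,H,13.46,L,10.83,16.73,103.88,L,83.57,129.13,254.56,M,204.78,316.45
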