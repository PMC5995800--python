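code,ed20_mg_kg,index,ed20_umol_kg,level,iop_cluster
RU 0185,6.60,2,12.54,1,0
RU 0238,22.40,1,51.92,1,0
RU 0239,19.00,1,43.85,1,0
RU 0243,11.70,1,25.47,1,0
RU 0244,15.00,1,32.51,1,0
RU 0247,11.22,1,26.01,1,1
RU 0850,19.95,1,39.76,1,0
RU 0284,7.40,2,17.65,1,1
RU 0412,17.80,1,43.17,1,1
RU 0437,7.00,2,15.04,1,0
RU 0438,8.90,2,14.21,1,0
RU 0441,3.62,3,8.17,1,1
RU 0477,4.30,2,8.20,1,1
RU 0487,12.00,1,23.80,1,0
RU 0490,5.60,2,11.73,1,0
RU 0519,2.50,3,3.95,2,0
RU 0551,5.10,2,16.44,1,1
RU 0554,13.10,1,29.36,1,0
RU 0555,5.30,2,14.76,1,1
RU 0576,3.23,3,6.65,2,0
RU 0615,11.70,1,26.15,1,1
RU 0616,51.20,0,113.96,0,0
RU 0828,9.50,2,28.86,1,0
RU 0829,25.10,0,73.56,0,0
RU 0832,6.90,2,17.91,1,0
RU 0839,3.80,3,12.68,1,1
RU 0842,1.30,3,3.62,2,0
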