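sd1,ld,sd2,bd,pa,pi,pr
,1,,,0.2245,0.2164,3.79E-02
,-1,,,0.2473,0.2220,1.58E-02
,,,...1,0.3113,0.2833,1.41E-02
,,,p..1,0.0310,0.0222,4.73E-02
-N<,1,,,0.0600,0.0573,4.69E-02
-N<,2,,,0.0682,0.0676,4.72E-02
>N+=,1,,,0.0025,0.0003,2.86E-02
>N+=,2,,,0.0031,0.0003,1.03E-02
>N+=,3,,,0.0025,0.0003,2.86E-02
>S,2,,,0.0031,0.0003,1.03E-02
-C(Ar)<,-1,,,0.0675,0.0673,4.75E-02
Cyc06,-1,,,0.0269,0.0213,3.55E-02
>N+=,,-C(Ar)<,,0.0094,0.0005,4.95E-04
>O,,-C(Ar)<,,0.0247,0.0163,3.82E-02
=NH,,,p..1,0.0025,0.0003,2.81E-02
-N<,,,...1,0.0532,0.0449,2.41E-02
-N<,,,.A.1,0.0595,0.0568,4.74E-02
-N=,,,...0,0.0057,0.0024,3.81E-02
>N+=,,,...0,0.0025,0.0003,2.81E-02
>N+=,,,.a.0,0.0032,0.0003,1.01E-02
>N+=,,,.A.1,0.0025,0.0003,2.81E-02
>O,,,.A.1,0.0120,0.0070,2.60E-02
>S,,,...0,0.0025,0.0003,2.81E-02
>S,,,.a.0,0.0032,0.0003,1.01E-02
>C=,,,...1,0.0101,0.0062,4.37E-02
-C(Ar)<,,,...1,0.0925,0.0923,4.14E-02
Cyc06,,,...0,0.0304,0.0227,2.02E-02
CycAr06,,,...1,0.0754,0.0725,4.28E-02
,1,,...1,0.1049,0.0951,4.20E-02
,-1,,...0,0.0550,0.0429,3.24E-02
,-1,,...1,0.1816,0.1750,4.09E-02
>N+=,2,-C(Ar)<,,0.0041,0.0005,3.74E-02
Cyc06,-1,,...0,0.0245,0.0204,4.77E-02
>N+=,,-C(Ar)<,.A.1,0.0043,0.0005,3.54E-02
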