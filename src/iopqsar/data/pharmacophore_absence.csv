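sd1,ld,sd2,bd,pa,pi,pr
,2,,,0.2204,0.2214,4.18E-02
,3,,,0.1438,0.1471,4.83E-02
,4,,,0.0833,0.0943,4.18E-02
,,,...0,0.2049,0.2133,3.83E-02
,,,.a.1,0.1725,0.1767,4.45E-02
,,,.A.1,0.2102,0.2200,3.66E-02
,,,pA.1,0.0040,0.0133,1.80E-02
-CH3,2,,,0.0044,0.0083,4.25E-02
>C(<),1,,,0.0269,0.0323,4.09E-02
-C(Ar)<,5,,,0.0113,0.0156,4.91E-02
-N<,,-C(Ar)<,,0.1943,0.1966,4.11E-02
-OH,,-C(Ar)<,,0.0012,0.0089,1.04E-02
=O,,-C(Ar)<,,0.0059,0.0184,4.43E-03
>PH<,,-C(Ar)<,,0.0012,0.0110,2.89E-03
-Cl,,-C(Ar)<,,0.0012,0.0079,1.94E-02
-CH3,,-C(Ar)<,,0.0012,0.0068,3.57E-02
>C=,,-C(Ar)<,,0.0059,0.0184,4.43E-03
-C(Ar)<,,CycAr06,,0.1154,0.1264,3.66E-02
-N<,,,...0,0.0551,0.0582,4.72E-02
-OH,,,.A.1,0.0006,0.0046,1.26E-02
=O,,,pA.1,0.0019,0.0065,1.52E-02
-Cl,,,...0,0.0006,0.0076,3.99E-04
-Cl,,,.A.1,0.0006,0.0046,1.26E-02
>C=,,,.A.1,0.0019,0.0065,1.52E-02
>C(<),,,...0,0.0709,0.0742,4.26E-02
-C(Ar)<,,,.a.1,0.0551,0.0574,4.95E-02
-C(Ar)<,,,.A.1,0.0861,0.0928,3.12E-02
-C(Ar)<,,,pA.1,0.0006,0.0046,1.26E-02
,1,,...0,0.0575,0.0663,5.00E-02
,2,,...0,0.0550,0.0647,4.64E-02
-C(Ar)<,-1,CycAr06,,0.0919,0.1006,3.98E-02
>C(<),1,,...0,0.0245,0.0310,2.83E-02
-C(Ar)<,-1,,...1,0.0616,0.0646,4.32E-02
=O,,-C(Ar)<,pA.1,0.0011,0.0085,8.11E-03
-Cl,,-C(Ar)<,.A.1,0.0011,0.0060,4.06E-02
>C=,,-C(Ar)<,.A.1,0.0011,0.0085,8.11E-03
-C(Ar)<,,CycAr06,...1,0.1002,0.1067,4.51E-02
-C(Ar)<,,CycAr06,.A.1,0.0011,0.0075,1.56E-02
-C(Ar)<,-1,CycAr06,...1,0.0875,0.0982,3.30E-02
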