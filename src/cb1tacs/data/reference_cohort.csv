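subject,age_y,sex,bmi,interval_d,dose_test_MBq,purity_test_pct,mass_test_ug,specact_test_MBq_nmol,dose_retest_MBq,purity_retest_pct,mass_retest_ug,specact_retest_MBq_nmol
1,28,M,23,24,365,98,4.2,39,364,98,6.2,27
2,44,M,28,23,375,96,3.0,56,376,99,4.3,40
3,42,M,25,122,356,96,2.3,70,373,100,2.3,72
4,26,M,24,1,361,98,3.4,48,366,98,2.7,61
5,31,M,24,19,353,98,4.2,38,355,99,2.7,60
6,27,F,21,309,367,99,4.6,37,363,97,1.7,99
7,32,F,36,37,351,100,3.2,50,316,100,8.3,17
8,65,F,22,23,355,97,2.3,69,371,96,4.0,42
9,27,M,22,67,369,98,3.9,43,366,98,3.1,54
10,29,F,23,4,360,97,9.7,17,364,100,5.8,29
11,57,M,30,30,373,97,2.9,60,399,96,5.0,37
12,61,F,36,93,361,96,1.8,92,349,96,1.6,97
13,63,F,29,12,384,97,3.5,50,380,98,3.3,52
14,25,F,31,156,364,97,2.4,69,357,100,4.4,37
15,62,F,24,10,362,97,1.4,122,366,97,3.3,51
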