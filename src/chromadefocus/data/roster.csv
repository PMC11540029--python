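subject,age_y,test_eye,cl_rx_D,baseline_al_mm,reference,csm,csh
1,19,OD,-3.75,24.41,1,1,1
2,23,OS,-1.75,24.64,1,1,1
3,19,OS,-1.25,25.21,1,1,1
4,20,OD,-4.75,25.90,1,1,1
5,24,OD,-4.50,26.00,1,1,1
6,25,OS,-3.75,26.05,1,1,1
7,20,OS,-5.50,26.24,1,1,1
8,24,OS,-2.00,26.44,1,1,1
9,24,OS,-2.25,23.85,1,1,0
10,20,OS,-2.50,24.34,1,1,0
11,24,OD,-2.50,25.01,1,1,0
12,18,OS,-2.50,25.16,1,1,0
13,21,OD,-4.25,25.37,1,1,0
14,22,OD,-4.00,25.50,1,1,0
15,25,OD,-5.00,25.63,1,1,0
16,26,OD,-1.75,23.45,1,0,1
17,24,OD,-2.75,24.05,1,0,1
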