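bmi,d_e_cm,conversion_factor
15,20.8,1.73
16,21.6,1.68
17,22.3,1.63
18,23.1,1.59
19,23.8,1.54
20,24.6,1.50
21,25.4,1.46
22,26.1,1.42
23,26.9,1.38
24,27.6,1.34
25,28.4,1.31
26,29.2,1.27
27,29.9,1.23
28,30.7,1.20
29,31.4,1.17
30,32.2,1.14
31,33.0,1.10
32,33.7,1.07
33,34.5,1.04
34,35.2,1.02
35,36.0,0.99
36,36.8,0.96
37,37.5,0.93
38,38.3,0.91
39,39.0,0.88
40,39.8,0.86
41,40.6,0.84
42,41.3,0.81
43,42.1,0.79
44,42.8,0.77
45,43.6,0.75
46,44.4,0.73
47,45.1,0.71
48,45.9,0.69
49,46.6,0.67
50,47.4,0.65
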