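ti,0.5,0.75,1,1.25,1.5,1.75,2,2.25,2.5
38,0,0,0,0,0,0,0,0,0
37,0,0,0.1,0.2,0.3,0.45,0.6,0.8,1
36,0,0.1,0.3,0.5,0.8,1.2,1.6,1.9,2.4
35,0,0.15,0.5,0.8,1.2,1.8,2.5,3,3.6
34,0,0.2,0.7,1.2,1.4,2,3,3.6,4.3
33,0,0.35,0.9,1.4,1.6,2.5,3.4,4,4.8
32,0,0.4,1,1.5,1.8,3,3.8,4.7,5.3
31,0,0.45,1.1,1.65,1.95,3.15,3.95,4.9,5.7
30,0,0.5,1.1,1.8,2.15,3.3,4.1,5.1,5.8
29,0,0.54,1.2,1.95,2.3,3.5,4.3,5.3,6
28,0,0.57,1.2,2.1,2.45,3.7,4.5,5.5,6.2
27,0,0.61,1.3,2.2,2.55,3.8,4.6,5.6,6.3
26,0,0.64,1.3,2.3,2.65,3.9,4.7,5.7,6.4
25,0,0.67,1.4,2.4,2.75,4,4.8,5.8,6.5
24,0,0.71,1.5,2.5,2.85,4.1,4.9,5.9,6.6
23,0,0.74,1.6,2.6,2.95,4.2,5,6,
22,0,0.76,1.7,2.7,3.05,4.3,5.1,,
21,0,0.78,1.8,2.75,3.1,4.4,,,
20,0,0.8,1.9,2.8,3.15,,,,
19,0,0.83,2,2.85,,,,,
18,0,0.85,2,,,,,,
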