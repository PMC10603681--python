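ti,5,10,15,20,25,inf
35,0.65,1.25,1.80,2.30,2.80,3.20
34,0.60,1.20,1.70,2.25,2.70,3.10
33,0.60,1.15,1.65,2.20,2.60,3.00
32,0.55,1.10,1.55,2.10,2.50,2.90
31,0.55,1.05,1.45,1.95,2.40,2.70
30,0.50,1.00,1.35,1.85,2.30,2.50
29,0.50,0.95,1.30,1.75,2.15,2.30
28,0.45,0.85,1.25,1.65,1.95,2.20
27,0.40,0.75,1.15,1.50,1.80,2.00
26,0.35,0.70,1.05,1.35,1.65,1.90
25,0.30,0.65,0.95,1.20,1.50,1.70
24,0.30,0.60,0.90,1.15,1.40,1.60
23,0.30,0.55,0.80,1.05,1.25,1.45
22,0.30,0.50,0.75,1.00,1.15,1.35
21,0.25,0.45,0.70,0.90,1.05,1.25
20,0.25,0.40,0.60,0.80,0.95,1.10
19,0.20,0.35,0.50,0.65,0.80,0.90
18,0.15,0.25,0.35,0.45,0.55,0.65
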