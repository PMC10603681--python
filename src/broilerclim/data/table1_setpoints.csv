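age_min,age_max,tmax,tmin,rh_min,rh_max
1,2,36,33,72,75
3,4,33,31,72,75
5,6,31,30,72,75
7,10,30,27,70,75
11,15,27,24,70,75
16,20,24,22,65,70
21,25,22,21,65,70
26,30,21,20,60,65
31,35,20,19,60,65
36,,18,18,60,65
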