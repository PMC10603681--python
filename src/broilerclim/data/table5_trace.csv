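time,ti,to,tih,RH,RHout,dp,SAF,NH3,CO2,CO,H2S
0,22,5,26,72,50,25,0.25,0,500,0,0
30,22,5,26,72,50,25,0.25,0,500,0,0
60,22,5,26,72,50,25,0.25,0,500,0,0
90,22,5,26,72,50,25,0.25,0,500,0,0
120,22,5,26,72,50,25,0.25,0,500,0,0
150,22,5,26,72,50,25,0.25,0,500,0,0
180,22,5,26,72,50,25,0.25,0,500,0,0
210,22,5,26,72,50,25,0.25,0,500,0,0
240,22,15,22,72,50,25,0.25,0,500,0,0
270,22,15,22,72,50,25,0.25,0,500,0,0
300,22,15,22,72,50,25,0.25,0,500,0,0
330,22,15,22,72,50,25,0.25,0,500,0,0
360,22,15,22,72,50,25,0.25,0,500,0,0
390,22,15,22,72,50,25,0.25,0,500,0,0
420,22,15,22,72,50,25,0.25,0,500,0,0
450,22,15,22,72,50,25,0.25,0,500,0,0
480,26,15,30,72,50,25,0.25,0,500,0,0
510,26,15,30,72,50,25,0.25,0,500,0,0
540,26,15,30,72,50,25,0.25,0,500,0,0
570,26,15,30,72,50,25,0.25,0,500,0,0
600,26,15,30,72,50,25,0.25,0,500,0,0
630,26,15,30,72,50,25,0.25,0,500,0,0
660,26,15,30,72,50,25,0.25,0,500,0,0
690,26,15,30,72,50,25,0.25,0,500,0,0
720,26,15,30,72,50,25,0.25,0,500,0,0
750,26,15,30,72,50,25,0.25,0,500,0,0
780,26,15,30,72,50,25,0.25,0,500,0,0
810,26,15,30,72,50,25,0.25,0,500,0,0
840,25,15,30,72,50,25,0.25,0,500,0,0
870,25,15,30,72,50,25,0.25,0,500,0,0
900,25,15,30,72,50,25,0.25,0,500,0,0
930,25,15,30,72,50,25,0.25,0,500,0,0
960,25,15,30,72,50,25,0.25,0,500,0,0
990,25,15,30,72,50,25,0.25,0,500,0,0
1020,25,15,30,72,50,25,0.25,0,500,0,0
1050,25,15,30,72,50,25,0.25,0,500,0,0
1080,25,15,30,72,50,25,0.25,0,500,0,0
1110,25,15,30,72,50,25,0.25,0,500,0,0
1140,25,15,25,72,50,25,0.25,0,2500,0,0
1170,25,15,25,72,50,25,0.25,0,2500,0,0
1200,25,15,25,72,50,25,0.25,0,2500,0,0
1230,25,15,25,72,50,25,0.25,0,2500,0,0
1260,25,15,25,72,50,25,0.25,0,2500,0,0
1290,25,15,25,72,50,25,0.25,0,2500,0,0
1320,25,15,25,72,50,25,0.25,0,2500,0,0
1350,25,15,25,72,50,25,0.25,0,2500,0,0
1380,25,15,25,72,50,25,0.25,0,2500,0,0
1410,25,15,25,72,50,25,0.25,0,2500,0,0
1440,24.5,15,25,72,50,25,0.25,0,3500,0,0
1470,24.5,15,25,72,50,25,0.25,0,3500,0,0
1500,24.5,15,25,72,50,25,0.25,0,3500,0,0
1530,24.5,15,25,72,50,25,0.25,0,3500,0,0
1560,24.5,15,25,72,50,25,0.25,0,3500,0,0
1590,24.5,15,25,72,50,25,0.25,0,3500,0,0
1620,25,15,25,72,50,25,0.25,0,500,0,0
1650,25,15,25,72,50,25,0.25,0,500,0,0
1680,25,15,25,72,50,25,0.25,0,500,0,0
1710,25,15,25,72,50,25,0.25,0,500,0,0
1740,25,15,25,72,50,25,0.25,0,500,0,0
1770,25,15,25,72,50,25,0.25,0,500,0,0
1800,25,15,25,72,50,25,0.25,0,500,0,0
1830,25,15,25,72,50,25,0.25,0,500,0,0
1860,25,15,25,72,50,25,0.25,0,500,0,0
1890,25,15,25,72,50,25,0.25,0,500,0,0
1920,25,15,25,72,50,25,0.25,0,500,0,0
1950,25,15,25,72,50,25,0.25,0,500,0,0
1980,25,15,25,72,50,25,0.25,0,500,0,0
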