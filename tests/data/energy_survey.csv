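DOEID,WASHER,NUMCOOK,FUEL,METRO,REGION,MONEYPY,TYPEHUQ,NRA,NRC,NWEIGHT
E000000,1,1,2,NONE,1,162532.03,02,3,0,74.85
E000001,1,2,2,NONE,1,35543.63,02,1,0,53.44
E000002,1,2,2,MICRO,2,46976.91,01,3,0,49.4
E000003,0,1,5,METRO,3,22739.26,02,3,1,48.94
E000004,1,1,1,NONE,4,56289.52,06,3,3,20.98
E000005,1,1,1,METRO,4,91542.24,06,1,0,72.85
E000006,0,1,1,MICRO,3,26104.73,01,2,0,31.65
E000007,0,1,2,METRO,4,50827.71,04,2,0,55.55
E000008,1,1,2,METRO,1,37547.05,01,2,0,134.97
E000009,1,1,2,NONE,3,66292.74,04,2,0,29.5
E000010,0,1,1,METRO,1,38256.23,04,1,0,104.8
E000011,1,1,1,METRO,4,58805.18,03,2,0,68.52
E000012,1,1,1,METRO,4,48335.62,01,3,0,77.22
E000013,1,1,1,NONE,4,50880.25,01,3,0,116.05
E000014,1,1,2,NONE,2,37546.52,02,3,0,78.34
E000015,1,1,1,METRO,1,121480.45,01,1,1,121.17
E000016,1,2,2,METRO,1,94366.08,03,2,0,108.73
E000017,1,1,2,METRO,4,102600.09,01,3,0,42.62
E000018,1,1,5,METRO,4,155597.71,01,2,0,77.83
E000019,1,1,2,NONE,1,41475.37,02,2,0,87.85
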