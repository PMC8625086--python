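CONTROL,ROOMS,BEDRMS,BATHS,UNITSF,BLD,METRO,REGION,HINCP,TEN,VAC,CEILFAN,WINDOWS,POOL,VEH,HICEIL,NRA,NRC,WEIGHT
A000000,3,2,1,1095.1,04,1,1,76830.19,1,0,2,10,2,1,1,2,0,33.87
A000001,4,1,2,1458.2,02,1,4,23065.43,1,0,1,9,2,1,2,2,3,54.05
A000002,8,4,2,3727.2,01,2,2,180742.6,2,0,2,9,2,1,2,3,3,70.1
A000003,7,3,2,5077.4,03,1,2,83117.12,1,0,2,6,2,2,2,3,0,20.11
A000004,6,4,2,1609.8,03,1,1,43377.95,1,0,0,10,2,1,2,3,1,31.46
A000005,1,0,1,545.3,01,1,1,18151.1,2,0,3,12,2,1,1,3,3,42.49
A000006,6,3,2,2488.1,02,2,2,104356.62,1,0,1,13,2,1,2,1,1,62.31
A000007,5,2,2,655.7,02,3,1,31542.48,1,0,2,13,2,2,2,2,1,39.25
A000008,4,2,2,396.1,02,2,4,26665.92,2,0,4,10,2,1,2,3,1,114.7
A000009,6,2,3,1840.9,01,1,2,27947.81,2,0,2,14,2,1,2,1,0,47.56
A000010,8,3,3,3638.6,02,3,4,240164.9,1,0,1,14,2,1,1,2,2,26.24
A000011,9,4,3,3166.1,02,3,3,73385.81,1,0,0,14,2,2,2,3,3,70.91
A000012,5,2,2,1536.7,02,3,4,31578.25,1,0,0,9,2,1,2,2,1,44.23
A000013,1,0,1,937.2,01,2,3,13792.46,1,0,1,8,1,1,2,3,3,77.43
A000014,4,2,2,1271.1,02,2,1,46376.03,1,0,3,5,2,1,2,3,2,47.77
A000015,7,3,2,1910.5,02,3,3,83750.66,1,0,2,8,2,1,2,2,0,58.44
A000016,8,4,2,1872.4,02,2,2,84206.03,1,0,3,12,2,1,1,3,1,74.09
A000017,3,1,2,535.9,03,2,3,12679.91,1,0,1,8,2,1,1,1,0,39.6
A000018,9,4,3,2111.6,02,2,3,57293.83,2,0,2,11,2,1,2,2,0,59.58
A000019,9,4,2,1960.5,02,3,3,90103.38,1,0,3,8,2,1,2,1,0,38.35
A000020,2,2,3,869.7,04,3,4,41098.9,1,1,1,10,2,1,2,1,2,36.15
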