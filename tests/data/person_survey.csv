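PID,HHID,AGEP,SEX,RAC1P,HISP,ST,PUMA,DENSITY,HINCP,NRA,NRC,BLD,PWGTP
P0000000,H000000,70,1,1,2,06,0600114,766.8,104129.96,3,3,04,192.18
P0000001,H000000,85,2,2,1,06,0600114,766.8,104129.96,3,3,04,66.81
P0000002,H000000,91,1,1,1,06,0600114,766.8,104129.96,3,3,04,95.62
P0000003,H000000,17,2,1,1,06,0600114,766.8,104129.96,3,3,04,60.67
P0000004,H000000,1,1,1,1,06,0600114,766.8,104129.96,3,3,04,123.16
P0000005,H000000,15,2,1,1,06,0600114,766.8,104129.96,3,3,04,68.64
P0000006,H000001,59,2,1,1,39,3900102,32.5,39821.59,1,2,01,138.19
P0000007,H000001,12,1,6,1,39,3900102,32.5,39821.59,1,2,01,153.34
P0000008,H000001,17,1,1,1,39,3900102,32.5,39821.59,1,2,01,167.32
P0000009,H000002,89,1,1,1,17,1700108,117.1,50933.56,1,0,04,50.64
P0000010,H000003,70,1,1,1,13,1300110,993.9,191983.29,3,0,03,48.77
P0000011,H000003,20,2,1,1,13,1300110,993.9,191983.29,3,0,03,154.72
P0000012,H000003,32,1,1,1,13,1300110,993.9,191983.29,3,0,03,186.86
P0000013,H000004,70,2,1,1,39,3900106,25.4,28372.16,3,1,02,87.69
P0000014,H000004,29,1,3,1,39,3900106,25.4,28372.16,3,1,02,40.54
P0000015,H000004,89,1,1,1,39,3900106,25.4,28372.16,3,1,02,54.65
P0000016,H000004,16,1,2,1,39,3900106,25.4,28372.16,3,1,02,170.41
P0000017,H000005,55,2,1,1,06,0600111,52.7,71657.81,2,2,06,110.79
P0000018,H000005,95,1,1,2,06,0600111,52.7,71657.81,2,2,06,188.96
P0000019,H000005,6,2,2,1,06,0600111,52.7,71657.81,2,2,06,48.11
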