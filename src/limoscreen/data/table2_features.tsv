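metabolite_id	label	rt	mz	error_ppm	anion_formula	hl01_pct	hl08_pct	tissue	msms
M1	limonene+COOH+OH+OH glucuronide	1.89	375.1304	-1.8	C16H23O10	23.00	12.13	U	375.1333 (20); 357.1104 (5); 183.1088 (5); 172.9903 (100); 160.0421 (15); 113.0224 (40); 93.0353 (85); 85.0291 (45); 75.0086 (65); 59.0141 (75)
M2	limonene+COOH+OH+OH+H2 glucuronide	2.01	377.1460	-1.9	C16H25O10	0.27	0.44	U	377.1469 (100); 204.0368 (10); 201.1180 (5); 178.0497 (20); 175.0236 (5); 172.9923 (60); 160.0399 (33); 113.0251 (30); 93.0344 (55); 85.0293 (35); 75.0087 (60); 71.0145 (70); 59.0147 (70)
M3	limonene+COOH+OH+H2+H2 glucuronide	2.83	361.1504	-0.1	C16H25O9	4.37	5.18	U	361.1500 (85); 301.1299 (5); 185.1181 (10); 175.0256 (3); 157.0128 (5); 113.0239 (60); 85.0294 (65); 71.0138 (90); 59.0141 (100)
M4-I	limonene+COOH+OH+H2 glucuronide	2.95	359.1344	1.0	C16H23O9	0.54	0.64	U	359.1347 (35); 297.1331 (5); 241.1095 (5); 183.1047 (15); 175.0242 (5); 113.0241 (45); 99.0084 (15); 85.0290 (60); 75.0088 (100); 71.0131 (80); 59.0143 (95); 44.9989 (20)
M4-II	limonene+COOH+OH+H2 glucuronide	3.18	359.1345	0.8	C16H23O9	0.68	0.66	U	359.1332 (10); 315.1646 (5); 183.1020 (65); 175.0240 (5); 155.1070 (25); 137.0971 (10); 113.0249 (30); 99.0097 (10); 85.0294 (40); 71.0137 (45); 59.0137 (100); 44.9985 (20)
M5-I	limonene+COOH+OH+H2 glycine	3.41	240.1224	7.2	C12H18NO4	0.68	1.38	U	240.1228 (5); 178.1213 (1); 111.0801 (5); 74.0242 (100); 72.0453 (20); 56.0152 (2)
M4-III	limonene+COOH+OH+H2 glucuronide	3.57	359.1326	6.0	C16H23O9	0.50	2.02	U	183.1015 (100); 175.0243 (5); 137.0965 (30); 113.0233 (45); 99.0080 (15); 85.0292 (35); 71.0137 (30); 59.0138 (80); 44.9983 (30)
M6	limonene+COOH sulfate	3.62	245.0490	-0.3	C10H13O5S	0.85	0.25	U	245.0517 (20); 165.0919 (10); 79.9569 (20); 74.0241 (20); 59.0151 (45)
M5-II	limonene+COOH+OH+H2 glycine	3.62	240.1229	5.3	C12H18NO4	0.30	0.56	U	240.1229 (5); 178.1244 (1); 111.0793 (5); 74.0244 (100); 72.0446 (20); 56.0148 (2)
M7-I	limonene+OH+OH glucuronide	3.71	345.1550	1.4	C16H25O8	0.09	0.26	U	345.1546 (50); 327.1414 (5); 285.1317 (5); 269.1388 (5); 193.0382 (5); 175.0227 (5); 169.1228 (5); 157.0139 (10); 113.0236 (60); 99.0082 (10); 85.0291 (70); 75.0084 (100); 59.0138 (60)
M7-II	limonene+OH+OH glucuronide	3.80	345.1548	2.1	C16H25O8	26.15	24.36	U,L	345.1537 (50); 327.1414 (5); 285.1324 (5); 269.1388 (5); 193.0382 (5); 175.0227 (5); 169.1207 (5); 157.0133 (10); 113.0237 (60); 99.0082 (10); 85.0291 (70); 75.0084 (100); 59.0141 (60)
M8	limonene+COOH+OH+H2 taurine	3.92	290.1054	4.6	C12H20NO5S	0.00	0.09	U	290.2051 (45); 152.0006 (10); 124.0063 (30); 106.9814 (10); 79.9570 (100); 74.0242 (85)
M7-III	limonene+OH+OH glucuronide	4.13	345.1538	5.0	C16H25O8	0.95	1.94	U	n.d.
M9-I	limonene+OH glucuronide	4.36	327.1437	4.1	C16H23O7	3.71	7.44	U	327.1439 (20); 309.1323 (5); 209.1191 (5); 175.0247 (3); 157.0141 (5); 151.1132 (2); 113.0233 (30); 85.0290 (60); 75.0085 (100); 59.0139 (80)
M10	limonene+COOH glucuronide	4.49	341.1243	-0.3	C16H21O8	0.08	0.42	U	261.0763 (10); 175.0230 (3); 165.0923 (45); 113.0241 (35); 99.0081 (20); 85.0295 (55); 71.0141 (40); 59.0142 (100); 44.9993 (25)
M9-II	limonene+OH glucuronide	4.51	327.1435	4.1	C16H23O7	5.84	9.73	U,L	327.1424 (15); 209.1177 (5); 175.0237 (1); 157.0123 (5); 151.1120 (1); 113.0235 (30); 85.0287 (10); 75.0083 (100); 57.0348 (45); 44.9985 (20)
M11	limonene+COOH+H2 taurine	4.55	274.1101	6.2	C12H20NO4S	1.10	1.10	U	274.1092 (60); 206.0483 (5); 124.0062 (5); 106.9791 (10); 79.9570 (100); 72.0445 (5)
M12	limonene+COOH glycine	4.63	222.1134	0.8	C12H16NO3	20.04	14.26	U	222.1120 (25); 178.1218 (75); 176.1078 (80); 121.1019 (25); 119.0852 (45); 110.0612 (35); 108.0453 (20); 74.0246 (100); 56.0143 (15)
M13	limonene+COOH taurine	4.66	272.0949	5	C12H18NO4S	0.38	1.47	U	272.0949 (35); 204.0322 (25); 164.1039 (3); 124.0070 (5); 106.9803 (10); 79.9567 (100)
M9-III	limonene+OH glucuronide	4.71	327.1433	4.1	C16H23O7	2.69	2.98	U	327.1429 (15); 309.1361 (3); 209.1166 (5); 151.1120 (15); 113.0235 (10); 85.0289 (50); 83.0498 (65); 75.0083 (100); 57.0348 (35); 44.9984 (10)
M14	limonene+COOH+H2 glucuronide	4.71	343.1389	1.3	C16H23O8	3.97	6.20	U,L	175.0235 (3); 167.1069 (75); 113.0238 (40); 99.0081 (20); 85.0288 (50); 71.0133 (35); 59.0139 (100)
M15	limonene+COOH+H2 glycine	4.71	224.1277	6.7	C12H18NO3	3.30	5.77	U	224.1287 (5); 180.1399 (5); 178.1203 (10); 54.0479 (5); 74.0247 (100); 56.0151 (5)
M16	limonene+OH+H2 glucuronide	4.90	329.1585	5.6	C16H25O7	0.47	0.73	U	329.1575 (15); 269.1356 (5); 211.1321 (5); 153.1355 (3); 113.0245 (20); 85.0264 (65); 75.0080 (100); 55.0186 (35)
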