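compound	systematic_name	rt	relative_area_pct	fragments
alpha-pinene	pin-2,3-ene	9.12	0.57	136 (8); 121 (13); 105 (11); 93 (100); 92 (38); 91 (41); 79 (24); 77 (29); 67 (9); 53 (7)
beta-phellandrene	p-menthane-2,7-diene	10.43	0.75	136 (13); 121 (5); 105 (3); 93 (100); 92 (10); 91 (40); 79 (27); 77 (35); 69 (9); 53 (7)
beta-pinene	pin-2,10-ene	11.07	1.52	136 (4); 121 (5); 107 (3); 93 (100); 92 (12); 91 (22); 79 (18); 77 (16); 69 (73); 53 (12)
octanal	octanal	11.42	0.23	136 (4); 100 (16); 93 (22); 84 (72); 69 (51); 68 (38); 67 (29); 57 (100); 56 (89); 55 (78)
delta-3-carene	car-3,4-ene	11.56	0.14	136 (18); 121 (19); 105 (14); 93 (100); 92 (24); 91 (42); 80 (24); 79 (34); 77 (38); 67 (11)
m-cymene	m-menthane-1,3,5-triene	12.03	0.01	134 (22); 119 (100); 117 (16); 115 (8); 103 (2); 91 (24); 77 (11); 65 (8); 51 (6); 56 (6)
limonene	p-mentha-1,8-diene	12.26	96.45	136 (21); 121 (24); 107 (23); 93 (73); 92 (24); 91 (22); 79 (36); 67 (76); 68 (100); 53 (23)
gamma-terpinene	p-menthane-1,4-diene	13.04	0.07	136 (36); 121 (30); 119 (14); 105 (11); 93 (100); 92 (26); 91 (55); 79 (27); 77 (36); 53 (9)
linalool	3,7-dimethylocta-1,6-dien-3-ol	14.21	0.27	154 (6); 136 (8); 121 (22); 105 (7); 93 (78); 83 (17); 80 (32); 71 (100); 69 (44); 55 (58)
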