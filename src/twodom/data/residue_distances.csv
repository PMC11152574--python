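residue,dist_operator_A,dist_ligand_A
26,7.3,24.7
32,12.6,30.4
42,8.1,25.0
44,9.4,21.6
47,7.7,21.9
49,11.4,17.8
53,17.0,12.1
57,22.5,7.0
76,45.7,17.9
98,19.9,15.6
102,18.1,14.2
105,24.8,7.7
132,39.3,16.0
143,29.4,16.9
146,25.8,17.6
147,26.8,16.0
150,23.2,19.0
174,34.5,14.9
176,38.8,19.5
177,35.5,17.5
203,55.1,28.7
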