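marker,CFSC-2G,HSC-T6,PAV-1,Rat-1
73,"194, 203",194,194,"211, 213"
8,236,234,"234, 238","232, 236"
2,126,127,128,129
4,"268, 270",238,"236, 238","250, 252"
3,"160, 182","160, 162",162,"178, 182"
26,150,166,154,162
19,180,175,179,"176, 178"
81,"130, 134","130, 132",130,128
34,"184, 189",188,"182, 187","184, 189"
30,"188, 192","186, 192",192,186
24,260,"249, 253","254, 259","247, 249"
59,145,"143, 146, 180","145, 148","176, 178"
62,166,177,166,154
1,105,96,"96, 105",96
55,"210, 214","210, 218","210, 218","203, 205"
36,222,234,222,228
67,"154, 156",165,165,"165, 167"
13,121,"121, 135",121,121
35,197,"197, 203",203,203
42,125,127,"144, 156","154, 156"
70,"158, 175","175, 179","158, 175",158
61,128,128,128,110
79,"172, 180",172,172,172
90,"159, 161",174,175,"159, 161"
69,138,139,"136, 139",148
78,"136, 151","147, 151","147, 149","136, 140"
15,232,232,232,238
16,"251, 260","247, 251",251,"247, 251"
75,144,"144, 184","144, 184",144
96,210,"210, 212",210,"208, 210"
91,221,"205, 211","211, 225","219, 221"
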