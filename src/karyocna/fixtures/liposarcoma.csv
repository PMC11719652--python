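region,status
1p31.3q23.1,no CNA
1q24.13q24.3,gain
2pterp16.3,no CNA
2p13.3p11.2,no CNA
2q24.3q32.1,loss and gain
3p26.3p25.2,no CNA
3p24.1q24,no CNA
3p22.2p21.31,no CNA
3q24q25.1,no CNA
3q26.2q26.33,no CNA
3p14.1p12.3,no CNA
4q22.3q26,no CNA
4q28.1q32.2,no CNA
5p15.31p14.1,gain
5p13.3p13.2,gain
6q13q14.3,loss
7pterp22.1,gain
7p22.1p21.3,no CNA
7p21.2p15.3,no CNA
7p15.3p14.2,no CNA
7q11.21q11.23,no CNA
7q11.23q21.2,no CNA
7q21.2q22.1,no CNA
7q22.3q31.1,no CNA
7q31.1q36.1,no CNA
8q12.3q13.1,gain
8q21.11q24.3,gain
10p11.22p11.21,no CNA
11p14.2q12.1,no CNA
11q14.3qter,loss
12p13.33p11.21,no CNA
12q12q23.3,gain
13q12.13q13.2,loss and gain
14q12q32.33,gain
15q14q24.3,loss
16q11.2qter,loss
17q21.31qter,gain
19p13.2p13.12,gain
20p13qter,gain
22q12.3q13.33,loss
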