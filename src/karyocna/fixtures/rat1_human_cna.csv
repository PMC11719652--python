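region,delta
1p31.3q23.1,-1
1q24.13q24.3,+1
2pterp16.3,+1
2p13.3p11.2,-1
2q24.3q32.1,-1
3p26.3p25.2,-1
3p24.1q24,-1
3p22.2p21.31,-1
3q24q25.1,+1
3q26.2q26.33,+1
3p14.1p12.3,-1
4q22.3q26,-1
4q28.1q32.2,-1
5p15.31p14.1,+1
5p13.3p13.2,+1
6q13q14.3,-1
7pterp22.1,+1
7p22.1p21.3,-1
7p21.2p15.3,+1
7p15.3p14.2,-1
7q11.21q11.23,+1
7q11.23q21.2,-1
7q21.2q22.1,+1
7q22.3q31.1,+1
7q31.1q36.1,-1
8q12.3q13.1,+1
8q21.11q24.3,+1
10p11.22p11.21,+1
11p14.2q12.1,-1
11q14.3qter,-1
12p13.33p11.21,-1
12q12q23.3,+1
13q12.13q13.2,+1
14q12q32.33,+1
15q14q24.3,-1
16q11.2qter,+1
17q21.31qter,+1
19p13.2p13.12,+1
20p13qter,-1
22q12.3q13.33,+1
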