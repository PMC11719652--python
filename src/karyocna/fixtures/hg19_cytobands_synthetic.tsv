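chr5	0	5000000	p15.33	gneg
chr5	5000000	8000000	p15.32	gpos50
chr5	8000000	12000000	p15.31	gneg
chr5	12000000	15000000	p15.2	gpos50
chr5	15000000	18000000	p15.1	gneg
chr5	18000000	22000000	p14.3	gpos50
chr5	22000000	25000000	p14.2	gneg
chr5	25000000	28000000	p14.1	gpos50
chr5	28000000	35000000	p13	gneg
chr5	35000000	42000000	p12	gpos50
chr5	42000000	46000000	p11	gneg
chr5	46000000	60000000	q11	gpos50
chr5	60000000	180915260	q21	gneg
chr16	0	35000000	p11	gneg
chr16	35000000	40000000	q11	gpos50
chr16	40000000	46000000	q12.1	gneg
chr16	46000000	52000000	q12.2	gpos50
chr16	52000000	60000000	q21	gneg
chr16	60000000	66000000	q22.1	gpos50
chr16	66000000	72000000	q22.2	gneg
chr16	72000000	90354753	q23	gpos50
chr17	0	22000000	p11	gneg
chr17	22000000	30000000	q11	gpos50
chr17	30000000	40000000	q21.2	gneg
chr17	40000000	48000000	q21.31	gpos50
chr17	48000000	55000000	q21.32	gneg
chr17	55000000	62988804	q25	gpos50
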