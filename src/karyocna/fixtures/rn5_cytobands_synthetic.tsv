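chr1	0	20000000	p11	gneg
chr1	20000000	60000000	q11	gpos50
chr1	60000000	120000000	q12	gneg
chr1	120000000	180000000	q21	gpos50
chr1	180000000	240000000	q22	gneg
chr1	240000000	290094216	q23	gpos50
chr2	0	25000000	p11	gneg
chr2	25000000	45000000	q11	gpos50
chr2	45000000	80406982	q21	gneg
chr2	80406982	100000000	q22	gpos50
chr2	100000000	115000000	q23	gneg
chr2	115000000	130000000	q24	gpos50
chr2	130000000	139816749	q25	gneg
chr2	139816749	165000000	q31	gpos50
chr2	165000000	180000000	q32	gneg
chr2	180000000	192680325	q33	gpos50
chr2	192680325	210000000	q34	gneg
chr2	210000000	240000000	q35	gpos50
chr2	240000000	285068071	q36	gneg
chr3	0	20000000	q11	gneg
chr3	20000000	45000000	q21	gpos50
chr3	45000000	58164791	q22	gneg
chr3	58164791	90000000	q23	gpos50
chr3	90000000	120000000	q24	gneg
chr3	120000000	150000000	q31	gpos50
chr3	150000000	183740530	q32	gneg
chr4	0	5000000	p11	gneg
chr4	5000000	40000000	q11	gpos50
chr4	40000000	80000000	q12	gneg
chr4	80000000	120000000	q21	gpos50
chr4	120000000	160000000	q22	gneg
chr4	160000000	200000000	q31	gpos50
chr4	200000000	248343840	q32	gneg
chr5	0	10000000	p11	gneg
chr5	10000000	60000000	q11	gpos50
chr5	60000000	120000000	q21	gneg
chr5	120000000	177180328	q22	gpos50
chr6	0	15000000	q11	gneg
chr6	15000000	50000000	q12	gpos50
chr6	50000000	90000000	q21	gneg
chr6	90000000	120000000	q22	gpos50
chr6	120000000	156897508	q31	gneg
chr7	0	8000000	p11	gneg
chr7	8000000	40000000	q11	gpos50
chr7	40000000	80000000	q21	gneg
chr7	80000000	110000000	q22	gpos50
chr7	110000000	143501887	q31	gneg
chr8	0	7000000	p11	gneg
chr8	7000000	40000000	q11	gpos50
chr8	40000000	80000000	q21	gneg
chr8	80000000	110000000	q22	gpos50
chr8	110000000	132457389	q31	gneg
chr9	0	15000000	q11	gneg
chr9	15000000	60000000	q21	gpos50
chr9	60000000	90000000	q22	gneg
chr9	90000000	121549591	q31	gpos50
chr10	0	6000000	p11	gneg
chr10	6000000	30000000	q11	gpos50
chr10	30000000	55000000	q21	gneg
chr10	55000000	75000000	q22	gpos50
chr10	75000000	89211696	q31	gneg
chr10	89211696	95000000	q32.1	gpos50
chr10	95000000	103000000	q32.2	gneg
chr10	103000000	112200500	q32.3	gpos50
chr11	0	12000000	q11	gneg
chr11	12000000	45000000	q21	gpos50
chr11	45000000	70000000	q22	gneg
chr11	70000000	90463843	q31	gpos50
chr12	0	5000000	p11	gneg
chr12	5000000	15000000	q11	gpos50
chr12	15000000	31247709	q12	gneg
chr12	31247709	46782294	q13	gpos50
chr13	0	15000000	q11	gneg
chr13	15000000	50000000	q21	gpos50
chr13	50000000	80000000	q22	gneg
chr13	80000000	114033958	q31	gpos50
chr14	0	15000000	q11	gneg
chr14	15000000	50000000	q21	gpos50
chr14	50000000	85000000	q22	gneg
chr14	85000000	115493446	q31	gpos50
chr15	0	14000000	q11	gneg
chr15	14000000	50000000	q21	gpos50
chr15	50000000	80000000	q22	gneg
chr15	80000000	111246239	q31	gpos50
chr16	0	8000000	p11	gneg
chr16	8000000	35000000	q11	gpos50
chr16	35000000	65000000	q21	gneg
chr16	65000000	90668790	q22	gpos50
chr17	0	9000000	p11	gneg
chr17	9000000	35000000	q11	gpos50
chr17	35000000	65000000	q21	gneg
chr17	65000000	90843779	q22	gpos50
chr18	0	8000000	p11	gneg
chr18	8000000	35000000	q11	gpos50
chr18	35000000	60000000	q21	gneg
chr18	60000000	88201929	q22	gpos50
chr19	0	10000000	p13	gneg
chr19	10000000	20000000	p12	gpos50
chr19	20000000	27543415	p11	gneg
chr19	27543415	35000000	q11	gpos50
chr19	35000000	50000000	q12	gneg
chr19	50000000	72914587	q13	gpos50
chr20	0	5000000	p11	gneg
chr20	5000000	20000000	q11	gpos50
chr20	20000000	40000000	q21	gneg
chr20	40000000	56205956	q22	gpos50
chrX	0	12000000	p11	gneg
chrX	12000000	50000000	q11	gpos50
chrX	50000000	100000000	q21	gneg
chrX	100000000	159970021	q22	gpos50
chrY	0	1000000	p11	gneg
chrY	1000000	3310458	q11	gpos50
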