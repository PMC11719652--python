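srcChrom	srcStart	srcEnd	tgtChrom	tgtStart	tgtEnd	strand
2	80406982	100406982	5	8000000	28000000	-
19	0	20000000	16	46000000	66000000	+
10	89211696	112200500	17	40000000	62988804	+
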