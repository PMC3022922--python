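family	group	arabidopsis	vitis	poplar	rice
ERF	I	10	5	5	9
ERF	II	15	8	20	16
ERF	III	23	22	35	27
ERF	IV	9	5	6	6
ERF	V	5	11	10	8
ERF	VI	8	5	11	6
ERF	VII	5	3	6	15
ERF	VIII	15	11	17	15
ERF	IX	17	40	42	18
ERF	X	8	10	9	12
ERF	VI-L	4	2	4	3
ERF	Xb-L	3	0	4	10
RAV		6	6	6	5
AP2		18	20	26	29
Soloist		1	1	1	1
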