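structure	1	2	3	4	5	6	7	8	9	10	11	12	13	14
2ayh	F92	Y94	W103	d104	E105	D107	E109	L111	Q119	N121	Y123	Y147	W158	W184
3h3l	F125	-	Y138	-	s140	E142	q144	L146	A166	Y168	-	t187	H198	H256
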