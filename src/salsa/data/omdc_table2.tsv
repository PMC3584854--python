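structure	1	2	3	4	5	6	7	8
#annotation	β1	β2	β3		β4		β7	β8
1dbt	D11	K33	D60	K62	D65	H88	P182	R215
1dvj	D20	K42	D70	K72	D75	H98	P180	R203
1dqw	D37	K59	D91	K93	D96	H122	P202	R235
1l2u	D22	K44	D71	K73	D76	H99	P189	R222
2za1	D23	K102	D136	K138	D141	n165	P264	R294
2aqw	D23	K105	D139	K141	D144	n168	P267	R297
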