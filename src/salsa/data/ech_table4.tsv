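structure	1	2	3	4	5	6	7	8	9
1ey3	A98	g141	E144	C149	D150	E164	R178	k241	N245
3q1t	G76	A123	V126	a131	D132	H146	C160	k223	n227
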