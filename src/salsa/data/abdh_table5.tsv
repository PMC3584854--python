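structure	1	2	3	4	5	6	7
3q1t	D155	H146	E244	D144	H44	C160	H156
2j5s	D153	H144	E243	D141	H43	l158	g154
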