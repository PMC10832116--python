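# name=synthetic-positional context_length=30 link=identity-clamped intercept=0.5
position	pattern	weight
24	G	0.1
24	C	-0.1
24	T	-0.05
23	G	0.05
23	T	-0.05
22	T	-0.04
5	G	0.03
5	A	0.02
28	G	-0.05
4	C	0.02
20	A	0.03
20	T	-0.03
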