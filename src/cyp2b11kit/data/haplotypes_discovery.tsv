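label	#1	#2	#3	#4	#5	#6	#7	#8	#9	greyhound_count	other_breeds_count
H1	G	A	TCA	C	TG	G	A	T	G	8	56
H2	A	G	TCCA	C	CA	A	G	T	C	13	16
H3	G	A	TCA	T	TG	G	A	T	G	5	3
H4	G	G	TCA	C	TG	G	A	G	G	0	7
H5	A	G	TCA	C	TG	G	A	G	G	0	6
H6	G	G	TCCA	C	TG	G	A	T	G	0	2
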