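population	n_dogs	H1/H1	H1/H2	H2/H2	H1/H3	H2/H3	H3/H3
Beagle	50	30	15	5	0	0	0
Mixed-breed	153	95	44	9	3	2	0
Greyhound (NGA)	180	56	54	12	39	14	5
Greyhound (AKC)	61	14	0	0	22	0	25
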