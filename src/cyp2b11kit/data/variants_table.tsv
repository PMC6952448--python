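id	genomic_pos	cdna_pos	ref_allele	var_allele	region	dbsnp_id
#1	112817078	-489	G	A	enhancer	.
#2	112828499	966	G	A	exon_7	rs21894687
#3	112832580	1913	TCA	TCCA	utr3	rs852076551
#4	112832619	1952	C	T	utr3	.
#5	112832805	2137	TG	CA	utr3	.
#6	112832834	2166	G	A	utr3	.
#7	112832951	2283	A	G	utr3	.
#8	112833166	2498	G	T	utr3	rs850924485
#9	112833204	2536	G	C	utr3	.
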