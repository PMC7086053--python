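##fileformat=VCFv4.2
##INFO=<ID=FRAG,Number=1,Type=String,Description="GBS fragment ID">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=frag1>
##contig=<ID=frag2>
##contig=<ID=frag3>
##contig=<ID=frag4>
##contig=<ID=frag5>
##contig=<ID=frag6>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	s1	s2	s3	s4	s5	s6	s7	s8	s9	s10
frag1	10	snpA	A	T	.	PASS	FRAG=frag1	GT	0/0	0/1	1/1	0/0	0/1	0/0	0/1	0/0	0/0	0/1
frag2	12	snpB	C	G	.	PASS	FRAG=frag2	GT	1/1	1/1	0/1	0/1	0/0	0/0	1/1	0/1	0/0	0/1
frag3	8	snpC	A	T,G	.	PASS	FRAG=frag3	GT	0/1	1/2	0/0	0/2	1/1	0/0	0/1	0/0	0/2	1/1
frag4	30	snpD	G	A	.	PASS	FRAG=frag4	GT	0/1	0/1	0/1	0/1	0/1	0/1	0/1	0/1	0/0	1/1
frag5	5	snpE	T	C	.	PASS	FRAG=frag5	GT	./.	./.	./.	./.	./.	./.	0/0	0/1	1/1	0/1
frag6	22	snpF	A	C	.	PASS	FRAG=frag6	GT	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0
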