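##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Forward-strand allele depths">
##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Reverse-strand allele depths">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	PARENT	BULK1	BULK2
chr1	1000	.	A	G	100	PASS	MQ=60	GT:AD	0/0:20,0	1/1:0,18	0/1:12,8
chr1	2000	.	C	T	100	PASS	MQ=60	GT:AD	./.:0,0	1/1:0,20	0/1:10,10
chr1	3000	.	G	A	100	PASS	MQ=60	GT:AD	0/1:10,10	0/1:10,10	0/1:10,10
chr1	4000	.	A	G,T	100	PASS	MQ=60	GT:AD	0/0:20,0,0	1/1:0,18,0	0/1:10,8,0
chr1	5000	.	A	AT	100	PASS	MQ=60	GT:AD	0/0:20,0	0/1:10,10	0/1:8,12
chr1	6000	.	T	C	100	PASS	MQ=20	GT:AD	0/0:20,0	1/1:0,300	0/1:10,10
chr1	7000	.	C	G	100	PASS	MQ=60	GT:AD:ADF:ADR	0/0:20,0:10,0:10,0	1/1:0,20:0,20:0,0	1/1:0,20:0,20:0,0
chr1	8000	.	G	T	100	PASS	MQ=60	GT:AD	0/0:20,0	0/1:2,2	0/1:10,10
chr1	9000	.	T	A	100	PASS	MQ=60	GT:AD	0/0:30,0	0/0:18,2	1/1:0,20
chr1	10000	.	A	C	100	PASS	MQ=60	GT:AD	0/0:20,0	0/0:18,2	0/0:16,4
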