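# Per-study allele-level 2x2 tables for the pooled analyses (case/control allele counts).
# Exposed allele: A for rs13397, T for rs1059703 and rs1059702, C for rs3027898.
# Chinese rs3027898 control alleles are derived from the published genotype row
# (AA 337, AC 103, CC 35); the published allele row for that cell is internally
# inconsistent with its genotype row and is not used.
snp	study	exposed_allele	other_allele	case_exposed	case_other	control_exposed	control_other
rs13397	Tunisia	A	G	60	178	55	207
rs13397	France	A	G	179	399	143	537
rs1059703	Tunisia	T	C	169	69	205	57
rs1059703	France	T	C	377	201	541	139
rs1059703	Greece	T	C	206	66	234	60
rs1059703	Korea	T	C	507	1819	441	1273
rs1059702	Tunisia	T	C	71	167	66	196
rs1059702	France	T	C	164	414	123	557
rs1059702	Korea	T	C	1807	517	1266	454
rs3027898	Greece	C	A	85	187	65	229
rs3027898	Korea	C	A	495	1821	421	1277
rs3027898	China	C	A	324	98	173	777
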