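# Published chromosome-level allele counts for the Tunisian/French RA cohorts.
# Must equal 2*hom + het applied to the genotype-count fixture (consistency-checked in tests).
population	group	snp	allele_major	allele_minor	n_major	n_minor	chrom
Tunisian	case	rs13397	G	A	178	60	X
Tunisian	control	rs13397	G	A	207	55	X
French	case	rs13397	G	A	399	179	X
French	control	rs13397	G	A	537	143	X
Tunisian	case	rs1059703	T	C	169	69	X
Tunisian	control	rs1059703	T	C	205	57	X
French	case	rs1059703	T	C	377	201	X
French	control	rs1059703	T	C	541	139	X
Tunisian	case	rs1059702	C	T	167	71	X
Tunisian	control	rs1059702	C	T	196	66	X
French	case	rs1059702	C	T	414	164	X
French	control	rs1059702	C	T	557	123	X
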