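# Published per-SNP genotype counts, case-control RA cohorts (female, X-linked panel).
# Orientation: major/minor alleles as observed in the Tunisian/French control groups.
population	group	snp	n_hom_major	n_het	n_hom_minor	allele_major	allele_minor	chrom
Tunisian	case	rs13397	66	46	7	G	A	X
Tunisian	control	rs13397	92	23	16	G	A	X
French	case	rs13397	131	137	21	G	A	X
French	control	rs13397	220	97	23	G	A	X
Tunisian	case	rs1059703	59	51	9	T	C	X
Tunisian	control	rs1059703	89	27	15	T	C	X
French	case	rs1059703	122	133	34	T	C	X
French	control	rs1059703	228	85	27	T	C	X
Greek	case	rs1059703	77	52	7	T	C	X
Greek	control	rs1059703	94	46	7	T	C	X
Korean	case	rs1059703	59	389	715	T	C	X
Korean	control	rs1059703	52	337	468	T	C	X
Tunisian	case	rs1059702	62	43	14	C	T	X
Tunisian	control	rs1059702	81	34	16	C	T	X
French	case	rs1059702	157	100	32	C	T	X
French	control	rs1059702	237	83	20	C	T	X
Korean	case	rs1059702	62	393	707	C	T	X
Korean	control	rs1059702	59	336	465	C	T	X
Greek	case	rs3027898	71	45	20	A	C	X
Greek	control	rs3027898	91	47	9	A	C	X
Korean	case	rs3027898	719	383	56	A	C	X
Korean	control	rs3027898	478	321	50	A	C	X
Chinese	case	rs3027898	28	42	141	A	C	X
Chinese	control	rs3027898	337	103	35	A	C	X
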