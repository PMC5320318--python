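# Published HLA-DRB1 allele-group counts among RA cases, Tunisian (264 alleles) vs French (346 alleles).
# se = 1 marks shared-epitope allele groups.
allele	se	n_tunisian	total_tunisian	n_french	total_french
DRB1*01:XX	1	16	264	59	346
DRB1*01:03	0	0	264	1	346
DRB1*03:XX	0	42	264	15	346
DRB1*04:01	1	11	264	48	346
DRB1*04:02	0	1	264	1	346
DRB1*04:03	0	3	264	4	346
DRB1*04:04	1	8	264	30	346
DRB1*04:05	1	19	264	12	346
DRB1*04:06	0	6	264	0	346
DRB1*04:07	0	0	264	1	346
DRB1*04:08	1	3	264	9	346
DRB1*04:11	0	1	264	0	346
DRB1*07:XX	0	41	264	46	346
DRB1*08:XX	0	3	264	1	346
DRB1*09:XX	0	1	264	2	346
DRB1*10:01	1	33	264	13	346
DRB1*11:XX	0	19	264	25	346
DRB1*12:XX	0	0	264	5	346
DRB1*13:XX	0	40	264	24	346
DRB1*14:XX	0	4	264	4	346
DRB1*15:XX	0	12	264	33	346
DRB1*16:XX	0	1	264	13	346
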