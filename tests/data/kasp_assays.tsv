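marker	chrom	pos	allele_x	allele_y	fam_primer	vic_primer	common_primer
SNP1	Chr01	748311	A	G	GAAGGTGACCAAGTTCATGCTCTACAGTACCCTCTCCTGCATCTTATA	GAAGGTCGGAGTCAACGGATTCAGTACCCTCTCCTGCATCTTATG	ATTCCTACAATCATCTCCATATGCA
SNP2	Chr02	891832	T	A	GAAGGTGACCAAGTTCATGCTCCTCAACGTGATGCTTGGATAT	GAAGGTCGGAGTCAACGGATTCCTCAACGTGATGCTTGGATAA	CCAAGAGATRTCATCGCTCCTTA
SNP3	Chr04	1507807	C	T	GAAGGTGACCAAGTTCATGCTTTCAACCCCAAAATCACTTCAC	GAAGGTCGGAGTCAACGGATTTTCAACCCCAAAATCACTTCAT	GATTGGGGTGAAATTCACAGAC
SNP4	Chr05	840191	C	A	GAAGGTGACCAAGTTCATGCTGCCATCTCCCTGCTGAGC	GAAGGTCGGAGTCAACGGATTTGCCATCTCCCTGCTGAGA	TTAAAGATGTTGTAATGTGGAGTTCC
SNP5	Chr06	822640	C	T	GAAGGTGACCAAGTTCATGCTGAAAATTTTTGAACATGAAGACATATC	GAAGGTCGGAGTCAACGGATTGAAAATTTTTGAACATGAAGACATATT	AAATTCAAAATTTCTCTTCGTGC
SNP6	Chr06	1542780	C	G	GAAGGTGACCAAGTTCATGCTGACAAACAGTCCAGAGGTAGCC	GAAGGTCGGAGTCAACGGATTGACAAACAGTCCAGAGGTAGCG	GTTAACAAACCAGCACACATGG
SNP7	Chr07	273819	G	A	GAAGGTGACCAAGTTCATGCTGTCGAATAGGTCAGCAATTAAGG	GAAGGTCGGAGTCAACGGATTGGTCGAATAGGTCAGCAATTAAGA	AAGGTCAGAGTCCGGAACAAA
SNP8	Chr07	2457030	G	A	GAAGGTGACCAAGTTCATGCTCAAACGACCTCTCTTTGGCTG	GAAGGTCGGAGTCAACGGATTTCAAACGACCTCTCTTTGGCTA	AGTGAAGTTGAATCTTAAACAACGC
SNP9	Chr08	4052324	A	G	GAAGGTGACCAAGTTCATGCTAATCTGTCTTGACTGGCGACA	GAAGGTCGGAGTCAACGGATTATCTGTCTTGACTGGCGACG	ACATCTCCTGTCCGAACGATC
SNP10	Chr09	2609642	G	A	GAAGGTGACCAAGTTCATGCTTTCTGCCGAGCAAATATCG	GAAGGTCGGAGTCAACGGATTTTTCTGCCGAGCAAATATCA	AAACACTTCTGAATCTCACGGAC
SNP11	Chr10	16289987	A	G	GAAGGTGACCAAGTTCATGCTATGCATAAATGTGGTCATTGGAA	GAAGGTCGGAGTCAACGGATTATGCATAAATGTGGTCATTGGAG	AGTAGTGCCAATTTCTCCTTTTTAA
SNP12	Chr11	546091	A	T	GAAGGTGACCAAGTTCATGCTCCTTTGAATTTGGTGTACCATTGA	GAAGGTCGGAGTCAACGGATTCCTTTGAATTTGGTGTACCATTGT	GGTTCAAATGGCAACTTTTCACT
SNP13	Chr11	97692	G	A	GAAGGTGACCAAGTTCATGCTAGGAGCAAACAATGGCGAG	GAAGGTCGGAGTCAACGGATTAGGAGCAAACAATGGCGAA	TCGATCAGGAGATACWGCAACT
SNP14	Chr04	2732996	A	C	GAAGGTGACCAAGTTCATGCTCAGAGCGTTTTTATGCTTCCA	GAAGGTCGGAGTCAACGGATTCAGAGCGTTTTTATGCTTCCC	GCATGCCAGTAAGCTCTATGAAT
SNP15	Chr08	2517264	C	T	GAAGGTGACCAAGTTCATGCTCCAGTATAAAACTTAGGCTACCACTG	GAAGGTCGGAGTCAACGGATTGCCAGTATAAAACTTAGGCTACCACTA	GCTACGCATATGGTCAGCCTAG
SNP16	Chr10	2162356	A	G	GAAGGTGACCAAGTTCATGCTGGGAAAAGTGCATCAAGAACA	GAAGGTCGGAGTCAACGGATTGGGAAAAGTGCATCAAGAACG	AGAATTGTTTATTACTAATGACTTTATCCTA
SNP17	Chr01	15609708	G	A	GAAGGTGACCAAGTTCATGCTGCAATCAGTTTTTATCAACTACCTAAG	GAAGGTCGGAGTCAACGGATTGCAATCAGTTTTTATCAACTACCTAAA	ACCTGAAGAGTTTGCTATTGGG
SNP18	Chr04	19767972	A	G	GAAGGTGACCAAGTTCATGCTGCATTTGTTGTTGGATACTTGAA	GAAGGTCGGAGTCAACGGATTGCATTTGTTGTTGGATACTTGAG	CAAACCTCTTTGGGAAGTTCAT
SNP19	Chr05	14648703	T	C	GAAGGTGACCAAGTTCATGCTCCTCCACCTTATATATACATCGGACT	GAAGGTCGGAGTCAACGGATTCTCCACCTTATATATACATCGGACC	GTTGTAATGGAGATAATGCTGCTTC
SNP20	Chr06	32096649	A	G	GAAGGTGACCAAGTTCATGCTGTCCCCTGACCAATTGTTAATTA	GAAGGTCGGAGTCAACGGATTCCCCTGACCAATTGTTAATTG	TTACAAGTAAGATTTAAATCAGTATTTTTAAT
SNP21	Chr07	2539626	T	C	GAAGGTGACCAAGTTCATGCTCACCAAAATTTGGAGGGGTTA	GAAGGTCGGAGTCAACGGATTACCAAAATTTGGAGGGGTTG	GGAAACCAACTTGAAAACCTGAC
SNP22	Chr07	12819152	G	A	GAAGGTGACCAAGTTCATGCTGCCGCTATTAAAAGGCTACTG	GAAGGTCGGAGTCAACGGATTGGCCGCTATTAAAAGGCTACTA	GCCTATAAGATAGTGTGCCATTCA
SNP23	Chr08	1096769	T	C	GAAGGTGACCAAGTTCATGCTGGAAGAAAGAAGCCACTCCTACTT	GAAGGTCGGAGTCAACGGATTGGAAGAAAGAAGCCACTCCTACTC	TTAACTTCCTTAACGACACTGGTAGA
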