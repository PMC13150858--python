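cultivar	fingerprint
Zhenpingtailihong	GTGTTGGGGTTAAAATGTGTTGCGAGCGTTGCATGAGCAC
Shandonglizao	TTTATTCCTCAACGTGATGCTTGGATAATTGAATAAGGAG
Dayewuhe	AGAAAACTTCAACCCCAAAATCACTTCATAAGTCTGTGAA
Jingcang No.1	CCAACTACATATGATTGATAACCACATTCGATCCATTTGG
Shanxihuluzao	AACAGAGTTTGGTTTAGTTCCCTCTGCATGCATCTGTTTG
Saimisu No.1	CGAAAATTACGTTTACTACCATTTGCTCTTCCAATGCAAA
Jiancuizao	GACAAACAGTCCAGAGGTAGCCGCCGTACCATGTGTGCTG
Jinmangguozao	TCTAACTTGGTCAAATATTTTGCCCCACTAAGTTGGTCGA
Suanzao No.1	TCTGCCTTTTGTTTTGCTTTCGAAAAACAGAAAAATCGGC
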