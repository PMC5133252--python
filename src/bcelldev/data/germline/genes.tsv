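gene	locus	segment	family	sequence
IGHV1-2	IGH	V	1	GTTCACTATCCATCTGCCCCGACGACTGGAGCGTCGCCAATCGTTGTACACCCGCCAATGTGTTTTCCA
IGHV1-3	IGH	V	1	ATAAGCTATTACTGGCCGAGCCAGGTCTACATAAGCGGCGACGGAGATTGCAAAGTAGGTTGCCGCTGT
IGHV1-18	IGH	V	1	TCTCTCATTCAAATACTTTTGCACTCGCATCTTGTTGTATGCCGATATGCATCGATGCTGTGTGTGATA
IGHV1-46	IGH	V	1	GTTCGTTCTCTCACTGAGACCCCGCGGCCATGGAGCGGGTCGCTTAGATATGTCCAGGTTTGTGTATGG
IGHV1-69	IGH	V	1	CATACGCTAGGTCGCTACTCGCCCTGGTCGCACTATCGCGCGATTAAGCGGGCGACGCGATGTCACGCG
IGHV2-5	IGH	V	2	TCGCCGGCCCTCTCGGTGAACATAGTGATTTTCTATCGATCCACGCACTTTCATACTTTTTGCAACTCA
IGHV2-26	IGH	V	2	TTTACCGTCGAGCTAGCAGCAACTGGGATGTGGGTTTACAGGAGTTCCAAGCGGGCTAATTGCCCCCGC
IGHV3-7	IGH	V	3	GATTTAGGGCCCTGGCTCCTTCATGCCAAGCTGATTCGACAGTTAAGTCGGAAAGTGACATGTCCTACT
IGHV3-9	IGH	V	3	AGGATAATACAAAGGCATACCCTAAATCTGAATTTCCACACCCCGCCTTCTCAATCTCATTGTATGAGA
IGHV3-11	IGH	V	3	CTGCCCATCTCCATGGGGCCTTCCTCGACAGAACAGTTGCATGGGATGGATCGGTTTGAGTGTAGCGGA
IGHV3-15	IGH	V	3	AGAATGCTAGTTACCGGGATCTTGACTACTTGTTTATTGCACGACCTAGCGTTACTGACTTGTTCAGTG
IGHV3-21	IGH	V	3	TTTCTGCGGTCCTCCCTTCCTATCAGGAACCAGTGTTGTGTGGTTCTGCGGGCTCGTACTTGTGCAAGT
IGHV3-23	IGH	V	3	CATATGCCGAACCCTCCTTTTAGACATGTGCCTACGCAGGCTACTCTGCACAGTGAGGGGTGTGTGCCA
IGHV3-30	IGH	V	3	GGGCAGTTGGGGTTCTCAACCGCCGCTAATTGGGTGAACCAGGATGAATGCAACAAAATGTGTACTAAT
IGHV3-33	IGH	V	3	TCGTCTCATGATACTAAATCTACAATCCTGCCGCGAGTGATGCCAGTAAGCCCGTGGAGGTGTAACCCC
IGHV3-48	IGH	V	3	TATTGTGGCACGGTACTTGGCTGGCTATCTCCATGGTTATTGTGCTACACCCCGATCCGATGTCTCGAG
IGHV3-53	IGH	V	3	GGGCGCATTGAGTGCTTCGGGGAACCGCGCATTGCTGACGGGTGTGTTTCTAGTAGCGTATGTGCAATA
IGHV3-74	IGH	V	3	CTCGCGTCCCCATCTCCAGCCCCCTTCTGTTTTCATATAGCACTCCTGCAGCGGACTCGATGTCCCCGA
IGHV4-4	IGH	V	4	GAGGAAACGGAGCTTAGGTGTAACTCACTGGCAGGCCCCTTCTGTGCGACGTGGCTGGGATGTGGACGG
IGHV4-31	IGH	V	4	ACTAGGAAACCACAGGGCGGAGTAGCCTGGGCGGTCCAATCGGGCAGATCGGATGTGTCGTGTGAGGTT
IGHV4-34	IGH	V	4	TTTCTGTTAAACCAGTCGCTGGCCCGTAGCTCACGGTGGCTGATTTTGTACCCGTTTAGATGTTCGTGG
IGHV4-39	IGH	V	4	TCCGCCCGCGTCCGGTGGCCTCGTTCATGGTGCCCATGTCGGAAAAGCGCAGCGGTGGCCTGTGCAATG
IGHV4-59	IGH	V	4	TCGTTGATTATAAGCCCTGGGCGGAATAAGCTAACTAGAGATTGGACGCGGCCGACATCGTGTCTGAAT
IGHV5-51	IGH	V	5	GCTCACCACGATCTACATACATCGCCGGCGCATTCCCTCACGAAGGATTTTCACGCGGCTTGTGGGGGT
IGHV6-1	IGH	V	6	CACAACAATTCTCAATGTTCCATAGAGAATACAGAACTTTATGTATTGTTCTCGCTGTCGTGCAGTAAG
IGHV7-4-1	IGH	V	7	CAATATCGGGGACGCTCGGTCCAAGAGAGCGGACAGCTCCGCTACTCGCACGGACTTCACTGTAGGGCT
IGHD1-1	IGH	D	1	GGAGCCGATCACC
IGHD1-7	IGH	D	1	TCCCTGTCACATATCGAACGT
IGHD1-26	IGH	D	1	CTCACATAGAGATCATCCCG
IGHD2-2	IGH	D	2	CTGTGGAGCATACGGCC
IGHD2-15	IGH	D	2	GGCGGACCTTGTGCAAGAC
IGHD2-21	IGH	D	2	CTAACGCAGGTAACCGAGGGA
IGHD3-3	IGH	D	3	CTAATTGATCTCTGGCC
IGHD3-10	IGH	D	3	TACCTACACCGGCAC
IGHD3-22	IGH	D	3	GGAATGCTGGCCAGCCCG
IGHD4-17	IGH	D	4	CGGCAGCAACGCG
IGHD5-12	IGH	D	5	CTCACGCCCGATA
IGHD6-13	IGH	D	6	CAGAGGCTTGGTAGAAATC
IGHD6-19	IGH	D	6	GTACGGATTTAACAGCCCGC
IGHD7-27	IGH	D	7	GACGCGGCAAGA
IGHJ1	IGH	J	1	ATCGAGCACTGGGGCGGTTCGTTCTATTCT
IGHJ2	IGH	J	2	ATTTGGTAGTGGGGGCGGCATTCATGTTAC
IGHJ3	IGH	J	3	CTGGGCGTATGGGGGGAGTCTGTCTTAGAT
IGHJ4	IGH	J	4	TTGACGAGATGGGGGATACGTCGTGATACA
IGHJ5	IGH	J	5	GCACTAGTGTGGGGTTATTAACCGGTTCGC
IGHJ6	IGH	J	6	CCCCAGTCCTGGGGCAGACGTCGGACAATT
IGKV1-5	IGK	V	1	TATTGTGGGGACGCCGACCACCATTATCAATTACGGTCTCGCTCGCGCCCCGGAATGCTGTGCTGCACC
IGKV1-39	IGK	V	1	ATCGATCCGAAATGGTGCCGTAATTGGCCTACCCCGAGGCAGTACTATTGCCTGGTAGGCTGTATGTCT
IGKV2-28	IGK	V	2	CCAGTGTTCGTACCGGATGCCCTCAGGAATGGCGTGAAGCTCGTCACTGATCCAATGAAATGCTCAGTG
IGKV2-30	IGK	V	2	AGTGCCCGTTGTGATATGAAATATAGACCGGTGCTGATGAAGGAAATGCAAGGGGCCAACTGTCTATCT
IGKV3-11	IGK	V	3	GGCGGATTAACCCTCATCAAGAGTGCGGGTCCCTCTGTGGCGAGCAACGATAACTCAGCGTGTCGTCAT
IGKV3-15	IGK	V	3	TCACCGTGGAAAGTATTCGCAATAGCTTGGATAGTTTCGACGGCCGTCGGAAGGGCATGGTGCCGGCCT
IGKV3-20	IGK	V	3	GTGGCAAGTAACGAGCGACGATGTCCTACAGCAGCGAAAAAAAAAAACTTGACCAAAGTCTGCGCCTCA
IGKV4-1	IGK	V	4	ACAACTCTCGAGACTGTCCTCTCTTCCACAGCGCCTCAAAAGGCAGTCGTGTTCCTCATGTGCGTTCAC
IGKJ1	IGK	J	1	AATGTTTCCTTCGGTCCCTATTACCACAAG
IGKJ2	IGK	J	2	GTTTGGTCATTCGGTCTTGGGACGTTAATC
IGKJ3	IGK	J	3	AACAAGTTATTCGGAGCGGCCCACGACCTT
IGKJ4	IGK	J	4	GATGTGATATTCGGCGTACTCATAACTCCA
IGKJ5	IGK	J	5	CCAGGGCTGTTCGGCGGGTGTTGTTCGGCT
IGLV1-40	IGL	V	1	CGATCAGAACGAGAGGGGTCTCGGAACCCTGGTCATGACTTCAGCGGAAGTACGAGCCTCTGTTCACAT
IGLV1-44	IGL	V	1	TCTATCCGATGCAGGCTGATCGACGAGTTGAGGAGCGAACCCCATAGCCTACCTGTGTTATGTGACTAA
IGLV1-51	IGL	V	1	ACACATGGAAGGCTCCCGGTCCGACGATTCGGTGTGTCTAAATGTGTTTTGATGAGCGTATGTTTGTAC
IGLV2-8	IGL	V	2	GCCGACGTTATCCTAGCGGTACTTTTGGTTATACTAACACTAACGACGGTTCCGCCACGGTGTGAGAAA
IGLV2-11	IGL	V	2	TACATGGACGGCTGGCGGCAGAGTGTTGAAGGCAGTTGCTTTCCTAGAAGATTATCCTTTTGTAGGTAG
IGLV2-14	IGL	V	2	CCTAGGTCCGATGAGCGCAATGCGTGTCGTAACGTAGATAGTGCAAGCGACAAAGATCTGTGTTGCGTG
IGLV2-23	IGL	V	2	GTTGTGTATGAAAGTGATTTAGTCCCTTGGACTGAATGCGACGTCAGGGCTCGGAGGCTCTGTGAGATG
IGLV3-1	IGL	V	3	GAATTGATAGTTTGTGAGCAGCACCATCTCGCGCGGGTACGGATAGTAGCCACCTGTGGATGTACATTT
IGLV3-21	IGL	V	3	GGGAGGCCTAGCGGGCGCTGGGTCGCTGAAGTACGGGTAGCGTGTAGGCGTTGGCGTTGTTGCTCCCTC
IGLV3-25	IGL	V	3	GGTGTTCGGTGCCGGACCCATGTACACACTGGCGACAGGTACGAGGGACTAGCTCAATTTTGCCCCTGT
IGLJ1	IGL	J	1	CTCAGTACATTCGGCAGGGCGAGAACGAGC
IGLJ2	IGL	J	2	GATGTTTTATTCGGATCTCTCGGTCCAGCT
IGLJ3	IGL	J	3	CCTGGTAGATTCGGTCAGCCTCCACCATCG
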