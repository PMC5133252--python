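>IGHV1-2
GTTCACTATCCATCTGCCCCGACGACTGGAGCGTCGCCAATCGTTGTACACCCGCCAATGTGTTTTCCA
>IGHV1-3
ATAAGCTATTACTGGCCGAGCCAGGTCTACATAAGCGGCGACGGAGATTGCAAAGTAGGTTGCCGCTGT
>IGHV1-18
TCTCTCATTCAAATACTTTTGCACTCGCATCTTGTTGTATGCCGATATGCATCGATGCTGTGTGTGATA
>IGHV1-46
GTTCGTTCTCTCACTGAGACCCCGCGGCCATGGAGCGGGTCGCTTAGATATGTCCAGGTTTGTGTATGG
>IGHV1-69
CATACGCTAGGTCGCTACTCGCCCTGGTCGCACTATCGCGCGATTAAGCGGGCGACGCGATGTCACGCG
>IGHV2-5
TCGCCGGCCCTCTCGGTGAACATAGTGATTTTCTATCGATCCACGCACTTTCATACTTTTTGCAACTCA
>IGHV2-26
TTTACCGTCGAGCTAGCAGCAACTGGGATGTGGGTTTACAGGAGTTCCAAGCGGGCTAATTGCCCCCGC
>IGHV3-7
GATTTAGGGCCCTGGCTCCTTCATGCCAAGCTGATTCGACAGTTAAGTCGGAAAGTGACATGTCCTACT
>IGHV3-9
AGGATAATACAAAGGCATACCCTAAATCTGAATTTCCACACCCCGCCTTCTCAATCTCATTGTATGAGA
>IGHV3-11
CTGCCCATCTCCATGGGGCCTTCCTCGACAGAACAGTTGCATGGGATGGATCGGTTTGAGTGTAGCGGA
>IGHV3-15
AGAATGCTAGTTACCGGGATCTTGACTACTTGTTTATTGCACGACCTAGCGTTACTGACTTGTTCAGTG
>IGHV3-21
TTTCTGCGGTCCTCCCTTCCTATCAGGAACCAGTGTTGTGTGGTTCTGCGGGCTCGTACTTGTGCAAGT
>IGHV3-23
CATATGCCGAACCCTCCTTTTAGACATGTGCCTACGCAGGCTACTCTGCACAGTGAGGGGTGTGTGCCA
>IGHV3-30
GGGCAGTTGGGGTTCTCAACCGCCGCTAATTGGGTGAACCAGGATGAATGCAACAAAATGTGTACTAAT
>IGHV3-33
TCGTCTCATGATACTAAATCTACAATCCTGCCGCGAGTGATGCCAGTAAGCCCGTGGAGGTGTAACCCC
>IGHV3-48
TATTGTGGCACGGTACTTGGCTGGCTATCTCCATGGTTATTGTGCTACACCCCGATCCGATGTCTCGAG
>IGHV3-53
GGGCGCATTGAGTGCTTCGGGGAACCGCGCATTGCTGACGGGTGTGTTTCTAGTAGCGTATGTGCAATA
>IGHV3-74
CTCGCGTCCCCATCTCCAGCCCCCTTCTGTTTTCATATAGCACTCCTGCAGCGGACTCGATGTCCCCGA
>IGHV4-4
GAGGAAACGGAGCTTAGGTGTAACTCACTGGCAGGCCCCTTCTGTGCGACGTGGCTGGGATGTGGACGG
>IGHV4-31
ACTAGGAAACCACAGGGCGGAGTAGCCTGGGCGGTCCAATCGGGCAGATCGGATGTGTCGTGTGAGGTT
>IGHV4-34
TTTCTGTTAAACCAGTCGCTGGCCCGTAGCTCACGGTGGCTGATTTTGTACCCGTTTAGATGTTCGTGG
>IGHV4-39
TCCGCCCGCGTCCGGTGGCCTCGTTCATGGTGCCCATGTCGGAAAAGCGCAGCGGTGGCCTGTGCAATG
>IGHV4-59
TCGTTGATTATAAGCCCTGGGCGGAATAAGCTAACTAGAGATTGGACGCGGCCGACATCGTGTCTGAAT
>IGHV5-51
GCTCACCACGATCTACATACATCGCCGGCGCATTCCCTCACGAAGGATTTTCACGCGGCTTGTGGGGGT
>IGHV6-1
CACAACAATTCTCAATGTTCCATAGAGAATACAGAACTTTATGTATTGTTCTCGCTGTCGTGCAGTAAG
>IGHV7-4-1
CAATATCGGGGACGCTCGGTCCAAGAGAGCGGACAGCTCCGCTACTCGCACGGACTTCACTGTAGGGCT
>IGHD1-1
GGAGCCGATCACC
>IGHD1-7
TCCCTGTCACATATCGAACGT
>IGHD1-26
CTCACATAGAGATCATCCCG
>IGHD2-2
CTGTGGAGCATACGGCC
>IGHD2-15
GGCGGACCTTGTGCAAGAC
>IGHD2-21
CTAACGCAGGTAACCGAGGGA
>IGHD3-3
CTAATTGATCTCTGGCC
>IGHD3-10
TACCTACACCGGCAC
>IGHD3-22
GGAATGCTGGCCAGCCCG
>IGHD4-17
CGGCAGCAACGCG
>IGHD5-12
CTCACGCCCGATA
>IGHD6-13
CAGAGGCTTGGTAGAAATC
>IGHD6-19
GTACGGATTTAACAGCCCGC
>IGHD7-27
GACGCGGCAAGA
>IGHJ1
ATCGAGCACTGGGGCGGTTCGTTCTATTCT
>IGHJ2
ATTTGGTAGTGGGGGCGGCATTCATGTTAC
>IGHJ3
CTGGGCGTATGGGGGGAGTCTGTCTTAGAT
>IGHJ4
TTGACGAGATGGGGGATACGTCGTGATACA
>IGHJ5
GCACTAGTGTGGGGTTATTAACCGGTTCGC
>IGHJ6
CCCCAGTCCTGGGGCAGACGTCGGACAATT
>IGKV1-5
TATTGTGGGGACGCCGACCACCATTATCAATTACGGTCTCGCTCGCGCCCCGGAATGCTGTGCTGCACC
>IGKV1-39
ATCGATCCGAAATGGTGCCGTAATTGGCCTACCCCGAGGCAGTACTATTGCCTGGTAGGCTGTATGTCT
>IGKV2-28
CCAGTGTTCGTACCGGATGCCCTCAGGAATGGCGTGAAGCTCGTCACTGATCCAATGAAATGCTCAGTG
>IGKV2-30
AGTGCCCGTTGTGATATGAAATATAGACCGGTGCTGATGAAGGAAATGCAAGGGGCCAACTGTCTATCT
>IGKV3-11
GGCGGATTAACCCTCATCAAGAGTGCGGGTCCCTCTGTGGCGAGCAACGATAACTCAGCGTGTCGTCAT
>IGKV3-15
TCACCGTGGAAAGTATTCGCAATAGCTTGGATAGTTTCGACGGCCGTCGGAAGGGCATGGTGCCGGCCT
>IGKV3-20
GTGGCAAGTAACGAGCGACGATGTCCTACAGCAGCGAAAAAAAAAAACTTGACCAAAGTCTGCGCCTCA
>IGKV4-1
ACAACTCTCGAGACTGTCCTCTCTTCCACAGCGCCTCAAAAGGCAGTCGTGTTCCTCATGTGCGTTCAC
>IGKJ1
AATGTTTCCTTCGGTCCCTATTACCACAAG
>IGKJ2
GTTTGGTCATTCGGTCTTGGGACGTTAATC
>IGKJ3
AACAAGTTATTCGGAGCGGCCCACGACCTT
>IGKJ4
GATGTGATATTCGGCGTACTCATAACTCCA
>IGKJ5
CCAGGGCTGTTCGGCGGGTGTTGTTCGGCT
>IGLV1-40
CGATCAGAACGAGAGGGGTCTCGGAACCCTGGTCATGACTTCAGCGGAAGTACGAGCCTCTGTTCACAT
>IGLV1-44
TCTATCCGATGCAGGCTGATCGACGAGTTGAGGAGCGAACCCCATAGCCTACCTGTGTTATGTGACTAA
>IGLV1-51
ACACATGGAAGGCTCCCGGTCCGACGATTCGGTGTGTCTAAATGTGTTTTGATGAGCGTATGTTTGTAC
>IGLV2-8
GCCGACGTTATCCTAGCGGTACTTTTGGTTATACTAACACTAACGACGGTTCCGCCACGGTGTGAGAAA
>IGLV2-11
TACATGGACGGCTGGCGGCAGAGTGTTGAAGGCAGTTGCTTTCCTAGAAGATTATCCTTTTGTAGGTAG
>IGLV2-14
CCTAGGTCCGATGAGCGCAATGCGTGTCGTAACGTAGATAGTGCAAGCGACAAAGATCTGTGTTGCGTG
>IGLV2-23
GTTGTGTATGAAAGTGATTTAGTCCCTTGGACTGAATGCGACGTCAGGGCTCGGAGGCTCTGTGAGATG
>IGLV3-1
GAATTGATAGTTTGTGAGCAGCACCATCTCGCGCGGGTACGGATAGTAGCCACCTGTGGATGTACATTT
>IGLV3-21
GGGAGGCCTAGCGGGCGCTGGGTCGCTGAAGTACGGGTAGCGTGTAGGCGTTGGCGTTGTTGCTCCCTC
>IGLV3-25
GGTGTTCGGTGCCGGACCCATGTACACACTGGCGACAGGTACGAGGGACTAGCTCAATTTTGCCCCTGT
>IGLJ1
CTCAGTACATTCGGCAGGGCGAGAACGAGC
>IGLJ2
GATGTTTTATTCGGATCTCTCGGTCCAGCT
>IGLJ3
CCTGGTAGATTCGGTCAGCCTCCACCATCG
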