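>IGHV1-2|V
ATATCTCGCAGCTGCCTTGTCAGCAGTAATGGCACATCCAGTACACGGTTTGAGTCCCCA
AACCTCTGCTCGTCTTCCTATAGCCAGGCAGCCATATTGGCAAGAGAAGAAATCATAAAA
TGGTCGGATTCTGTCGTTCTAAAAAAACGGATACCGAGCACATGCCTTGGCAGCAAATCA
ATAAGGCGTCGGATTCGCATGGACCGGCTGCGCATAGTAGCCGGGCCGAGTACACTTGGT
CAGAAGGGCCGGACGCTATCCCGGCGGGGTTCGACGAACGGCCTCGTCAGACGGGGCGCA
AGCGAACCTTGTGCTGTT
>IGHV1-46|V
ATATGTCGCTGGTGCCTCGTCAGCAGTAATGGCACTTCCAGGACACGGTATGAGTCCCCA
AACCTCTGCTCGTCTTCCTATCGCCAGGCAGGCATAATGCCAAGAGAAGAAATCATAAAA
TGGTCGGATACAGTCGTTCTAAAAAAACGGATACCGAACACATGCCCTGTCAGCAAATCA
ATAAGGCGACGGATGCGCATGGACAGGCAGCGCAGAGTCACCGGGCCGAGGACACTTGGT
CTGAAGGGGGGGACGCTATCCCGGCGGGGTTCGACGAACTGTCTCGTTAGACCGGGCGCA
AGCGAACCTTGTGCTGTT
>IGHV2-5|V
GGTGATACCCGGTCAGCTCGTGGCATCGCGCTTATCACTCAAACCACAAGTCGGGGCTGC
TTCCATTGCCACTCTGCCCACCTTATGCTCTACACCGCTGCCAGTGAAGCAGTGTGGGAA
TGGCTACAGCTTTTGGAGCTGCTAGCTAAAGCGACCTTACCGCAACAGGCGTTAGGTATT
ATCGCGAATTTAACCACGATCCACCCGTACATCGAGAAGAAAGAAAACGTTTACCTGGCG
ATCTCTCCCAAAGTTCAAACTGCCATGGGGGTGGCAAGAAACCTAAGTTCGGTCACTCAA
CACAGTGGTTGTCAACCG
>IGHV2-70|V
GGTGATACCCGGTCAGCTCGGGGCATCGCGCTTATCACTCAAACCACAAGTTGGTGCTGC
TTCCATTGCCACTCCGCTCAACTTATGCTCTACACCGCAGCCAGTGAAGCAGTGTGGGAA
TGGGTACAGCTATTGCAGCTGCTAACTAAAGCGACCTTACCGCGACAGGCGTTAGGTATT
ATCGCGAATTTAATCACGATCCACTCATACATCAAGAAGAATGAAAACGTTCACCTGGTG
GTCTCTCCCAAATTACAAACTGCCACGGTGGTTGCAAGTAACCTACGCTCGGTCACTCAA
CACGGTTGTTGTCAACCG
>IGHV3-23|V
GTATTTACTGGAGTGAGGCGCTTAGACTCGCGGGAAAACGGGAATGCGAACGACATGGCA
ATCACGTGCAGGCCGCAGAGATCAGACCTTCTTTGCGGTGGCTTCGTGACACTGCTACTC
TGGTACGACCAGAAAAGTCTGTTGGCTGTAAAAACCAACACAAGCCACTGGGCCACACGG
ACACAGATTCGGATCCCCTGGTGCGATGACCCTAGCATAGACTGTGTGTACGAGTTTGCA
TCAACCGGTACCCGGGGGCAGCCAACAGCGAGTTCCGGAGCAGTCACACGACCTTATGGT
TCGACTTTATGTTCGCTG
>IGHV3-7|V
GTATTTATTGGAGTGAGCCGCCTAGACTCGGGGGAAAACGGGAATGCGAACGACAAGGGA
ATCAGGTGCTGGCCCCAGAGATCAGACCTGCTTTGCGGAGGCTTCATGACACTGCTACTC
TGGGACGGCCAGAAAACTCTGTTGGCTGTAAAAACCCACACAAGCGACTGGGCCCCACGG
ACACAGATTCGGATCCCCTGGTGCGATGACCCTAGCATAAACTGTGAGTACGAGTTTGCA
TCGACTGGTACCCGTGGTCAGCCAACAGCGGGTTCCGGAGCAGTCACACGACGTTATGGT
TCGGCTTTATGTTCGCTG
>IGHV4-34|V
AGAATTATGCTTGGAAAATCTTATCTTGGTCTGTTAAGAGCTCACGATTCTTACGATGGA
AAAACATGCACTGGAACAGGGCTGGTCGAATTAATGGTGGAATACCAGTTGGATTATCGG
TGGTTTTGTTGCATACTCGCTGATGCAGGTTTAGCCGCAGATATACAACGCGTGCTGCGA
AGTCGCGTAGTAATGCCGAAACTCTCTATTCATGTGTCTGTTTGGTGCGGCTGCAGTCGC
CCAGTGGTTAGTGATGCAATCCGTAGAATTCGGGCGCGTAACTTATCAGTTTACTTCATA
TCAAGCCCGTGTACTTTC
>IGHV4-59|V
AGAATTATGCTTGGAAAATCTTATCTTGGTGTGCTAAGAGCTCACGATTCGTACGATGGC
AAAACATGCACTGGAACAGGGTTGGTCGAATTAATGGTGGAACACCAGCTGGATTATCGG
TGGGATTGTTGCGTACTCGCTTATGCATTTTTAGCCGCAGATATACGACGCGTGCTGCGA
CGTCGCGTAGTAATGCCAAAACTCTCTATTCATGTCTCTGTTTGGTGCGGCTGCACTCGC
AGTGTGGTTAGTGATGCAATCCGTAAAATTCGAGCCCGTAACTTATCAGTTTACTTGTTT
TCAAGCCAGTGTAATTTC
>IGHV5-51|V
AAATGGCATCACGTTTTCAGTCGTGTGTTTGACACTCATGTGCCAAATAGGCAGTACGTG
GCACACTGCGATCAGTATTCCACGGGCAGTGGTATTGAATGCAAAAGAGTACTCGCGTTA
TGGGCTAGGGTGGGTGACGTGATCGTACAGGTAACGCTTTCTCCTTGGTGGACAGGCCCG
ATGTACTATTATCTTAGGTACACTTACTATTTTGCGCACGACCAATCGAATGGAGGGCCT
GGGGCACTTACACCTTCCGTTAACATCCAACAAGCTCCTCGCCCTCCAGGTCCTATCTTA
GTTGAATTCTGTTTATTT
>IGHV5-10|V
AAATGGCATCACGTTTTCAGTCGTGTGCTTGGAACTCATGGGCCATATAGGGAGTACGTG
GCACACTGCGATGACTACTCCACGGGCAGTGGTATTGAATGCATCAGAGTACTCGCGTTA
TGGGCTAGGGTGGGTGACGTGATCGTTCAGGTAACGTCTTCTCCTTGGTGGACAGGCCCG
ATGTACTATTATATTACGTACACTTACTCTTTTGCGCACGACGATTCGAATGGGGGGCCT
GGGGCAGTTACAACTTCCGTTAACATCCAACAAGATCCTCGCCCTCCAGGTCCTATCTTA
CATGTATTGTGTTTATTT
>IGHJ4|J
TTAAGTCTAACGAATTGGCATCATAAAGTCAGAGGTCGGATTTCTGGG
>IGHJ5|J
ATAAGTTTAACGAATTGGTATCATAAAACCAGAGAGCGGATTTCTGGG
>IGHJ6|J
TTAAGTCTAACGAATTGGCTTCATAAAGTCAGCGGTCGGATTTGTGTG
>IGHD1-26|D
GTCGCTTACGTTAT
>IGHD2-2|D
TGGTATTCCACCGACA
>IGHD3-10|D
GTGCGCCTGTCAAGC
>IGHD4-17|D
GCATGCACCCAT
>IGHD5-12|D
AATGGAGTATACC
>IGHG1|C|IgG1
TTCGTGATCCGCCAGAACGACTGCCACAACCCGTACACCACACTCTCCGATCAACAGAGA
AATACTTACGTATCCGTGACACTACACCCTTCGAGTAGAACTGCACCTGTAGGTCTCGTC
TCTTGCTTCACCCTACTGCGCTCCGCTTTCGCTGCATTTGGAAAGAGCCCTTGGAAGGGA
CGAGCCGGCGCGCCCCAAAAAAATGAAACTGTTTCTAAGGTGGCATTTCTATATGACTAT
GCCGGACTTGCGGGCGTGCCGTGTAACAAC
>IGHG2|C|IgG2
TTCGTGATCCGCCAGGACGACTGCTACAACCCGTTCACCCCACTCTCCGATCAACAGAGA
AATACTTACGTATCCGAGTCACTAAACCCTTCGAGTAGGTCTGCAGCTGTAGGTCTCTTC
TCTTGCTACACCCTTCTGCGCTCCACTTACGCAGCATTTGGAAAGAGCCCTTGGAAGGGA
CGAGCCGGCGCGCCCCAAAATAATAAAACGGTTGCTAAGGTCACAGTTCAATATGACTCC
GCCGGACTTAGGGGCGTGCCGTGTAACAAC
>IGHG3|C|IgG3
GTCGTGATCCGCCAGGACGACTGCTACAACCCGTTCACCACACTCTCCGATCAACCGAGA
CATACTTACGTATTCGCGTCACTACACCCTTCGAGTAGGACTGCAGCTGTAGGTCTCGTC
TCTTGCTACACCCTTCTGCGCTCCGCTTTCGCAGCAATTGGAAAGAGCCCTTGGCAGGGA
CGAGCCGGCGCGCCCCAAAAAAATAAAACTGTGGCTAAGGAGGCAGTTCAATATGACTCT
GCCGGACTTGCGGGCGTGCCGTGTAACAAG
>IGHG4|C|IgG4
TTCGTGATCCGCAAGGACGACTGCTACAACCCGGTCAGCACACTCTCCGATCAACAGAGA
AATACTTACGTATCGGTGTCACTTCACCCTTCGATTGGGACTGCACCTGCAGGTCTCGTC
TATTGCTACACCCTTCTGCGCTCCACTTTCGCAGCATTTGGGAAGAGCCGATGGAAGGCA
GGAGCCGGCGCGCCCCAAAAAAATAAAACTGTTGCTAAGGTGGCAGTTCAATATGACTCT
GCCGGACTTGCGGGCGTGCCGTGTAACAAC
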