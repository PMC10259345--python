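>MAGOH_protein synthetic stand-in for the human MAGOH/MAGOHB pair
MESSRVSNPLQTTNVAVLRGGHSRPAKTLAGLPDTGSYVPAIRLMTPWKGKCVVSRRVFS
RDWDKGYAYPCKTTHLRAMNPRSMCYTPAEKRCPLHRPTPLGPPASGNGAQASAQRYTAS
SLAMLGSPIKALGTLRSSIRSSGGFC
>MAGOHB_protein synthetic stand-in for the human MAGOH/MAGOHB pair
MQASRVSNPLQTTNVAVLRGGHSRPAKTLAGLPDTGSYVPAIRLMTPWKGKCVVSRRVFS
RDWDKGYAYPCKTTHLRAMNPRSMCYTPAEKRCPLHRPTPLGPPASGNGAQASAQRYTAS
SLAMLGSPIKALGTLRSSIRSSGGFC
>MAGOH_cds synthetic stand-in for the human MAGOH/MAGOHB pair
ATGGAATCTTCTAGAGTGAGCAACCCACTACAGACTACCAATGTGGCGGTTCTAAGAGGG
GGACACTCTCGCCCCGCTAAAACTCTTGCTGGGTTACCAGATACCGGTTCTTATGTCCCT
GCCATAAGGCTTATGACTCCCTGGAAGGGCAAATGTGTAGTAAGCCGAAGAGTATTTTCT
CGCGACTGGGACAAGGGGTATGCGTACCCGTGTAAAACAACTCACTTGCGAGCGATGAAT
CCCAGATCAATGTGTTATACGCCTGCCGAGAAGAGATGTCCTTTGCATCGTCCTACGCCT
TTGGGACCACCAGCCAGCGGAAACGGTGCTCAAGCGTCGGCACAGCGGTACACTGCCTCA
AGTCTGGCTATGCTTGGCTCCCCGATCAAGGCCTTGGGAACTCTTAGATCAAGTATCCGT
TCTTCCGGCGGCTTTTGTTAA
>MAGOHB_cds synthetic stand-in for the human MAGOH/MAGOHB pair
ATGCAAGCTTCCAGAGTGAGCAATCCACTACAGACGACCAATGTGGCTGTGCTACGAGGG
GGACACTCACGGCCCGCGAAGACTCTTGCTGGCTTGCCAGATACCGGGTCGTATGTTCCC
GCAATAAGACTAATGACGCCCTGGAAAGGCAAATGTGTAGTTAGTCGACGAGTGTTCTCG
CGAGATTGGGACAAAGGCTATGCGTACCCGTGTAAGACAACTCACTTGCGAGCGATGAAT
CCCAGATCAATGTGCTATACACCCGCCGAGAAGAGGTGCCCCTTGCATCGGCCAACGCCA
TTGGGACCACCAGCGAGTGGCAATGGTGCTCAAGCGTCGGCACAGCGTTATACTGCCTCA
AGTCTCGCTATGCTCGGCTCCCCGATAAAAGCCTTGGGAACACTGAGGTCCAGTATCCGC
TCATCAGGAGGTTTTTGTTAA
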