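>A_pothieri_like_01|A_pothieri_like|ITS2-like
ATACGACCTCTACGTATGTACATGTATTC------CCACTGGTCTGGGGATTCCAATCAGAAAAACAGCA
AACAGCCCGTGAGACATTTCGTATAGAGTACCGAGAATTAGAACCGCTGCTATAGGCGACTCTACCGCAC
AGGTAAACCATTCTGTCCATTGGATATACGAGCTAGCCTTACGCATGCGAGTATTAATTCATTAGCTTTT
TACTATTCGCAAGCCAACCGACAATATTCAGATACGTGGTAAACGCTTTTTACTCCTACGGAGTATTTGT
GTTCCGACCATCCCACGTTGGGCGATCTGTACTACTAATCGGCAGCTGGATACAGATGTCCTCTCTAGCC
GGACCCCCTGGACTTTTATATTACCAGCCTCCGATAGTGCAGCCTTTTCTTGGAGCCGTACGTGTGGAGA
GGACCCTCGGCACCAACACAGAGTGGGCTCTTACAAGCAATCCTGAATATTAAGTGATTATACTACCCTT
ACCGCCTGTATCCGTGATGGGATGCGTAGG
>A_pothieri_like_02|A_pothieri_like|ITS2-like
ATACGACCTCTACGTATGTACATGTATTC------CCACTGGTCTGGGGATTCCAATCAGAAAAACAGCA
AACAGCCCGTGAGACATTTCGTATAGAGTACCGAGAATTAGAACCGCTGCTATAGGCGACTCTACCGCAC
AGGTAAACCATTCTGTCCATTGGATATACGAGCTAGCCTTACGCATGCGAGTATTAATTCATTAGCTTTT
TACTATTCGCAAGCCAACCGACAATATTCAGATACGTGGTAAACGCTTTTTACTCCTACGGAGTATTTGT
GTTCCGACCATCCCACGTTGGGCGATCTGTACTACTAATCGGCAGCTGGATACAGATGTCCTCTCTAGCC
GGACCCCCTGGACTTTTATATTACCAGCCTCCGATAGTGCAGCCTTTTCTTGGAGCCGTACGTGTGGAGA
GGACCCTCGGCACCAACACAGAGTGGGCTCTTACAAGCAATCCTGAATATTAAGTGATTATACTACCCTT
ACCGCCTGTATCCGTGATGGGATGCGTAGG
>A_pothieri_like_03|A_pothieri_like|ITS2-like
ATACGACCTCTACGTATGTACATGTATTC------CCACTGGTCTGGGGATTCCAATCAGAAAAACAGCA
AACAGCCCGTGAGACATTTCGTATAGAGTACCGAGAATTAGAACCGCTGCTATAGGCGACTCTACCGCAC
AGGTAAACCATTCTGTCCATTGGATATACGAGCTAGCCTTACGCATGCGAGTATTAATTCATTAGCTTTT
TACTATTCGCAAGCCAACCGACAATATTCAGATACGTGGTAAACGCTTTTTACTCCTACGGAGTATTTGT
GTTCCGACCATCCCACGTTGGGCGATCTGTACTACTAATCGGCAGCTGGATACAGATGTCCTCTCTAGCC
GGACCCCCTGGACTTTTATATTACCAGCCTCCGATAGTGCAGCCTTTTCTTGGAGCCGTACGTGTGGAGA
GGACCCTCGGCACCAACACAGAGTGGGCTCTTACAAGCAATCCTGAATATTAAGTGATTATACTACCCTT
ACCGCCTGTATCCGTGATGGGATGCGTAGG
>A_pierrei_like_01|A_pierrei_like|ITS2-like
ATACGACCTCTACGTATGTACATGTATTCGCCATACCACTGGTCTGGGGATTCCAATTAGAAAAACAGCA
AACAGCCCGTGAGACATTTCGTATAGAGTACCGAGAATTAGAACCGCTGCTATAGGCGATTCTACCGCAC
AGGTAAACCATTCTGTCCATTGGATAGACGAGCTAGCCTTACGCATGCGAGTATTAATTCATTAGATATT
TACTATTCGCAAGCCAACCGAAAATATTCAGATACGTGGTAAACGCTTTTTACTCCTACGGAGTATTTGT
GTTCCGACGATACCACGTCGGGCGATCTGTACTACTAATGGGCAGCTAGATACAGATGTCCTCTCTAGCC
GGACCTACTGGACATTTATATTACAAGCCTCCGATAGTGCAGCCTTTTCTTGGAGCCGTACGTGTGGAGT
GGACCCTAGGCACCAACACAGAGTGGGCTCTTACAAGCAATCCTGACTATTAAGTGATTATACTACCCTT
ACCGTCTGTATCCTTGATGGGGTGCGTAGG
>A_pierrei_like_02|A_pierrei_like|ITS2-like
ATACGACCTCTACGTATGTACATGTATTCGCCATACCACTGGTCTGGGGATTCCAATTAGAAAAACAGCA
AACAGCCCGTGAGACATTTCGTATAGAGTACCGAGAATTAGAACCGCTGCTATAGGCGATTCTACCGCAC
AGGTAAACCATTCTGTCCATTGGATAGACGAGCTAGCCTTACGCATGCGAGTATTAATTCATTAGATATT
TACTATTCGCAAGCCAACCGAAAATATTCAGATACGTGGTAAACGCTTTTTACTCCTACGGAGTATTTGT
GTTCCGACGATACCACGTCGGGCGATCTGTACTACTAATGGGCAGCTAGATACAGATGTCCTCTCTAGCC
GGACCTACTGGACATTTATATTACAAGCCTCCGATAGTGCAGCCTTTTCTTGGAGCCGTACGTGTGGAGT
GGACCCTAGGCACCAACACAGAGTGGGCTCTTACAAGCAATCCTGACTATTAAGTGATTATACTACCCTT
ACCGTCTGTATCCTTGATGGGGTGCGTAGG
>A_pierrei_like_03|A_pierrei_like|ITS2-like
ATACGACCTCTACGTATGTACATGTATTCGCCATACCACTGGTCTGGGGATTCCAATTAGAAAAACAGCA
AACAGCCCGTGAGACATTTCGTATAGAGTACCGAGAATTAGAACCGCTGCTATAGGCGATTCTACCGCAC
AGGTAAACCATTCTGTCCATTGGATAGACGAGCTAGCCTTACGCATGCGAGTATTAATTCATTAGATATT
TACTATTCGCAAGCCAACCGAAAATATTCAGATACGTGGTAAACGCTTTTTACTCCTACGGAGTATTTGT
GTTCCGACGATACCACGTCGGGCGATCTGTACTACTAATGGGCAGCTAGATACAGATGTCCTCTCTAGCC
GGACCTACTGGACATTTATATTACAAGCCTCCGATAGTGCAGCCTTTTCTTGGAGCCGTACGTGTGGAGT
GGACCCTAGGCACCAACACAGAGTGGGCTCTTACAAGCAATCCTGACTATTAAGTGATTATACTACCCTT
ACCGTCTGTATCCTTGATGGGGTGCGTAGG
>A_tagala_like_01|A_tagala_like|ITS2-like
ATACGACCTCTACGTATGTACATGTATTCGCCATACCACTGGTCTGGGGATTCCAATTAGAAAAACAGCA
AACAGCCCGTGAGACATTTCGTATAGAGTACCGAGAATTAGAACCGCTGCTATAGGCGACTCTACCGCAC
AGGTAAACCATTCTGTCCCTTGGATAGACGAGCTAGCCTTACGCATGCGAGTATTAATTCATTAGCTATT
TCAGGTTCGCAAGCCAACCGAAAATATTCAGATACGTGGTGAACGCTTTTTACTCCTACCGAGTATTTGT
GTTCCGACCATACCACGTCGGGCGATCTGTACTACTAATGGGCAGCTAGAAACAGATGTCCTCTCTAGCC
GGACCTACTGGACTTTTATATTACCAGCCTCCGATAGTGCAGCCTTTTCTTGGAGCCGCACGTGTGGAGA
GGACCCTCGGCCCCAACACAGAGTGGGCTCTTACAAGCAATCCTGACTATTAAGTGATTATACTACCCTT
ACCGCCTGTATCCTTGATGGGATGCGTAGG
>A_tagala_like_02|A_tagala_like|ITS2-like
ATACGACCTCTACGTATGTACATGTATTCGCCATACCACTGGTCTGGGGATTCCAATTAGAAAAACAGCA
AACAGCCCGTGAGACATTTCGTATAGAGTACCGAGAATTAGAACCGCTGCTATAGGCGACTCTACCGCAC
AGGTAAACCATTCTGTCCCTTGGATAGACGAGCTAGCCTTACGCATGCGAGTATTAATTCATTAGCTATT
TCAGGTTCGCAAGCCAACCGAAAATATTCAGATACGTGGTGAACGCTTTTTACTCCTACCGAGTATTTGT
GTTCCGACCATACCACGTCGGGCGATCTGTACTACTAATGGGCAGCTAGAAACAGATGTCCTCTCTAGCC
GGACCTACTGGACTTTTATATTACCAGCCTCCGATAGTGCAGCCTTTTCTTGGAGCCGCACGTGTGGAGA
GGACCCTCGGCCCCAACACAGAGTGGGCTCTTACAAGCAATCCTGACTATTAAGTGATTATACTACCCTT
ACCGCCTGTATCCTTGATGGGATGCGTAGG
>A_tagala_like_03|A_tagala_like|ITS2-like
ATACGACCTCTACGTATGTACATGTATTCGCCATACCACTGGTCTGGGGATTCCAATTAGAAAAACAGCA
AACAGCCCGTGAGACATTTCGTATAGAGTACCGAGAATTAGAACCGCTGCTATAGGCGACTCTACCGCAC
AGGTAAACCATTCTGTCCCTTGGATAGACGAGCTAGCCTTACGCATGCGAGTATTAATTCATTAGCTATT
TCAGGTTCGCAAGCCAACCGAAAATATTCAGATACGTGGTGAACGCTTTTTACTCCTACCGAGTATTTGT
GTTCCGACCATACCACGTCGGGCGATCTGTACTACTAATGGGCAGCTAGAAACAGATGTCCTCTCTAGCC
GGACCTACTGGACTTTTATATTACCAGCCTCCGATAGTGCAGCCTTTTCTTGGAGCCGCACGTGTGGAGA
GGACCCTCGGCCCCAACACAGAGTGGGCTCTTACAAGCAATCCTGACTATTAAGTGATTATACTACCCTT
ACCGCCTGTATCCTTGATGGGATGCGTAGG
>substitute_sp_01|substitute_sp|ITS2-like
ATACGACCTCTACGTATGTACATGTATTCGCCATACCACTGGTCTGGGGATTCCAATCAGAAAAACAGCA
AACAGCCCGTGAGACATTTCGTATAGAGTACCGAGAATTAGAACCGCTGCTATAGGCGATTCTACCGCAC
AGGTAAACCATTCTGTCCCTTGGATATACGAGCTAGCCTTACGCATGCGAGTATTAATTCATTAGATTTT
TACTATTCGCAAGCCAACCGACAATATTCAGATACGTGGTGAACGCTTTTTACTCCTACCGAGTATTTGT
GTTCCGACCATCCCACGTTGGGCGATCTGTACTACTAATCGGCAGCTGGAAACAGATGTCCTCTCTAGCC
GGACCTACTGGACATTTATATTACAAGCCTCCGATAGTGCAGCCTTTTCTTGGAGCCGCACGTGTGGAGT
GGACCCTAGGCCCCAACACAGAGTGGGCTCTTACAAGCAATCCTGAATATTAAGTGATTATACTACCCTT
ACCGTCTGTATCCGTGATGGGGTGCGTAGG
>substitute_sp_02|substitute_sp|ITS2-like
ATACGACCTCTACGTATGTACATGTATTCGCCATACCACTGGTCTGGGGATTCCAATCAGAAAAACAGCA
AACAGCCCGTGAGACATTTCGTATAGAGTACCGAGAATTAGAACCGCTGCTATAGGCGATTCTACCGCAC
AGGTAAACCATTCTGTCCCTTGGATATACGAGCTAGCCTTACGCATGCGAGTATTAATTCATTAGATTTT
TACTATTCGCAAGCCAACCGACAATATTCAGATACGTGGTGAACGCTTTTTACTCCTACCGAGTATTTGT
GTTCCGACCATCCCACGTTGGGCGATCTGTACTACTAATCGGCAGCTGGAAACAGATGTCCTCTCTAGCC
GGACCTACTGGACATTTATATTACAAGCCTCCGATAGTGCAGCCTTTTCTTGGAGCCGCACGTGTGGAGT
GGACCCTAGGCCCCAACACAGAGTGGGCTCTTACAAGCAATCCTGAATATTAAGTGATTATACTACCCTT
ACCGTCTGTATCCGTGATGGGGTGCGTAGG
>substitute_sp_03|substitute_sp|ITS2-like
ATACGACCTCTACGTATGTACATGTATTCGCCATACCACTGGTCTGGGGATTCCAATCAGAAAAACAGCA
AACAGCCCGTGAGACATTTCGTATAGAGTACCGAGAATTAGAACCGCTGCTATAGGCGATTCTACCGCAC
AGGTAAACCATTCTGTCCCTTGGATATACGAGCTAGCCTTACGCATGCGAGTATTAATTCATTAGATTTT
TACTATTCGCAAGCCAACCGACAATATTCAGATACGTGGTGAACGCTTTTTACTCCTACCGAGTATTTGT
GTTCCGACCATCCCACGTTGGGCGATCTGTACTACTAATCGGCAGCTGGAAACAGATGTCCTCTCTAGCC
GGACCTACTGGACATTTATATTACAAGCCTCCGATAGTGCAGCCTTTTCTTGGAGCCGCACGTGTGGAGT
GGACCCTAGGCCCCAACACAGAGTGGGCTCTTACAAGCAATCCTGAATATTAAGTGATTATACTACCCTT
ACCGTCTGTATCCGTGATGGGGTGCGTAGG
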