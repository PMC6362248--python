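name: tss1_demo_synthetic
sequence: GCATCGATGAGTCCTCATCATTATATAAAAATCGAAGCTTTTTCCGGTTGGAACCGCAGTTGGTATGATTCACGGAGAGCTGGCTACCACTAACCGGACCTCTCAGTCTTAGCCCCTACACGCGAGTGGTTAGCGTTACGACGGACGGACATCATCTAACGCAAAGTCGTCGGTACCATTGAGCATGGGCATTCGCCCTACCGTTTGTATACTTCTACGTCGACTATAACGGTCACCCGGATGCAATAAATCAATATGAAGTAGCGGGGGCTGTTTAAATTCGGCCATATGATACTTGAGTTTACCATCAGAAAAATCATGTATCCCGGCCACGCGATCCAAATCTTTCCAAAGAGATCAGACTATAGTTCCGCTTGGCTCACCTCGTCCCCATCAAAATATAGGGCGCACTCGCTAAGTAGCATATTCTATCTTTCGAGGTGCGTTTCGTCTTCTTCCATGTATAATACCGGCCAACGCAGTAGGCATCCTCCAGTTTCGCAAGCTGTTAGTTCTCTCGGGGTACACATCAGACCCGCCAAGGGATGTAAGTGCCCAGCTACAGGTTATGGCAATGCTGGCTGGTCCTGTGGCTGCTGCAATGTTTCACAGAAATACCCGTGTAGCTGCACACGGACGAGCTTGTGGGAATGTTCGCCAGGTGTAGACTTACAACGATGCAAGTCCTTAACCATTGGCAGGGCACTGTTAATGCTGATCAACTACGTGCCAACTAAAAGTGGGGTGTGTCCTGCCGTATGCTTCCCACAACTCCATTCCTCTGCCAACGTTCAGTCACCAATAGTCGGAAAGTTTTGCACTGAAGAGCTACAAGAACCGAGTACAAGGTATAGGGAGGTATTGACCAGTCCGAAGCAATACCTCAACTGGTGCGACTTGGTCGCAAGGATGTGCGTCATCCGCAATACGTACATCAAACTAAAGACCTCCGTGAAAGAGTCGAAACAAGCGCTGCTGTGGTGTGCCTCCGGGAGCTCCATAATCCATAGACGTCTATTCCAAAAAAGATATGTCATTGAGTCGCGAGTGTGCAGTTGTGCACTGATCATGTGGAGTCTCCCCCTCGATGCGCGAGATTATGCGGTGGTATATCGAGGTATCACTAGATGTGGTGGAGTCAAGGCAGACCTATGTATTGAAAGGCGATACAATACCCATTTTTCATACGGTCTTGAAGGATGGACGGTCCACTGTTCTCATTTTTCCAGGCCGTCCTCCAAACGCTGCCTTCCGGCCGGCGGTTCCGGGTGCGTCGCGAGTGAGAGGGACGGACCGAGCTCCGTCCATTGGCTCCCGGGTGTCCTCGACAGCCCTAGACGCCACTGTCCTGCGAAGGCTGCATGGGGCCTGCTTGAGAGTTCTCAAGGAAGTACATCACATATTCGAGCAAATAGTCGACGTAAAAGTATACAAACGGTAGGGCGAATGCCCATGCCCAATGGTACCGACGACTTTGCGTTAGATGATGTCCGTCCGTCGTAACGCTAACCATTCGCGTGTAGGGGCTAAGACTGAGAGGTCCGGTTAGTGATAGCCAGCTCTCCGTGAATCATACCAACTGCGGTGCCAACCGGAAAAAGCTTCGATTTTCATATAATGATGAGGACTCATCGATGC
features:
  left_itr:
    start: 0
    end: 227
  cds:
    start: 300
    end: 1322
    frame: 0
  right_itr:
    start: 1411
    end: 1638
binding_regions:
- itr: left_itr
  start: 2
  end: 30
- itr: left_itr
  start: 192
  end: 220
- itr: right_itr
  start: 1416
  end: 1444
- itr: right_itr
  start: 1600
  end: 1628
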