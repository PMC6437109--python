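# Default FCGR2/3 locus definition: five low-affinity Fc-gamma-receptor
# genes, three copy number regions, eight variant systems.
# The rare CNR4 is merged into the similar CNR1.
genes: [FCGR2A, FCGR3A, FCGR2C, FCGR3B, FCGR2B]
cnrs:
  - id: CNR1
    genes: [FCGR3B, FCGR2C]
    copy_range: [0, 4]
  - id: CNR2
    genes: [FCGR3A, FCGR2C]
    copy_range: [1, 4]
  - id: CNR3
    genes: [FCGR3A, FCGR2C]
    copy_range: [1, 3]
variants:
  - id: FCGR2A_H131R
    gene: FCGR2A
    alleles: [H, R]
  - id: FCGR2A_Q27W
    gene: FCGR2A
    alleles: [Q, W]
  - id: FCGR3A_V158F
    gene: FCGR3A
    alleles: [V, F]
  - id: FCGR2C
    gene: FCGR2C
    alleles: [ORF, Stop, NC-ORF]
  - id: FCGR2C_prom
    gene: FCGR2C
    alleles: ["2B.1", "2B.2", "2B.4"]
  - id: FCGR3B_NA
    gene: FCGR3B
    alleles: [NA1, NA2, SH]
  - id: FCGR2B_prom
    gene: FCGR2B
    alleles: ["2B.1", "2B.2", "2B.4"]
  - id: FCGR2B_I232T
    gene: FCGR2B
    alleles: [I, T]
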