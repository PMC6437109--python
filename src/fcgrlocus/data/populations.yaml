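# Default population parameters for the synthetic-data generator.
#
# marginals: copy-number-aware allele frequencies of the eight variant
#   systems in European / Chinese / African reference cohorts (healthy
#   controls; the Chinese classic-ORF value uses the observed 2/856 count
#   behind the rounded published 0.00).  Three-allele systems whose rounded
#   published frequencies summed to 0.99 are renormalised here.
# cnr_chrom_freqs: per-CHROMOSOME copy distributions for each CNV region
#   (1 = no CNV), fitted so that the convolution of two chromosomes
#   reproduces the published per-individual copy-number distributions.
# ld_targets: pairwise r2 between the biallelic collapses (allele vs rest)
#   on the CNV-free background, positive-D orientation.
# dup_profiles: allele distribution of the EXTRA gene copy carried by a
#   duplicated chromosome; the nonclassic FCGR2C-ORF haplotype and (in
#   Europeans) FCGR3B-SH preferentially ride CNR1 duplications.
# stop_splice_fraction: fraction of FCGR2C-Stop copies that also carry the
#   intron-7 splice mutation (the Stop(2) sub-haplotype), visible only to
#   the MLPA caller.

EUR:
  marginals:
    FCGR2A_H131R: {H: 0.54, R: 0.46}
    FCGR2A_Q27W: {Q: 0.88, W: 0.12}
    FCGR3A_V158F: {V: 0.36, F: 0.64}
    FCGR2C: {Stop: 0.84, ORF: 0.11, NC-ORF: 0.05}
    FCGR2C_prom: {"2B.1": 0.89, "2B.2": 0.11, "2B.4": 0.0}
    FCGR3B_NA: {NA1: 0.355, NA2: 0.625, SH: 0.02}
    FCGR2B_prom: {"2B.1": 0.90, "2B.2": 0.0, "2B.4": 0.10}
    FCGR2B_I232T: {I: 0.88, T: 0.12}
  cnr_chrom_freqs:
    CNR1: {0: 0.036, 1: 0.913, 2: 0.051}
    CNR2: {0: 0.005, 1: 0.975, 2: 0.020}
    CNR3: {0: 0.0005, 1: 0.9985, 2: 0.0010}
  ld_targets:
    - [FCGR2C, ORF, FCGR2C_prom, "2B.2", 0.92]
    - [FCGR2C, ORF, FCGR2A_Q27W, W, 0.63]
    - [FCGR2C, ORF, FCGR2B_prom, "2B.4", 0.40]
    - [FCGR2C, ORF, FCGR3A_V158F, V, 0.24]
    - [FCGR2C, ORF, FCGR2A_H131R, H, 0.08]
    - [FCGR3A_V158F, V, FCGR2A_H131R, H, 0.06]
  dup_profiles:
    CNR1:
      FCGR2C: {Stop: 0.45, ORF: 0.05, NC-ORF: 0.50}
      FCGR2C_prom: {"2B.1": 1.0}
      FCGR3B_NA: {NA1: 0.25, NA2: 0.45, SH: 0.30}
    CNR2:
      FCGR2C: {Stop: 1.0}
      FCGR2C_prom: {"2B.1": 1.0}
      FCGR3A_V158F: {V: 0.36, F: 0.64}
    CNR3:
      FCGR2C: {Stop: 1.0}
      FCGR2C_prom: {"2B.1": 1.0}
      FCGR3A_V158F: {V: 0.36, F: 0.64}
  stop_splice_fraction: 0.02

CHN:
  marginals:
    FCGR2A_H131R: {H: 0.67, R: 0.33}
    FCGR2A_Q27W: {Q: 1.0, W: 0.0}
    FCGR3A_V158F: {V: 0.36, F: 0.64}
    FCGR2C: {Stop: 0.9977, ORF: 0.0023, NC-ORF: 0.0}
    FCGR2C_prom: {"2B.1": 0.9977, "2B.2": 0.0023, "2B.4": 0.0}
    FCGR3B_NA: {NA1: 0.62, NA2: 0.38, SH: 0.0}
    FCGR2B_prom: {"2B.1": 1.0, "2B.2": 0.0, "2B.4": 0.0}
    FCGR2B_I232T: {I: 0.74, T: 0.26}
  cnr_chrom_freqs:
    CNR1: {0: 0.046, 1: 0.859, 2: 0.095}
    CNR2: {0: 0.005, 1: 0.977, 2: 0.018}
    CNR3: {0: 0.0, 1: 0.990, 2: 0.010}
  ld_targets:
    - [FCGR3A_V158F, F, FCGR2A_H131R, H, 0.04]
  dup_profiles:
    CNR1:
      FCGR2C: {Stop: 1.0}
      FCGR2C_prom: {"2B.1": 1.0}
      FCGR3B_NA: {NA1: 0.62, NA2: 0.38}
    CNR2:
      FCGR2C: {Stop: 1.0}
      FCGR2C_prom: {"2B.1": 1.0}
      FCGR3A_V158F: {V: 0.36, F: 0.64}
    CNR3:
      FCGR2C: {Stop: 1.0}
      FCGR2C_prom: {"2B.1": 1.0}
      FCGR3A_V158F: {V: 0.36, F: 0.64}
  stop_splice_fraction: 0.0

AFR:
  marginals:
    FCGR2A_H131R: {H: 0.44, R: 0.56}
    FCGR2A_Q27W: {Q: 0.89, W: 0.11}
    FCGR3A_V158F: {V: 0.36, F: 0.64}
    FCGR2C: {Stop: 0.90, ORF: 0.02, NC-ORF: 0.08}
    FCGR2C_prom: {"2B.1": 0.95, "2B.2": 0.05, "2B.4": 0.0}
    FCGR3B_NA: {NA1: 0.385, NA2: 0.465, SH: 0.15}
    FCGR2B_prom: {"2B.1": 0.99, "2B.2": 0.0, "2B.4": 0.01}
    FCGR2B_I232T: {I: 0.73, T: 0.27}
  cnr_chrom_freqs:
    CNR1: {0: 0.057, 1: 0.865, 2: 0.078}
    CNR2: {0: 0.005, 1: 0.977, 2: 0.018}
    CNR3: {0: 0.0005, 1: 0.9995, 2: 0.0}
  ld_targets:
    - [FCGR2C, ORF, FCGR2A_Q27W, W, 0.17]
    - [FCGR3A_V158F, V, FCGR2A_H131R, H, 0.06]
  dup_profiles:
    CNR1:
      FCGR2C: {Stop: 0.50, NC-ORF: 0.50}
      FCGR2C_prom: {"2B.1": 1.0}
      FCGR3B_NA: {NA1: 0.30, NA2: 0.55, SH: 0.15}
    CNR2:
      FCGR2C: {Stop: 1.0}
      FCGR2C_prom: {"2B.1": 1.0}
      FCGR3A_V158F: {V: 0.36, F: 0.64}
    CNR3:
      FCGR2C: {Stop: 1.0}
      FCGR2C_prom: {"2B.1": 1.0}
      FCGR3A_V158F: {V: 0.36, F: 0.64}
  stop_splice_fraction: 0.02
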