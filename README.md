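# fcgrlocus

Copy-number-aware genetic analysis of the human **FCGR2/3 locus** — the
low-affinity Fc-gamma-receptor gene cluster at 1q23.3 (*FCGR2A, FCGR3A,
FCGR2C, FCGR3B, FCGR2B*).  The locus sits in a segmental duplication with
three copy number regions (CNRs) that delete or duplicate whole blocks of
genes, which breaks most standard genotyping and association tooling:
allele counts per individual range from 0 to 4, r²/D′ are undefined across
copy-number changes, and paralogous sequences (the *FCGR2B*/*FCGR2C*
promoters, the *FCGR2C* pseudogene haplotypes) can only be resolved by
dosage arithmetic.

The package is for statistical geneticists and immunogenetics labs who work
with MLPA-style dosage data at this locus (or want to simulate it).  It
provides:

* **`locus_model`** — genes, CNRs and eight variant systems; chromosome-level
  haplotypes (copy configuration + per-copy alleles) and unphased genotypes
  linked by the dosage-sum invariant
  `sum of allele dosages = 2 + Σ_CNRs (copies − 2)`.
* **`synthetic_data`** — haplotype pools matching requested allele
  frequencies and pairwise r² targets (iterative proportional fitting),
  with CNV chromosomes attached to realistic allele backgrounds; samplers
  for cohorts, case-control studies under an additive logistic disease
  model, affected-child trios, and noisy MLPA probe-ratio tables.
  European, Chinese and African defaults ship as a packaged config.
* **`mlpa_caller`** — probe ratios → copy-number calls
  (`round(2·median)`, no-call margin), *FCGR2C* Stop / classic-ORF /
  nonclassic-ORF resolution from the Q57X and intron-7 splice dosages
  (maximum posterior under population priors when ambiguous), 2B.2/2B.4
  promoter allocation between *FCGR2B* and *FCGR2C*, and exact
  misclassification rates by diplotype enumeration.
* **`popgen`** — allele frequencies with gene-copy denominators, EM
  haplotype-frequency estimation from unphased CNV-free genotypes, r²/D′
  with allele-vs-rest collapse, CNV-stratified Fisher exact tests
  (exact r×2 enumeration, seeded Monte-Carlo for larger tables).
* **`association`** — Fisher exact tests on genotype tables, additive
  logistic regression (per-copy OR, Wald CI), multiple logistic regression
  with collinearity dropping, backward selection.
* **`family_tdt`** — Mendelian phasing of trios into chromosome-level
  haplotypes across CNV, and the allele-wise transmission disequilibrium
  test `Z = (T−U)/√(T+U)` with the >10-informative-families filter.
* **`meta`** — fixed-effect inverse-variance pooling of a case-control
  log OR with a TDT effect (`log OR = ln(T/U)`, `SE = √(1/T+1/U)`).

A thin CLI (`fcgr-locus simulate|call|freq|ld|assoc|tdt|meta`) chains the
stages on TSV files.

## Worked example

```python
import numpy as np
import fcgrlocus as F
from fcgrlocus import association as A, popgen as P

pool = F.default_pool("EUR")                       # European defaults
model = F.DiseaseModel(log_or={("FCGR2C", "ORF"): np.log(1.46)})
cases, controls = F.sample_case_control(pool, model, 405, 919, seed=1)

fr = P.allele_frequency(cases, "FCGR2C")
print(f"ORF frequency in cases: {fr.frequencies['ORF']:.3f} "
      f"({fr.count('ORF')}/{fr.denominator} alleles)")

dose = np.r_[A.dose_vector(cases, "FCGR2C", "ORF"),
             A.dose_vector(controls, "FCGR2C", "ORF")]
status = np.r_[np.ones(len(cases)), np.zeros(len(controls))]
res = A.additive_logistic(dose, status, variant="FCGR2C:ORF")
print(f"additive OR {res.odds_ratio:.2f} "
      f"({res.ci_low:.2f}-{res.ci_high:.2f}), p = {res.p_value:.4f}")
```

Output from this exact snippet:

```
ORF frequency in cases: 0.146 (122/838 alleles)
additive OR 1.67 (1.30-2.15), p = 0.0001
```

The frequency denominator is 838, not 810 = 2×405: the sampled cases carry
CNVs, and individuals contribute one allele per *FCGR2C* gene copy.  The
recovered per-copy odds ratio (1.67, CI 1.30–2.15) is consistent with the
injected 1.46 at this sample size (the CI covers it).

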