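# Methods

## The locus and its representation

The FCGR2/3 cluster is modelled abstractly as five genes, three copy
number regions (CNRs) and eight variant systems; physical coordinates play
no role.  CNR1 contains *FCGR3B*+*FCGR2C*; CNR2 and CNR3 each contain
*FCGR3A*+*FCGR2C* (a rare fourth region described for this locus is merged
into the similar CNR1).  A parental chromosome carries 0, 1 or 2 copies of
each CNR (1 = no CNV; per-chromosome copies are capped at 2, consistent
with the maximum per-individual total of 4 ever observed), and one allele
of every variant system per gene copy.  The central invariant linking the
chromosome and genotype levels is the dosage-sum rule: for every variant,
the allele dosages of an individual sum to the gene copy number
`2 + Σ over CNRs containing the gene of (CNR copies − 2)`.

Variant systems: *FCGR2A* H131R and Q27W; *FCGR3A* V158F; the *FCGR2C*
haplotype system (Stop pseudogene / classic ORF, expressed / nonclassic
ORF, silenced by an intron-7 splice mutation); the *FCGR2B*/*FCGR2C*
promoter haplotypes 2B.1/2B.2/2B.4; *FCGR3B* NA1/NA2/SH; *FCGR2B* I232T.
The two *FCGR2C*-Stop sub-haplotypes (with and without the splice
mutation) behave identically and are collapsed to "Stop" everywhere except
inside the MLPA caller, which needs the distinction to enumerate dosage
interpretations.

## Synthetic-data generator

The generator defines the study conditions for every downstream test.

**Allele background.** The joint allele distribution of a no-CNV
chromosome over all eight systems (a 576-cell array) is fitted by
iterative proportional fitting: one marginal constraint per system plus a
2×2 block constraint per pairwise r² target (allele-vs-rest collapse,
positive-D orientation, target haplotype frequency from the closed form
`D = √(r² pA qA pB qB)`).  Iteration cap 1000 sweeps; tolerance 1e-4 on
each attained r² and 1e-7 on marginals; higher-order LD is whatever IPF
yields, since only pairwise LD is specified.  Infeasible targets (above
the Lewontin maximum for the given marginals) raise an error reporting the
feasible maximum; the packaged defaults instead pin such pairs at the
D′=1 boundary, because two published r² values (0.24 for classic
ORF–158V in Europeans, 0.17 for ORF–27W in Africans) sit marginally above
that maximum at the published rounded allele frequencies.

**CNV chromosomes.** Each chromosome belongs to one class: no-CNV, or a
single deleted/duplicated CNR (co-occurrence of two aberrant CNRs on one
chromosome, of order 10⁻³ in frequency, is neglected).  Chromosome-level
class frequencies are fitted so that the two-chromosome convolution
reproduces the published per-individual copy-number distributions (e.g.
European CNR1: 0.036 deleted / 0.913 normal / 0.051 duplicated per
chromosome).  The extra gene copy of a duplicated chromosome draws its
alleles from a configurable profile; the European default places the
nonclassic *FCGR2C*-ORF (probability 0.5) and *FCGR3B*-SH (0.3) on
duplicated CNR1 chromosomes, reproducing the published strong association
between increased CNR1 copy number and those alleles.  Base-copy
frequencies are corrected analytically so the copy-number-aware marginals
of the finished pool equal the requested values; LD targets are defined on
the CNV-free background, matching how background LD is estimated.

**Populations.** European, Chinese and African parameter sets ship in
`data/populations.yaml`.  Three-allele systems whose published rounded
frequencies sum to 0.99 are renormalised; the Chinese classic-ORF
frequency uses the underlying 2/856 count instead of the rounded 0.00.

**Sampling.** Individuals are two independent pool draws.  Case-control
sampling assigns case status with probability
`expit(logit(prevalence) + Σ dose·logOR)` and rejects until the quotas
fill (error after a configurable draw budget).  The default prevalence is
0.1 — under case-control ascertainment the recovered odds ratio does not
depend on this value, and a higher prevalence keeps rejection sampling
cheap.  Trios draw four parental chromosomes, transmit one uniformly
chosen chromosome per parent, and retain the family with probability equal
to the child's disease probability (single affected child, no sibships);
under a null model the ascertainment step is skipped, which leaves the
transmission distribution unchanged.

**MLPA simulation.** Probe ratios are `dosage/2 + N(0, σ)`; σ defaults to
0.05 (typical for normalized MLPA ratios).  Two replicate probes per
target are emitted, mirroring the redundancy of the real assay.  The probe
set carries exactly the information content of the real one: CNR reference
probes, allele-specific probes for the SNP systems, an ORF-site probe
(counting open-reading-frame copies at the Q57X position: classic plus
nonclassic ORF), a splice-mutation probe, and combined promoter probes
that cannot distinguish the sequence-identical *FCGR2B* and *FCGR2C*
promoters.

**What the generator does not emulate.** No recombination (the locus is
one non-recombining block, consistent with the strong observed LD), no
genotyping batch effects or probe-specific biases, no population
substructure within a population label, no missing data.  Tests passing on
this generator therefore validate the statistical machinery, not
robustness to assay artefacts.

## MLPA interpretation

Copy number is `round(2 × median ratio)` with a no-call margin of 0.2 copy
units (a margin larger than ~3σ of a two-probe median at the default
noise).  *FCGR2C* is resolved by enumerating, for the observed copy
number, ORF-site dosage and splice dosage, every multiset of the four
internal per-copy states; a unique solution is returned with posterior 1,
otherwise the maximum-posterior configuration under multinomial population
priors is returned, flagged, with ties broken toward more Stop copies (the
majority haplotype).  The default priors put 2% of Stop copies on the
splice-mutated background.  Promoter dosage is allocated 2B.2 → *FCGR2C*
and 2B.4 → *FCGR2B* (the genes where these haplotypes essentially always
reside), remainder 2B.1; overflow spills to the other gene and is flagged.
Misclassification rates of both rules are exact expectations over all
ordered diplotype pairs of a chromosome pool, cross-checked against a
Monte-Carlo twin.  Raw peak normalization is out of scope; the caller
consumes normalized ratios.

## Population statistics

Allele frequencies use gene-copy denominators (an individual contributes
as many alleles as gene copies), which is the only way the published
case-control frequencies are reproducible.  Haplotype frequencies come
from standard EM over unphased multilocus genotypes, restricted to
individuals with two copies of every involved gene; initialization is the
product of marginals with a deterministic 1e-3 sine-pattern jitter (the
unjittered product is a stationary saddle for perfectly symmetric data
such as all-double-heterozygote sets), at least five sweeps, stopping at
relative log-likelihood change < 1e-8 or 1000 iterations.  A single start
is used; the likelihood is effectively unimodal at these allele
frequencies, and the test suite checks EM against direct simplex
maximisation on small instances.  LD is reported after biallelic
allele-vs-rest collapse (full multiallelic D′ is out of scope):
`D = pAB − pA pB`, `r² = D²/(pA qA pB qB)`, `D′ = |D|/Dmax`, with a
1-df chi-square p-value from `n·r²` when the chromosome count is given.

Because r²/D′ are undefined across copy-number changes, LD between a CNR
and a variant is assessed by comparing copy-number-aware allele counts
between copy-number strata (≤1 / 2 / ≥3 copies) with Fisher's exact test.
The r×c exact test enumerates all tables with the observed margins for
two-column tables (up to ~5×10⁶ compositions) and small r×c tables, and
otherwise uses a seeded Monte-Carlo approximation (10⁶ Patefield draws,
p = (1+hits)/(1+draws)); the method used is recorded in the result.  The
exact path is verified in the tests against an independent implementation
of the same test.

## Association and family-based analysis

Case status is regressed on per-individual allele copy count; individuals
with more than two gene copies contribute dose 3 as its own level (no
capping).  Odds ratios are `exp(β)` with Wald 95% CIs on the log-odds
scale, matching the symmetric-in-log published intervals.  CNR association
uses two indicator contrasts (<2 vs rest, >2 vs rest) as separate fits.
Joint models drop columns with pairwise dose correlation > 0.95 (recorded),
as near-perfect LD proxies cannot be jointly estimated; backward selection
removes the highest-p variant until all remaining p < α = 0.05,
deterministically in column order.

Trios are phased by enumerating the child's decompositions into two
chromosomes and subtracting each candidate from the respective parent.
Several surviving combinations are resolved by maximum prior probability
(product of population frequencies of the four parental chromosomes,
absent chromosomes floored at 1e-6; without priors, a parsimony prior
penalises CNV chromosomes).  A trio is flagged ambiguous when the chosen
transmission pattern's prior-weighted posterior falls below 0.95, where
solutions are first aggregated by their transmission signature — the
unordered multiset of per-parent (transmitted, untransmitted) chromosome
pairs — because solutions differing only in which parent is which
contribute identically to the TDT.  A strict several-solutions flag would
fire on essentially every trio: any diploid CNR total of 2 also admits a
negligible-prior deletion+duplication decomposition.  Even so, with eight
systems phased jointly a substantial minority of trios (bounded below 35%
in the property tests) remains genuinely ambiguous; unambiguous trios are
phased exactly, as verified against retained simulation truth.  Mendelian
inconsistencies yield flagged no-calls, and incomplete trios (a missing
parent) are excluded from the statistic — a deliberate simplification
relative to family-based methods that salvage partial information.

The TDT is the classic allele-wise normal approximation
`Z = (T−U)/√(T+U)` over parents heterozygous for the tested
chromosome-level label (each distinct label, e.g. `VF` or `Stop-Stop` or
the deletion `–`, is treated as an allele); results with ≤10 informative
families are suppressed.  The empirical-variance refinement used by some
family-based software is intentionally omitted; under the null the two
statistics coincide, and the test suite verifies the 5% type-I error
calibration directly.

## Meta-analysis

TDT counts convert to an odds-ratio effect via `log OR = ln(T/U)`,
`SE = √(1/T + 1/U)`; zero counts raise unless an optional 0.5 continuity
correction is enabled.  The case-control effect uses the logistic
coefficient and its SE (not a 2×2 cross-product estimate).  Fixed-effect
inverse-variance pooling only; Cochran's Q is available behind a flag for
diagnostics.

## Published values that do not reproduce from published counts

Three groups of published numbers cannot be recovered exactly from the
published genotype-category counts, and the acceptance tests compare
against the published values anyway, documenting the discrepancy:

* the case *FCGR3A*-158V frequency (308/834 = 36.9% vs published 37.0%)
  and the control 2B.4 frequency (185/1838 = 10.1% vs published 10.0%);
* the four genotype-table Fisher p-values, where exact computation (and an
  independent implementation of the same test) gives 0.045 / 0.562 /
  0.004 / 0.360 against published 0.047 / 0.559 / 0.005 / 0.359 —
  consistent with the published p-values having been computed on a
  marginally different dataset than the final printed counts;
* the published control *FCGR3B*-SH frequency is likewise inconsistent
  with its genotype rows (the "1 SH" counts appear incomplete), so
  *FCGR3B* frequencies are not used as reference checks.

## Problem sizes used by the test suite

Frequency/OR reproductions run on the printed 405+919 cohort counts
(deterministic).  Recovery checks use 2000-individual cohorts for EM/LD,
2000 null replicates of 150 trios for TDT calibration, 1000 replicates of
500+500 for logistic calibration, and a 900-individual + 300-trio seeded
dataset for the end-to-end pipeline — sizes at which binomial noise is
comfortably inside the stated tolerance bands.

## Known limitations

* Per-chromosome CNR copies are capped at 2; individuals with ≥5 total
  copies of a region cannot be represented.
* The promoter allocation rule is deterministic; its exact-expectation
  error rate is zero under the default pools (which never place 2B.2/2B.4
  on the "wrong" gene), so the published >95% allocation accuracy in real
  carriers is emulated only qualitatively.
* EM uses a single (jittered) start; pathological multimodal likelihoods
  would need multiple starts.
* The CNV-stratified test treats strata as independent samples of alleles;
  within-individual allele correlation is ignored, as in the original
  procedure.
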