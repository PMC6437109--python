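"""Family-based association: trio phasing over CNV chromosomes and the TDT.

Parent-offspring trios allow the two parental chromosomes of the locus to
be reconstructed, including their copy number configuration: every
decomposition of each member's unphased genotype into two chromosome-level
haplotypes is enumerated, and combinations in which the child's genotype
equals one chromosome from each parent are kept.  When several
combinations survive, the one with the highest prior probability (product
of population frequencies of the four parental chromosomes) is chosen and
the trio is flagged ambiguous; a combination-free trio is a Mendelian
inconsistency and yields a flagged no-call.

The transmission disequilibrium test is the classic allele-wise TDT: a
parent is informative for a chromosome-level allele label if exactly one
of its two chromosomes carries it; with T transmissions and U
non-transmissions from informative parents, ``Z = (T-U)/sqrt(T+U)`` with a
two-sided normal p-value.  Labels with at most ``min_informative``
informative families (default 10) are suppressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product as _iproduct
from typing import Sequence

from scipy import stats

from .locus_model import (
    ChromosomeHaplotype,
    HaplotypeFrequencyTable,
    IndividualGenotype,
    LocusDefinition,
    default_locus,
    haplotype_label,
)

__all__ = [
    "Trio",
    "TrioTruth",
    "PhasedTrio",
    "TDTResult",
    "decompose_genotype",
    "phase_trio",
    "phase_trios",
    "tdt",
    "tdt_all_labels",
]


@dataclass(frozen=True)
class TrioTruth:
    father_haplotypes: tuple[ChromosomeHaplotype, ChromosomeHaplotype]
    mother_haplotypes: tuple[ChromosomeHaplotype, ChromosomeHaplotype]
    transmitted: tuple[int, int]


@dataclass
class Trio:
    family_id: str
    father: IndividualGenotype | None
    mother: IndividualGenotype | None
    child: IndividualGenotype
    truth: TrioTruth | None = None

    @property
    def complete(self) -> bool:
        return self.father is not None and self.mother is not None


@dataclass
class PhasedTrio:
    family_id: str
    father_haplotypes: tuple[ChromosomeHaplotype, ChromosomeHaplotype] | None
    mother_haplotypes: tuple[ChromosomeHaplotype, ChromosomeHaplotype] | None
    transmitted: tuple[int, int] | None  # index into each parent's pair
    ambiguous: bool = False
    mendelian_error: bool = False
    n_solutions: int = 0
    posterior: float = 1.0  # prior-weighted share of the chosen solution

    @property
    def ok(self) -> bool:
        return not self.mendelian_error and self.transmitted is not None


@dataclass(frozen=True)
class TDTResult:
    variant_id: str
    label: str
    allele_frequency: float
    informative_families: int
    transmitted: int
    untransmitted: int
    z: float | None
    p_value: float | None
    suppressed: bool


# ---------------------------------------------------------------------------
# Genotype decomposition into chromosome pairs
# ---------------------------------------------------------------------------

def _multiset_splits(items: Sequence[str], k1: int):
    """Unique ways to split a multiset into an ordered pair of sub-multisets
    of sizes (k1, len-k1)."""
    items = sorted(items)
    n = len(items)
    seen = set()
    out = []
    for mask in range(1 << n):
        if bin(mask).count("1") != k1:
            continue
        left = tuple(items[i] for i in range(n) if mask >> i & 1)
        right = tuple(items[i] for i in range(n) if not mask >> i & 1)
        if (left, right) in seen:
            continue
        seen.add((left, right))
        out.append((left, right))
    return out


def decompose_genotype(
    genotype: IndividualGenotype, locus: LocusDefinition | None = None
) -> list[tuple[ChromosomeHaplotype, ChromosomeHaplotype]]:
    """All unordered decompositions of an unphased genotype into two
    chromosome-level haplotypes."""
    locus = locus or default_locus()
    cnr_options = []
    for cnr in locus.cnrs:
        total = genotype.cnr_copies.get(cnr.id, 2)
        opts = [
            (a, total - a)
            for a in range(max(0, total - 2), min(2, total) + 1)
        ]
        cnr_options.append((cnr.id, opts))

    results: set[tuple] = set()
    out: list[tuple[ChromosomeHaplotype, ChromosomeHaplotype]] = []
    for cnr_combo in _iproduct(*[opts for _, opts in cnr_options]):
        cnr1 = {cnr_options[i][0]: cnr_combo[i][0] for i in range(len(cnr_options))}
        cnr2 = {cnr_options[i][0]: cnr_combo[i][1] for i in range(len(cnr_options))}
        # per-chromosome gene copies must be representable
        try:
            copies1 = {
                g: 1 + sum(cnr1[c.id] - 1 for c in locus.cnrs_containing(g))
                for g in locus.genes
            }
            copies2 = {
                g: 1 + sum(cnr2[c.id] - 1 for c in locus.cnrs_containing(g))
                for g in locus.genes
            }
        except KeyError:  # pragma: no cover
            continue
        if min(copies1.values()) < 0 or min(copies2.values()) < 0:
            continue
        var_splits = []
        feasible = True
        for v in locus.variants:
            dose = genotype.dosages.get(v.id, {})
            items = [a for a, d in dose.items() for _ in range(d)]
            k1 = copies1[v.gene]
            if len(items) != copies1[v.gene] + copies2[v.gene]:
                feasible = False
                break
            splits = _multiset_splits(items, k1)
            if not splits:
                feasible = False
                break
            var_splits.append((v.id, splits))
        if not feasible:
            continue
        for combo in _iproduct(*[s for _, s in var_splits]):
            al1 = {var_splits[i][0]: combo[i][0] for i in range(len(var_splits))}
            al2 = {var_splits[i][0]: combo[i][1] for i in range(len(var_splits))}
            h1 = ChromosomeHaplotype(cnr1, al1, locus)
            h2 = ChromosomeHaplotype(cnr2, al2, locus)
            key = tuple(sorted((h1._key, h2._key)))
            if key not in results:
                results.add(key)
                out.append((h1, h2) if h1._key <= h2._key else (h2, h1))
    return out


# ---------------------------------------------------------------------------
# Trio phasing
# ---------------------------------------------------------------------------

def _subtract_chromosome(
    genotype: IndividualGenotype,
    hap: ChromosomeHaplotype,
    locus: LocusDefinition,
) -> ChromosomeHaplotype | None:
    """The chromosome left after removing ``hap`` from ``genotype``,
    or None if no valid chromosome remains."""
    cnr = {}
    for c in locus.cnrs:
        rem = genotype.cnr_copies.get(c.id, 2) - hap.cnr_copies[c.id]
        if not 0 <= rem <= 2:
            return None
        cnr[c.id] = rem
    alleles = {}
    for v in locus.variants:
        dose = dict(genotype.dosages.get(v.id, {}))
        for a in hap.alleles[v.id]:
            dose[a] = dose.get(a, 0) - 1
            if dose[a] < 0:
                return None
        alleles[v.id] = tuple(a for a, d in dose.items() for _ in range(d))
    try:
        return ChromosomeHaplotype(cnr, alleles, locus)
    except ValueError:
        return None


def phase_trio(
    trio: Trio,
    priors: HaplotypeFrequencyTable | None = None,
    locus: LocusDefinition | None = None,
    *,
    prior_floor: float = 1e-6,
    ambiguity_posterior: float = 0.95,
    _decomp_cache: dict | None = None,
) -> PhasedTrio:
    """Mendelian phasing of one complete trio.

    Enumerates the child's decompositions into two chromosomes; each child
    chromosome must be one of the respective parent's chromosomes, so the
    other parental chromosome is obtained by subtraction.  When several
    solutions survive, the maximum prior-probability combination (product
    of population frequencies of the four parental chromosomes, then
    lexicographic order) is selected; chromosomes absent from the priors
    receive ``prior_floor``.  The trio is flagged ambiguous when the
    selected solution's prior-weighted posterior falls below
    ``ambiguity_posterior`` — a strict several-solutions flag would fire on
    virtually every trio, because any diploid copy number of 2 also admits
    a (deletion + duplication) chromosome pair whose prior probability is
    negligible.  ``n_solutions`` records the raw count.
    """
    locus = locus or default_locus()
    if not trio.complete:
        return PhasedTrio(trio.family_id, None, None, None, mendelian_error=False,
                          ambiguous=False, n_solutions=0)
    prior_map: dict = dict(priors.entries) if priors is not None else {}

    def prior(h: ChromosomeHaplotype) -> float:
        if h in prior_map:
            return prior_map[h]
        if priors is None:
            # parsimony prior: per-chromosome CNV is rare, so decompositions
            # that invoke aberrant chromosomes are penalised per aberration
            pen = 1.0
            for c in h.cnr_copies.values():
                pen *= 0.9 if c == 1 else 0.01
            return pen
        return prior_floor

    if _decomp_cache is not None:
        ckey = _genotype_key(trio.child, locus)
        if ckey not in _decomp_cache:
            _decomp_cache[ckey] = decompose_genotype(trio.child, locus)
        child_decomps = _decomp_cache[ckey]
    else:
        child_decomps = decompose_genotype(trio.child, locus)
    seen = set()
    unique = []
    for c1, c2 in child_decomps:
        for cf, cm in ((c1, c2), (c2, c1)):
            f_other = _subtract_chromosome(trio.father, cf, locus)
            m_other = _subtract_chromosome(trio.mother, cm, locus)
            if f_other is None or m_other is None:
                continue
            fpair = (cf, f_other) if cf._key <= f_other._key else (f_other, cf)
            mpair = (cm, m_other) if cm._key <= m_other._key else (m_other, cm)
            ti = fpair.index(cf) if fpair[0]._key != fpair[1]._key else 0
            tj = mpair.index(cm) if mpair[0]._key != mpair[1]._key else 0
            key = (
                fpair[0]._key, fpair[1]._key, mpair[0]._key, mpair[1]._key,
                fpair[ti]._key, mpair[tj]._key,
            )
            if key not in seen:
                seen.add(key)
                unique.append((fpair, mpair, (ti, tj)))
    if not unique:
        return PhasedTrio(trio.family_id, None, None, None,
                          mendelian_error=True, n_solutions=0)
    scores = [
        prior(s[0][0]) * prior(s[0][1]) * prior(s[1][0]) * prior(s[1][1])
        for s in unique
    ]
    order = sorted(
        range(len(unique)),
        key=lambda i: (
            -scores[i],
            unique[i][0][0]._key, unique[i][0][1]._key,
            unique[i][1][0]._key, unique[i][1][1]._key, unique[i][2],
        ),
    )
    best = order[0]
    total = sum(scores)
    # aggregate posterior over solutions sharing the transmission signature
    # (the unordered multiset of per-parent transmitted/untransmitted
    # chromosome pairs) — solutions differing only in which parent is which
    # contribute identically to the TDT
    def signature(s):
        fpair, mpair, (ti, tj) = s
        return tuple(sorted((
            (fpair[ti]._key, fpair[1 - ti]._key),
            (mpair[tj]._key, mpair[1 - tj]._key),
        )))

    sig_scores: dict = {}
    for s, sc in zip(unique, scores):
        k = signature(s)
        sig_scores[k] = sig_scores.get(k, 0.0) + sc
    posterior = (
        sig_scores[signature(unique[best])] / total if total > 0 else 1.0 / len(unique)
    )
    fpair, mpair, trans = unique[best]
    return PhasedTrio(
        family_id=trio.family_id,
        father_haplotypes=fpair,
        mother_haplotypes=mpair,
        transmitted=trans,
        ambiguous=posterior < ambiguity_posterior,
        n_solutions=len(unique),
        posterior=posterior,
    )


def _genotype_key(g: IndividualGenotype, locus: LocusDefinition):
    return (
        tuple(sorted((c.id, g.cnr_copies.get(c.id, 2)) for c in locus.cnrs)),
        tuple(
            (v.id, tuple(sorted((a, d) for a, d in g.dosages.get(v.id, {}).items() if d)))
            for v in locus.variants
        ),
    )


def phase_trios(
    trios: Sequence[Trio],
    priors: HaplotypeFrequencyTable | None = None,
    locus: LocusDefinition | None = None,
    **kwargs,
) -> list[PhasedTrio]:
    """Phase many trios, memoizing repeated genotype constellations."""
    locus = locus or default_locus()
    decomp_cache: dict = {}
    result_cache: dict = {}
    out = []
    for t in trios:
        if t.complete:
            key = (
                _genotype_key(t.father, locus),
                _genotype_key(t.mother, locus),
                _genotype_key(t.child, locus),
            )
        else:
            key = None
        if key is not None and key in result_cache:
            ph = result_cache[key]
            ph = PhasedTrio(
                t.family_id, ph.father_haplotypes, ph.mother_haplotypes,
                ph.transmitted, ph.ambiguous, ph.mendelian_error,
                ph.n_solutions, ph.posterior,
            )
        else:
            ph = phase_trio(t, priors, locus, _decomp_cache=decomp_cache, **kwargs)
            if key is not None:
                result_cache[key] = ph
        out.append(ph)
    return out


# ---------------------------------------------------------------------------
# Transmission disequilibrium test
# ---------------------------------------------------------------------------

def tdt(
    phased: Sequence[PhasedTrio],
    variant_id: str,
    label: str,
    *,
    min_informative: int = 10,
) -> TDTResult:
    """Allele-wise TDT for one chromosome-level allele label.

    ``variant_id`` may also name a CNV region, in which case the label is
    the per-chromosome copy count (``"0"``, ``"1"``, ``"2"``).
    """
    t_count = u_count = 0
    informative_families = 0
    label_count = 0
    chrom_count = 0
    for ph in phased:
        if not ph.ok:
            continue
        fam_informative = False
        for pair, ti in (
            (ph.father_haplotypes, ph.transmitted[0]),
            (ph.mother_haplotypes, ph.transmitted[1]),
        ):
            has = [haplotype_label(h, variant_id) == label for h in pair]
            chrom_count += 2
            label_count += sum(has)
            if sum(has) == 1:
                fam_informative = True
                if has[ti]:
                    t_count += 1
                else:
                    u_count += 1
        if fam_informative:
            informative_families += 1
    freq = label_count / chrom_count if chrom_count else 0.0
    if t_count + u_count == 0:
        return TDTResult(variant_id, label, freq, informative_families,
                         0, 0, None, None, suppressed=True)
    z = (t_count - u_count) / math.sqrt(t_count + u_count)
    p = 2.0 * stats.norm.sf(abs(z))
    return TDTResult(
        variant_id=variant_id,
        label=label,
        allele_frequency=freq,
        informative_families=informative_families,
        transmitted=t_count,
        untransmitted=u_count,
        z=z,
        p_value=float(p),
        suppressed=informative_families <= min_informative,
    )


def tdt_all_labels(
    phased: Sequence[PhasedTrio],
    variant_ids: Sequence[str],
    *,
    min_informative: int = 10,
) -> list[TDTResult]:
    """TDT for every chromosome-level label observed among parental
    chromosomes, for each requested variant system or CNV region."""
    out = []
    for vid in variant_ids:
        labels = sorted(
            {
                haplotype_label(h, vid)
                for ph in phased
                if ph.ok
                for pair in (ph.father_haplotypes, ph.mother_haplotypes)
                for h in pair
            }
        )
        for label in labels:
            out.append(tdt(phased, vid, label, min_informative=min_informative))
    return out
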