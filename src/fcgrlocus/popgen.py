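"""Population statistics for a copy-number-variable locus.

Allele frequencies use gene-copy denominators: the frequency of an allele
is the summed allele dosage divided by the summed gene copy number, not by
2n, because individuals contribute as many alleles as they carry gene
copies.  Haplotype frequencies between variant systems are estimated by
expectation-maximization over unphased genotypes restricted to CNV-free
individuals; pairwise LD (r², D') is computed from the estimated haplotype
frequencies after biallelic allele-vs-rest collapse.  Because r²/D' are
undefined across copy-number changes, LD between a CNV region and an
allele is assessed by comparing copy-number-aware allele frequencies
between copy-number strata (deleted <=1 / normal 2 / duplicated >=3) with
Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product as _iproduct
from typing import Sequence

import numpy as np
from scipy import stats

from .locus_model import (
    HaplotypeFrequencyTable,
    IndividualGenotype,
    LocusDefinition,
    default_locus,
)

__all__ = [
    "FrequencyResult",
    "LDResult",
    "StratifiedLDResult",
    "allele_frequency",
    "em_haplotypes",
    "ld_from_haplotypes",
    "cnv_stratified_ld",
    "fisher_exact_rxc",
]


# ---------------------------------------------------------------------------
# Copy-number-aware allele frequencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyResult:
    variant_id: str
    counts: tuple[tuple[str, int], ...]
    denominator: int

    @property
    def frequencies(self) -> dict[str, float]:
        return {a: c / self.denominator for a, c in self.counts}

    def count(self, allele: str) -> int:
        return dict(self.counts).get(allele, 0)


def allele_frequency(
    genotypes: Sequence[IndividualGenotype],
    variant_id: str,
    locus: LocusDefinition | None = None,
    *,
    validate: bool = True,
) -> FrequencyResult:
    """Allele counts over gene-copy denominators.

    ``frequency(a) = sum of dosages of a / sum of gene copy numbers``; for
    genes outside every CNV region the denominator is simply 2n.
    """
    locus = locus or default_locus()
    v = locus.variant(variant_id)
    counts = {a: 0 for a in v.alleles}
    denom = 0
    for g in genotypes:
        copies = g.gene_copy_number(v.gene, locus)
        dose = g.dosages.get(variant_id, {})
        if validate:
            bad = set(dose) - set(v.alleles)
            if bad or sum(dose.values()) != copies or any(d < 0 for d in dose.values()):
                raise ValueError(
                    f"individual {g.id}: dosages {dose} inconsistent with "
                    f"{copies} copies of {v.gene}"
                )
        denom += copies
        for a, d in dose.items():
            counts[a] += d
    if denom == 0:
        raise ValueError(f"no gene copies observed for {variant_id}")
    return FrequencyResult(
        variant_id=variant_id, counts=tuple(counts.items()), denominator=denom
    )


# ---------------------------------------------------------------------------
# EM haplotype frequency estimation (CNV-free individuals)
# ---------------------------------------------------------------------------

def _dosage_vector(g: IndividualGenotype, v) -> tuple[int, ...]:
    dose = g.dosages.get(v.id, {})
    return tuple(dose.get(a, 0) for a in v.alleles)


def _splits(vec: tuple[int, ...]):
    """All ordered ways to split a 2-copy dosage vector into two 1-copy
    allele indices."""
    alleles = [i for i, d in enumerate(vec) for _ in range(d)]
    a, b = alleles
    return [(a, b)] if a == b else [(a, b), (b, a)]


def em_haplotypes(
    genotypes: Sequence[IndividualGenotype],
    variant_ids: Sequence[str],
    locus: LocusDefinition | None = None,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
    return_loglik: bool = False,
):
    """EM estimate of multilocus haplotype frequencies from unphased data.

    Every individual must carry exactly two copies of every involved gene
    (no CNV); individuals with CNV raise an error — the caller filters.
    Initialization is the product of marginal allele frequencies; iteration
    stops when the relative log-likelihood change falls below ``tol``.
    """
    locus = locus or default_locus()
    variants = [locus.variant(vid) for vid in variant_ids]
    for g in genotypes:
        for v in variants:
            if g.gene_copy_number(v.gene, locus) != 2:
                raise ValueError(
                    f"individual {g.id} has CNV at {v.gene}; EM requires "
                    "CNV-free individuals"
                )
    if not genotypes:
        raise ValueError("no genotypes given")

    # group identical multilocus genotypes
    patterns: dict[tuple, int] = {}
    for g in genotypes:
        key = tuple(_dosage_vector(g, v) for v in variants)
        patterns[key] = patterns.get(key, 0) + 1

    # compatible unordered haplotype pairs per pattern
    pair_sets = {}
    for key in patterns:
        pairs = set()
        for combo in _iproduct(*[_splits(vec) for vec in key]):
            h1 = tuple(c[0] for c in combo)
            h2 = tuple(c[1] for c in combo)
            pairs.add((h1, h2) if h1 <= h2 else (h2, h1))
        pair_sets[key] = sorted(pairs)

    haps = sorted({h for pairs in pair_sets.values() for p in pairs for h in p})
    hidx = {h: i for i, h in enumerate(haps)}
    n_ind = sum(patterns.values())

    # init: product of marginals
    freqs = np.ones(len(haps))
    marg = [np.zeros(len(v.alleles)) for v in variants]
    for key, cnt in patterns.items():
        for k, vec in enumerate(key):
            marg[k] += cnt * np.asarray(vec)
    marg = [m / m.sum() for m in marg]
    for h, i in hidx.items():
        freqs[i] = math.prod(marg[k][h[k]] for k in range(len(variants)))
    # deterministic jitter breaks exact symmetries (e.g. all-double-het
    # data), where the product-of-marginals point is a stationary saddle
    freqs *= 1.0 + 1e-3 * np.sin(np.arange(1.0, len(freqs) + 1.0))
    freqs = freqs / freqs.sum()

    loglik = -np.inf
    for it in range(max_iter):
        new = np.zeros_like(freqs)
        ll = 0.0
        for key, cnt in patterns.items():
            ws = []
            for h1, h2 in pair_sets[key]:
                mult = 1.0 if h1 == h2 else 2.0
                ws.append(mult * freqs[hidx[h1]] * freqs[hidx[h2]])
            tot = sum(ws)
            if tot <= 0.0:
                # pattern momentarily unsupported; restart that mass uniformly
                ws = [1.0] * len(ws)
                tot = float(len(ws))
            ll += cnt * math.log(tot) if tot > 0 else -1e30
            for (h1, h2), w in zip(pair_sets[key], ws):
                share = cnt * w / tot
                new[hidx[h1]] += share
                new[hidx[h2]] += share
        new /= 2.0 * n_ind
        prev, loglik, freqs = loglik, ll, new
        # a few mandatory sweeps let the jitter escape symmetric saddles
        if it >= 5 and prev > -np.inf and abs(loglik - prev) <= tol * (abs(prev) + 1e-12):
            break

    table = HaplotypeFrequencyTable.normalized(
        {
            tuple(variants[k].alleles[h[k]] for k in range(len(variants))): f
            for h, f in zip(haps, freqs)
            if f > 0
        },
        variants=[v.id for v in variants],
    )
    return (table, loglik) if return_loglik else table


# ---------------------------------------------------------------------------
# Pairwise LD from haplotype frequencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDResult:
    variant_a: str
    allele_a: str
    variant_b: str
    allele_b: str
    p_a: float
    p_b: float
    p_ab: float
    d: float
    r2: float
    d_prime: float
    p_value: float | None

    def __post_init__(self) -> None:
        if not (0.0 - 1e-12 <= self.r2 <= self.d_prime + 1e-9 <= 1.0 + 1e-9):
            raise ValueError("LD invariant violated: need 0 <= r2 <= D' <= 1")


def ld_from_haplotypes(
    table: HaplotypeFrequencyTable,
    variant_a: str,
    allele_a: str,
    variant_b: str,
    allele_b: str,
    n_chromosomes: int | None = None,
) -> LDResult:
    """r² and D' between two allele-vs-rest collapses.

    ``D = pAB - pA pB``; ``r² = D²/(pA qA pB qB)``; ``D' = |D| / Dmax``
    with the usual Lewontin normalisation.  The p-value (if ``n_chromosomes``
    is given) is from the chi-square statistic ``n r²`` with 1 df.
    """
    if table.variants is None:
        raise ValueError("table must carry an ordered variant list")
    ia, ib = table.variants.index(variant_a), table.variants.index(variant_b)
    p_a = p_b = p_ab = 0.0
    for hap, f in table:
        a = hap[ia] == allele_a
        b = hap[ib] == allele_b
        p_a += f * a
        p_b += f * b
        p_ab += f * (a and b)
    qa, qb = 1.0 - p_a, 1.0 - p_b
    if min(p_a, qa, p_b, qb) <= 0.0:
        raise ValueError(
            f"monomorphic collapse ({variant_a}:{allele_a} p={p_a:.4g}, "
            f"{variant_b}:{allele_b} p={p_b:.4g}); r2 undefined"
        )
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * qa * p_b * qb)
    if d > 0:
        d_max = min(p_a * qb, qa * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, qa * qb)
    else:
        d_max = 1.0
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    p_value = None
    if n_chromosomes is not None:
        p_value = float(stats.chi2.sf(n_chromosomes * r2, df=1))
    return LDResult(
        variant_a, allele_a, variant_b, allele_b,
        p_a, p_b, p_ab, d, min(r2, 1.0), min(d_prime, 1.0), p_value,
    )


# ---------------------------------------------------------------------------
# Exact / Monte-Carlo Fisher test on r x c tables
# ---------------------------------------------------------------------------

def _table_logprob_luts(rows: np.ndarray, col1: int) -> list[np.ndarray]:
    return [
        np.array([math.lgamma(r + 1) - math.lgamma(a + 1) - math.lgamma(r - a + 1)
                  for a in range(min(r, col1) + 1)])
        for r in rows
    ]


def _fisher_rx2_exact(table: np.ndarray) -> float:
    rows = table.sum(axis=1)
    n = int(rows.sum())
    col1 = int(table[:, 0].sum())
    luts = _table_logprob_luts(rows, col1)
    lden = math.lgamma(n + 1) - math.lgamma(col1 + 1) - math.lgamma(n - col1 + 1)
    lobs = sum(luts[i][table[i, 0]] for i in range(len(rows))) - lden
    # enumerate all but the largest row; the remainder is determined
    order = np.argsort(rows)
    lead = order[:-1]
    last = order[-1]
    grids = np.meshgrid(
        *[np.arange(min(int(rows[i]), col1) + 1) for i in lead], indexing="ij"
    )
    s = sum(grids) if grids else np.array(0)
    a_last = col1 - s
    valid = (a_last >= 0) & (a_last <= int(rows[last]))
    logp = np.full(np.shape(a_last), -np.inf)
    lp = luts[last][np.clip(a_last, 0, len(luts[last]) - 1)]
    for g, i in zip(grids, lead):
        lp = lp + luts[i][g]
    logp = np.where(valid, lp - lden, -np.inf)
    keep = logp <= lobs + 1e-7
    return float(np.exp(logp[keep & valid]).sum())


def _rxc_size(table: np.ndarray) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    size = 1.0
    for r in np.sort(rows)[:-1]:
        for c in np.sort(cols)[:-1]:
            size *= min(r, c) + 1
    return size


def _fisher_rxc_mc(table: np.ndarray, n_draws: int, seed) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    rng = np.random.default_rng(seed)
    lg = [math.lgamma(k + 1) for k in range(int(rows.sum()) + 1)]

    def logprob(tabs):
        flat = np.vectorize(lambda k: lg[k])(tabs)
        return -flat.sum(axis=(-2, -1))

    lobs = logprob(table[None, :, :])[0]
    dist = stats.random_table(rows, cols, seed=rng)
    hits = 0
    chunk = 100_000
    left = n_draws
    while left > 0:
        m = min(chunk, left)
        left -= m
        draws = dist.rvs(m, random_state=rng)
        hits += int((logprob(draws) <= lobs + 1e-7).sum())
    return (hits + 1) / (n_draws + 1)


def fisher_exact_rxc(
    table,
    *,
    exact_limit: float = 5e6,
    n_draws: int = 1_000_000,
    seed: int | None = 0,
) -> tuple[float, str]:
    """Fisher's exact test for independence of an r x c count table.

    Returns ``(p, method)`` with ``method`` one of ``exact`` (full
    enumeration, always used for two-column tables of moderate size) or
    ``monte-carlo`` (seeded, ``n_draws`` Patefield draws).  The two-sided
    p-value sums the probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("empty table")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        # a monomorphic margin carries no evidence against independence
        return 1.0, "degenerate"
    if t.shape[1] == 2 or t.shape[0] == 2:
        t2 = t if t.shape[1] == 2 else t.T
        rows = t2.sum(axis=1)
        col1 = int(t2[:, 0].sum())
        size = np.prod(
            [min(int(r), col1) + 1 for r in np.sort(rows)[:-1]], dtype=float
        )
        if size <= exact_limit:
            return _fisher_rx2_exact(t2), "exact"
    if _rxc_size(t) <= 2000:
        return _fisher_rxc_enumerate(t), "exact"
    return _fisher_rxc_mc(t, n_draws, seed), "monte-carlo"


def _fisher_rxc_enumerate(table: np.ndarray) -> float:
    """Full recursive enumeration for small r x c tables."""
    rows = table.sum(axis=1).tolist()
    cols = table.sum(axis=0).tolist()
    n = int(table.sum())
    lg = [math.lgamma(k + 1) for k in range(n + 1)]
    lconst = sum(lg[r] for r in rows) + sum(lg[c] for c in cols) - lg[n]
    lobs = lconst - sum(lg[int(x)] for x in table.flat)
    total = 0.0

    def rec(i, rem_cols, acc):
        nonlocal total
        if i == len(rows) - 1:
            lp = acc - sum(lg[c] for c in rem_cols)
            if lconst + lp <= lobs + 1e-7:
                total += math.exp(lconst + lp)
            return
        def cells(j, left, acc2, rc):
            if j == len(cols) - 1:
                if 0 <= left <= rem_cols[j]:
                    rc2 = list(rc) + [rem_cols[j] - left]
                    rec(i + 1, rc2, acc2 - lg[left])
                return
            for x in range(min(left, rem_cols[j]) + 1):
                cells(j + 1, left - x, acc2 - lg[x], list(rc) + [rem_cols[j] - x])
        cells(0, rows[i], acc, [])

    rec(0, cols, 0.0)
    return total


# ---------------------------------------------------------------------------
# CNV-stratified LD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratifiedLDResult:
    cnr_id: str
    variant_id: str
    strata: tuple[str, ...]
    frequencies: tuple[FrequencyResult, ...]
    p_value: float
    method: str


def cnv_stratified_ld(
    genotypes: Sequence[IndividualGenotype],
    cnr_id: str,
    variant_id: str,
    locus: LocusDefinition | None = None,
    *,
    seed: int | None = 0,
) -> StratifiedLDResult:
    """LD between a CNV region and a variant via copy-number strata.

    Individuals are split into decreased (<=1 copies), normal (2) and
    increased (>=3 copies) strata of the CNV region; copy-number-aware
    allele counts per stratum form an allele x stratum table tested for
    independence with Fisher's exact test.
    """
    locus = locus or default_locus()
    locus.cnr(cnr_id)
    strata_def = (("<=1", lambda c: c <= 1), ("2", lambda c: c == 2), (">=3", lambda c: c >= 3))
    groups: dict[str, list[IndividualGenotype]] = {name: [] for name, _ in strata_def}
    for g in genotypes:
        c = g.cnr_copies.get(cnr_id, 2)
        for name, pred in strata_def:
            if pred(c):
                groups[name].append(g)
                break
    names = [name for name, _ in strata_def if groups[name]]
    if len(names) < 2:
        raise ValueError(
            f"all individuals fall in one {cnr_id} copy-number stratum; "
            "stratified LD needs >=2 non-empty strata"
        )
    v = locus.variant(variant_id)
    freqs = tuple(allele_frequency(groups[name], variant_id, locus) for name in names)
    table = np.array([[fr.count(a) for fr in freqs] for a in v.alleles])
    table = table[table.sum(axis=1) > 0]
    p, method = fisher_exact_rxc(table, seed=seed)
    return StratifiedLDResult(
        cnr_id=cnr_id,
        variant_id=variant_id,
        strata=tuple(names),
        frequencies=freqs,
        p_value=p,
        method=method,
    )
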