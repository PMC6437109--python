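"""Population statistics: CNV-aware frequencies, EM, LD, exact tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import optimize

import fcgrlocus as F
from fcgrlocus import popgen as P
from fcgrlocus import synthetic_data as S
from fcgrlocus.locus_model import HaplotypeFrequencyTable, IndividualGenotype



def _geno(locus, ident, cnrs=None, **dosages):
    base = {
        "FCGR2A_H131R": {"R": 2}, "FCGR2A_Q27W": {"Q": 2},
        "FCGR3A_V158F": {"F": 2}, "FCGR2C": {"Stop": 2},
        "FCGR2C_prom": {"2B.1": 2}, "FCGR3B_NA": {"NA2": 2},
        "FCGR2B_prom": {"2B.1": 2}, "FCGR2B_I232T": {"I": 2},
    }
    base.update(dosages)
    cnr = {"CNR1": 2, "CNR2": 2, "CNR3": 2}
    cnr.update(cnrs or {})
    g = IndividualGenotype(ident, cnr, base)
    g.validate(locus)
    return g


# ---------------------------------------------------------------------------
# allele_frequency
# ---------------------------------------------------------------------------

def test_allele_frequency_homogeneous(locus):
    genotypes = [_geno(locus, f"i{k}") for k in range(10)]
    fr = P.allele_frequency(genotypes, "FCGR2C", locus)
    assert fr.frequencies == {"ORF": 0.0, "Stop": 1.0, "NC-ORF": 0.0}
    assert fr.denominator == 20


def test_allele_frequency_single_cnv_individual(locus):
    g = _geno(locus, "dup", cnrs={"CNR1": 3}, FCGR2C={"Stop": 3},
              FCGR2C_prom={"2B.1": 3}, FCGR3B_NA={"NA2": 3})
    fr = P.allele_frequency([g], "FCGR2C", locus)
    assert fr.denominator == 3
    assert fr.frequencies["Stop"] == 1.0


def test_allele_frequency_names_offending_individual(locus):
    g = _geno(locus, "ok")
    g.dosages["FCGR2C"] = {"Stop": 3}  # corrupt after validation
    with pytest.raises(ValueError, match="ok"):
        P.allele_frequency([g], "FCGR2C", locus)


# ---------------------------------------------------------------------------
# EM haplotype estimation vs independent maximum likelihood
# ---------------------------------------------------------------------------

def _brute_force_ml(genotypes, locus, variants=("FCGR2A_H131R", "FCGR2B_I232T")):
    """Direct likelihood maximisation over the haplotype simplex
    (softmax-parametrised, multi-start BFGS) — independent of EM."""
    v1, v2 = (locus.variant(v) for v in variants)
    haps = list(itertools.product(range(len(v1.alleles)), range(len(v2.alleles))))

    data = []
    for g in genotypes:
        vec1 = tuple(g.dosages[variants[0]].get(a, 0) for a in v1.alleles)
        vec2 = tuple(g.dosages[variants[1]].get(a, 0) for a in v2.alleles)
        data.append((vec1, vec2))

    def pairs_for(vec1, vec2):
        def splits(vec):
            alleles = [i for i, d in enumerate(vec) for _ in range(d)]
            a, b = alleles
            return [(a, b)] if a == b else [(a, b), (b, a)]
        out = set()
        for (a1, b1), (a2, b2) in itertools.product(splits(vec1), splits(vec2)):
            h1, h2 = (a1, a2), (b1, b2)
            out.add((h1, h2) if h1 <= h2 else (h2, h1))
        return sorted(out)

    def negll(theta):
        w = np.exp(theta - theta.max())
        f = w / w.sum()
        fd = {h: f[i] for i, h in enumerate(haps)}
        ll = 0.0
        for vec1, vec2 in data:
            tot = sum(
                (1.0 if h1 == h2 else 2.0) * fd[h1] * fd[h2]
                for h1, h2 in pairs_for(vec1, vec2)
            )
            ll += math.log(max(tot, 1e-300))
        return -ll

    best = None
    rng = np.random.default_rng(0)
    for start in range(8):
        theta0 = rng.normal(size=len(haps))
        res = optimize.minimize(negll, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    w = np.exp(best.x - best.x.max())
    f = w / w.sum()
    labels = {
        (i, j): (v1.alleles[i], v2.alleles[j])
        for i in range(len(v1.alleles)) for j in range(len(v2.alleles))
    }
    return {labels[h]: f[k] for k, h in enumerate(haps)}, -best.fun


SMALL_INSTANCES = [
    # (H dosages, T dosages) per individual; both systems biallelic
    [({"H": 2}, {"I": 2})] * 3,
    [({"H": 1, "R": 1}, {"I": 1, "T": 1})] * 4,
    [({"H": 2}, {"I": 1, "T": 1}), ({"H": 1, "R": 1}, {"T": 2}),
     ({"R": 2}, {"I": 2})],
    [({"H": 1, "R": 1}, {"I": 2}), ({"H": 1, "R": 1}, {"I": 1, "T": 1}),
     ({"R": 2}, {"I": 1, "T": 1}), ({"H": 2}, {"I": 2}),
     ({"H": 1, "R": 1}, {"T": 2}), ({"R": 2}, {"T": 2})],
]


@pytest.mark.parametrize("instance", SMALL_INSTANCES)
def test_em_equals_brute_force_ml_on_small_instances(locus, instance):
    genotypes = [
        _geno(locus, f"i{k}", FCGR2A_H131R=dict(d1), FCGR2B_I232T=dict(d2))
        for k, (d1, d2) in enumerate(instance)
    ]
    table, ll_em = P.em_haplotypes(
        genotypes, ["FCGR2A_H131R", "FCGR2B_I232T"], locus, return_loglik=True
    )
    ml_freqs, ll_ml = _brute_force_ml(genotypes, locus)
    assert ll_em == pytest.approx(ll_ml, abs=1e-5)
    # frequency multisets agree (maxima can be symmetric under label swaps)
    em_sorted = sorted(table.entries.get(h, 0.0) for h in ml_freqs)
    ml_sorted = sorted(ml_freqs.values())
    assert em_sorted == pytest.approx(ml_sorted, abs=2e-3)


def test_em_equals_counting_when_phase_known(locus):
    genotypes = [
        _geno(locus, "a", FCGR2A_H131R={"H": 2}, FCGR2B_I232T={"T": 2}),
        _geno(locus, "b", FCGR2A_H131R={"R": 2}, FCGR2B_I232T={"I": 2}),
        _geno(locus, "c", FCGR2A_H131R={"R": 2}, FCGR2B_I232T={"I": 2}),
    ]
    table = P.em_haplotypes(genotypes, ["FCGR2A_H131R", "FCGR2B_I232T"], locus)
    assert table.entries[("H", "T")] == pytest.approx(1 / 3, abs=1e-9)
    assert table.entries[("R", "I")] == pytest.approx(2 / 3, abs=1e-9)


def test_em_loglik_monotone(locus, eur_pool):
    cohort = S.sample_population(eur_pool, 150, seed=29)
    cnv_free = [g for g in cohort if all(c == 2 for c in g.cnr_copies.values())]
    lls = []
    for iters in (1, 2, 3, 5, 10, 50):
        _, ll = P.em_haplotypes(
            cnv_free, ["FCGR2C", "FCGR2A_H131R"], locus,
            max_iter=iters, tol=0.0, return_loglik=True,
        )
        lls.append(ll)
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_em_rejects_cnv_individuals(locus):
    g = _geno(locus, "dup", cnrs={"CNR1": 3}, FCGR2C={"Stop": 3},
              FCGR2C_prom={"2B.1": 3}, FCGR3B_NA={"NA2": 3})
    with pytest.raises(ValueError, match="CNV"):
        P.em_haplotypes([g], ["FCGR2C", "FCGR2A_H131R"], locus)


# ---------------------------------------------------------------------------
# LD from haplotype frequencies
# ---------------------------------------------------------------------------

def _two_locus_table(p_ab, p_a, p_b):
    return HaplotypeFrequencyTable(
        {
            ("A", "B"): p_ab,
            ("A", "b"): p_a - p_ab,
            ("a", "B"): p_b - p_ab,
            ("a", "b"): 1 - p_a - p_b + p_ab,
        },
        variants=["va", "vb"],
    )


def test_ld_equilibrium():
    res = P.ld_from_haplotypes(_two_locus_table(0.15, 0.3, 0.5), "va", "A", "vb", "B")
    assert res.r2 == pytest.approx(0.0, abs=1e-12)
    assert res.d_prime == pytest.approx(0.0, abs=1e-12)


def test_ld_complete():
    res = P.ld_from_haplotypes(_two_locus_table(0.5, 0.5, 0.5), "va", "A", "vb", "B")
    assert res.r2 == pytest.approx(1.0)
    assert res.d_prime == pytest.approx(1.0)


def test_ld_closed_form_strong_pair():
    """pA=0.11, pB=0.115, pAB=0.1086 gives r2 about 0.92 — the near-complete
    LD between the classic ORF and the 2B.2 promoter."""
    res = P.ld_from_haplotypes(
        _two_locus_table(0.1086, 0.11, 0.115), "va", "A", "vb", "B"
    )
    d = 0.1086 - 0.11 * 0.115
    expect = d * d / (0.11 * 0.89 * 0.115 * 0.885)
    assert res.r2 == pytest.approx(expect, rel=1e-12)
    assert res.r2 == pytest.approx(0.92, abs=0.01)


@pytest.mark.parametrize("p_a", [0.1, 0.3, 0.5, 0.8])
@pytest.mark.parametrize("p_b", [0.2, 0.5, 0.7])
@pytest.mark.parametrize("frac", [0.0, 0.25, 0.7, 1.0])
def test_ld_invariants_grid(p_a, p_b, frac):
    """0 <= r2 <= D' <= 1 across the feasible pAB range, and both measures
    are invariant to swapping allele labels."""
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    p_ab = lo + frac * (hi - lo)
    res = P.ld_from_haplotypes(_two_locus_table(p_ab, p_a, p_b), "va", "A", "vb", "B")
    assert -1e-12 <= res.r2 <= res.d_prime + 1e-9 <= 1.0 + 1e-9
    swapped = P.ld_from_haplotypes(
        _two_locus_table(p_ab, p_a, p_b), "va", "a", "vb", "b"
    )
    assert swapped.r2 == pytest.approx(res.r2, abs=1e-12)
    assert swapped.d_prime == pytest.approx(res.d_prime, abs=1e-12)


def test_ld_monomorphic_errors():
    with pytest.raises(ValueError, match="monomorphic"):
        P.ld_from_haplotypes(_two_locus_table(0.0, 0.0, 0.5), "va", "A", "vb", "B")


# ---------------------------------------------------------------------------
# Fisher exact r x c
# ---------------------------------------------------------------------------

# reference p-values computed independently with R's fisher.test
R_FISHER_ORACLE = [
    ([[289, 713], [108, 194], [8, 12]], 0.0445583),
    ([[122, 269], [211, 463], [72, 187]], 0.561723),
    ([[283, 721], [113, 184], [9, 13], [0, 1]], 0.00411248),
    ([[322, 697], [76, 201], [7, 21]], 0.360194),
    ([[1, 1], [27, 60], [348, 768], [27, 83], [2, 7]], 0.541981),
]


@pytest.mark.parametrize("table, expected", R_FISHER_ORACLE)
def test_fisher_rx2_matches_r_oracle(table, expected):
    p, method = P.fisher_exact_rxc(np.array(table))
    assert method == "exact"
    assert p == pytest.approx(expected, rel=1e-4)


def test_fisher_2x2_matches_scipy():
    from scipy.stats import fisher_exact

    table = np.array([[12, 5], [7, 19]])
    p, _ = P.fisher_exact_rxc(table)
    assert p == pytest.approx(fisher_exact(table)[1], rel=1e-10)


def test_fisher_balanced_table_p_one():
    p, _ = P.fisher_exact_rxc(np.array([[10, 10], [10, 10]]))
    assert p == pytest.approx(1.0)


def test_fisher_monte_carlo_close_to_exact():
    table = np.array([[30, 20, 10], [25, 25, 12]])
    p_exact, _ = P.fisher_exact_rxc(table, exact_limit=5e6)
    p_mc = P._fisher_rxc_mc(table, 200_000, seed=3)
    assert p_mc == pytest.approx(p_exact, abs=0.01)


# ---------------------------------------------------------------------------
# CNV-stratified LD
# ---------------------------------------------------------------------------

def test_stratified_ld_detects_duplication_linkage(eur_pool, locus):
    """Nonclassic ORF rides duplicated CNR1 chromosomes in the default
    pool, so the stratified exact test is strongly significant at n=900."""
    cohort = S.sample_population(eur_pool, 900, seed=31)
    res = P.cnv_stratified_ld(cohort, "CNR1", "FCGR2C", locus, seed=0)
    assert res.p_value < 0.001


def test_stratified_ld_null(locus):
    """Identical allele frequencies across strata give p = 1 on a balanced
    table."""
    genos = []
    for k in range(10):
        genos.append(_geno(locus, f"n{k}"))
    for k in range(10):
        genos.append(
            _geno(locus, f"d{k}", cnrs={"CNR1": 3}, FCGR2C={"Stop": 3},
                  FCGR2C_prom={"2B.1": 3}, FCGR3B_NA={"NA2": 3})
        )
    res = P.cnv_stratified_ld(genos, "CNR1", "FCGR2B_I232T", locus)
    assert res.p_value == pytest.approx(1.0)


def test_stratified_ld_requires_two_strata(locus):
    genos = [_geno(locus, f"x{k}") for k in range(5)]
    with pytest.raises(ValueError, match="stratum"):
        P.cnv_stratified_ld(genos, "CNR1", "FCGR2C", locus)
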