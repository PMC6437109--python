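"""Synthetic-data generator: pool construction, sampling, MLPA simulation."""

import math

import pytest

import fcgrlocus as F
from fcgrlocus import synthetic_data as S
from fcgrlocus.locus_model import HaplotypeFrequencyTable
from fcgrlocus.popgen import ld_from_haplotypes

from conftest import make_hap

ALL_VARIANTS = [
    "FCGR2A_H131R", "FCGR2A_Q27W", "FCGR3A_V158F", "FCGR2C",
    "FCGR2C_prom", "FCGR3B_NA", "FCGR2B_prom", "FCGR2B_I232T",
]


# ---------------------------------------------------------------------------
# build_pool
# ---------------------------------------------------------------------------

def test_default_pool_marginals_match_reference_frequencies(eur_pool):
    """European defaults reproduce the reference allele frequencies
    (classic ORF 0.11, Stop 0.84, nonclassic ORF 0.05, etc.)."""
    m = eur_pool.marginal("FCGR2C")
    assert m["ORF"] == pytest.approx(0.11, abs=1e-6)
    assert m["Stop"] == pytest.approx(0.84, abs=1e-6)
    assert m["NC-ORF"] == pytest.approx(0.05, abs=1e-6)
    assert eur_pool.marginal("FCGR2A_Q27W")["W"] == pytest.approx(0.12, abs=1e-6)
    assert eur_pool.marginal("FCGR2B_I232T")["T"] == pytest.approx(0.12, abs=1e-6)


def test_pool_frequencies_sum_to_one(eur_pool):
    assert sum(f for _, f in eur_pool) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("population", ["EUR", "CHN", "AFR"])
def test_all_population_pools_build_and_normalise(population):
    pool = F.default_pool(population)
    assert sum(f for _, f in pool) == pytest.approx(1.0, abs=1e-9)
    cfg = S.load_population_config(population)
    for vid, marg in cfg["marginals"].items():
        got = pool.marginal(vid)
        for allele, want in marg.items():
            if want > 0:
                assert got.get(allele, 0.0) == pytest.approx(
                    want / sum(marg.values()), abs=1e-6
                ), (population, vid, allele)


def test_zero_r2_target_gives_product_frequencies(locus):
    cfg = S.load_population_config("EUR")
    pool = S.build_pool(
        cfg["marginals"],
        [S.LDTarget("FCGR2A_H131R", "H", "FCGR2B_I232T", "T", 0.0)],
    )
    base = pool.baseline_allele_table(ALL_VARIANTS)
    res = ld_from_haplotypes(base, "FCGR2A_H131R", "H", "FCGR2B_I232T", "T")
    assert res.r2 == pytest.approx(0.0, abs=1e-6)
    assert res.p_ab == pytest.approx(res.p_a * res.p_b, abs=1e-6)


def test_ld_targets_honoured_on_cnv_free_background(eur_pool):
    base = eur_pool.baseline_allele_table(ALL_VARIANTS)
    for va, aa, vb, ab, target in [
        ("FCGR2C", "ORF", "FCGR2C_prom", "2B.2", 0.92),
        ("FCGR2C", "ORF", "FCGR2A_Q27W", "W", 0.63),
        ("FCGR2C", "ORF", "FCGR2B_prom", "2B.4", 0.40),
        ("FCGR2C", "ORF", "FCGR2A_H131R", "H", 0.08),
    ]:
        res = ld_from_haplotypes(base, va, aa, vb, ab)
        assert res.r2 == pytest.approx(target, abs=2e-4), (vb, ab)
    # the published 0.24 for 158V sits above the Lewontin bound at these
    # frequencies; the builder pins the pair at the D'=1 boundary
    res = ld_from_haplotypes(base, "FCGR2C", "ORF", "FCGR3A_V158F", "V")
    assert res.d_prime == pytest.approx(1.0, abs=1e-3)
    assert res.r2 == pytest.approx(0.2324, abs=5e-3)


def test_infeasible_r2_target_reports_feasible_maximum(locus):
    cfg = S.load_population_config("EUR")
    with pytest.raises(ValueError, match="feasible maximum"):
        S.build_pool(
            cfg["marginals"],
            [S.LDTarget("FCGR2C", "ORF", "FCGR3A_V158F", "V", 0.5)],
        )


def test_closed_form_two_locus_inversion():
    """pA=pB=0.11, r2=0.92: the builder's pAB solves the closed form and
    recomputing r2 from the pool returns the target."""
    p_ab, r2 = S._target_pab(0.11, 0.11, 0.92, clamp=False)
    d = p_ab - 0.11 * 0.11
    assert d**2 / (0.11 * 0.89 * 0.11 * 0.89) == pytest.approx(0.92, abs=1e-12)
    assert r2 == 0.92


# ---------------------------------------------------------------------------
# sample_population
# ---------------------------------------------------------------------------

def test_sample_population_seed_determinism(eur_pool):
    a = S.sample_population(eur_pool, 50, seed=9)
    b = S.sample_population(eur_pool, 50, seed=9)
    assert [g.dosages for g in a] == [g.dosages for g in b]
    assert [g.cnr_copies for g in a] == [g.cnr_copies for g in b]


def test_sample_population_recovers_orf_frequency(eur_pool):
    """At the reference cohort size the ORF estimate falls inside the
    binomial 95% CI of the control frequency 0.112."""
    from fcgrlocus.popgen import allele_frequency

    cohort = S.sample_population(eur_pool, 919, seed=11)
    fr = allele_frequency(cohort, "FCGR2C")
    p = fr.frequencies["ORF"]
    half = 1.96 * math.sqrt(0.112 * 0.888 / fr.denominator)
    assert abs(p - 0.112) < half + 0.01


def test_single_haplotype_pool_yields_identical_homozygotes(locus):
    pool = HaplotypeFrequencyTable({make_hap(locus): 1.0})
    cohort = S.sample_population(pool, 5, seed=0)
    for g in cohort:
        assert g.dosages["FCGR2C"] == {"Stop": 2}
        assert all(c == 2 for c in g.cnr_copies.values())


def test_sample_population_rejects_n_zero(eur_pool):
    with pytest.raises(ValueError):
        S.sample_population(eur_pool, 0, seed=0)


def test_sampled_genotypes_satisfy_invariants(locus, eur_pool):
    for g in S.sample_population(eur_pool, 100, seed=13):
        g.validate(locus)


# ---------------------------------------------------------------------------
# case-control and trio sampling
# ---------------------------------------------------------------------------

def test_null_model_case_control_frequencies_close(eur_pool):
    from fcgrlocus.popgen import allele_frequency

    model = S.DiseaseModel(log_or={}, prevalence=0.3)
    cases, controls = S.sample_case_control(eur_pool, model, 400, 400, seed=3)
    fa = allele_frequency(cases, "FCGR2C").frequencies["ORF"]
    fb = allele_frequency(controls, "FCGR2C").frequencies["ORF"]
    assert abs(fa - fb) < 0.05  # sampling noise only


def test_disease_model_rejects_bad_parameters():
    with pytest.raises(ValueError):
        S.DiseaseModel(log_or={}, prevalence=1.5)
    with pytest.raises(ValueError):
        S.DiseaseModel(log_or={("FCGR2C", "ORF"): float("inf")})


def test_case_control_sampling_cap(eur_pool):
    model = S.DiseaseModel(log_or={}, prevalence=0.01)
    with pytest.raises(RuntimeError, match="draws"):
        S.sample_case_control(eur_pool, model, 500, 10, seed=0, max_draw_factor=2)


def test_trios_null_transmissions_balanced(biallelic_pool):
    """Without a disease model transmissions are 50/50 on average."""
    trios = S.sample_trios(biallelic_pool, None, 400, seed=21)
    t = sum(
        tr.truth.father_haplotypes[tr.truth.transmitted[0]].alleles["FCGR2A_H131R"][0]
        == "H"
        for tr in trios
    )
    assert abs(t / 400 - 0.5) < 0.07


def test_trios_without_marker_allele(locus):
    pool = HaplotypeFrequencyTable({make_hap(locus): 1.0})
    trios = S.sample_trios(pool, None, 20, seed=1)
    from fcgrlocus.family_tdt import phase_trios, tdt

    phased = phase_trios(trios, pool, locus)
    res = tdt(phased, "FCGR2A_H131R", "H")
    assert res.informative_families == 0
    assert res.suppressed


# ---------------------------------------------------------------------------
# simulate_mlpa
# ---------------------------------------------------------------------------

def test_mlpa_noise_free_baseline_is_all_ones(locus):
    g = F.combine_chromosomes(make_hap(locus), make_hap(locus), "b", locus)
    df = S.simulate_mlpa([g], noise_sd=0.0, seed=0, locus=locus)
    ref = df[df["target"].isin(["CNR1", "CNR2", "CNR3"])]
    assert (ref["ratio"] == 1.0).all()
    assert df.loc[df["target"] == "FCGR2B_I232T:I", "ratio"].iloc[0] == 1.0
    assert df.loc[df["target"] == "FCGR2C:ORFsite", "ratio"].iloc[0] == 0.0


def test_mlpa_cnr1_duplication_ratio(locus):
    dup = make_hap(
        locus, cnr_copies={"CNR1": 2}, FCGR3B_NA=("NA1", "NA2"),
        FCGR2C=("Stop", "NC-ORF"), FCGR2C_prom=("2B.1", "2B.1"),
    )
    g = F.combine_chromosomes(dup, make_hap(locus), "d", locus)
    df = S.simulate_mlpa([g], noise_sd=0.0, seed=0, locus=locus)
    assert (df.loc[df["target"] == "CNR1", "ratio"] == 1.5).all()
    # one nonclassic ORF copy: ORF-site and splice probes both see dosage 1
    assert df.loc[df["target"] == "FCGR2C:ORFsite", "ratio"].iloc[0] == 0.5
    assert df.loc[df["target"] == "FCGR2C:splice", "ratio"].iloc[0] == 0.5


def test_mlpa_rejects_negative_noise(locus, eur_pool):
    g = S.sample_population(eur_pool, 1, seed=0)
    with pytest.raises(ValueError):
        S.simulate_mlpa(g, noise_sd=-0.1)
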