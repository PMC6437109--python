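"""MLPA interpretation: copy-number calls, FCGR2C resolution, promoter
allocation, misclassification estimation."""

import pytest

import fcgrlocus as F
from fcgrlocus import mlpa_caller as M
from fcgrlocus import synthetic_data as S


# ---------------------------------------------------------------------------
# call_copy_number
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ratios, expected",
    [
        ([1.02, 0.98], 2),
        ([1.49, 1.52], 3),
        ([0.52, 0.48], 1),
        ([0.02], 0),
    ],
)
def test_call_copy_number(ratios, expected):
    assert M.call_copy_number(ratios) == expected


def test_call_copy_number_no_call_outside_margin():
    with pytest.raises(M.NoCall):
        M.call_copy_number([1.25], margin=0.2)  # 0.5 copies from integer


def test_call_copy_number_empty_input():
    with pytest.raises(ValueError):
        M.call_copy_number([])


# ---------------------------------------------------------------------------
# resolve_fcgr2c
# ---------------------------------------------------------------------------

def test_resolve_unambiguous_stop_homozygote():
    call = M.resolve_fcgr2c(2, 0, 0)
    assert call.as_dict() == {"ORF": 0, "Stop": 2, "NC-ORF": 0}
    assert not call.ambiguous and call.posterior == 1.0


def test_resolve_unambiguous_classic_orf_het():
    call = M.resolve_fcgr2c(2, 1, 0)
    assert call.as_dict() == {"ORF": 1, "Stop": 1, "NC-ORF": 0}
    assert not call.ambiguous


def test_resolve_ambiguous_orf_plus_splice():
    """Copies=2 with one open frame and one splice mutation: either
    {classic ORF, Stop-with-splice} or {nonclassic ORF, Stop}.  European
    priors favour the nonclassic interpretation; the posterior equals the
    prior-weighted share of that configuration."""
    priors = {"ORF": 0.11, "NC-ORF": 0.05, "Stop(1)": 0.823, "Stop(2)": 0.017}
    call = M.resolve_fcgr2c(2, 1, 1, priors)
    assert call.ambiguous
    assert call.as_dict() == {"ORF": 0, "Stop": 1, "NC-ORF": 1}
    w_nc = 2 * priors["NC-ORF"] * priors["Stop(1)"]
    w_orf = 2 * priors["ORF"] * priors["Stop(2)"]
    assert call.posterior == pytest.approx(w_nc / (w_nc + w_orf), rel=1e-12)


def test_resolve_counts_always_sum_to_copies():
    for n in range(5):
        for orf in range(n + 1):
            for splice in range(n + 1):
                call = M.resolve_fcgr2c(n, orf, splice)
                assert sum(call.as_dict().values()) == n


def test_resolve_rejects_excess_dosage():
    with pytest.raises(ValueError):
        M.resolve_fcgr2c(2, 3, 0)


# ---------------------------------------------------------------------------
# allocate_promoter
# ---------------------------------------------------------------------------

def test_allocate_2b2_goes_to_fcgr2c():
    alloc = M.allocate_promoter(1, 0, 2, 2)
    c2, b2 = alloc.as_dicts()
    assert c2 == {"2B.1": 1, "2B.2": 1, "2B.4": 0}
    assert b2 == {"2B.1": 2, "2B.2": 0, "2B.4": 0}
    assert not alloc.ambiguous


def test_allocate_all_default():
    c2, b2 = M.allocate_promoter(0, 0, 2, 2).as_dicts()
    assert c2 == {"2B.1": 2, "2B.2": 0, "2B.4": 0}
    assert b2 == {"2B.1": 2, "2B.2": 0, "2B.4": 0}


def test_allocate_overflow_spills_and_flags():
    alloc = M.allocate_promoter(3, 0, 2, 2)
    c2, b2 = alloc.as_dicts()
    assert c2 == {"2B.1": 0, "2B.2": 2, "2B.4": 0}
    assert b2 == {"2B.1": 1, "2B.2": 1, "2B.4": 0}
    assert alloc.ambiguous


def test_allocate_rejects_excess_total():
    with pytest.raises(ValueError):
        M.allocate_promoter(3, 2, 2, 2)


# ---------------------------------------------------------------------------
# misclassification estimation
# ---------------------------------------------------------------------------

def test_misclassification_zero_without_splice_variants(eur_pool):
    """Without any splice-carrying haplotype (nonclassic ORF or Stop(2))
    the FCGR2C caller can never be wrong."""
    chrom_pool = [(("Stop(1)",), 0.89), (("ORF",), 0.11)]
    assert M.estimate_misclassification(chrom_pool, "fcgr2c") == 0.0


def test_misclassification_zero_for_degenerate_pool():
    assert M.estimate_misclassification([(("Stop(1)",), 1.0)], "fcgr2c") == 0.0


def test_misclassification_enumeration_matches_monte_carlo(eur_pool):
    chrom_pool = M.fcgr2c_chromosome_pool(eur_pool, stop_splice_fraction=0.02)
    exact = M.estimate_misclassification(chrom_pool, "fcgr2c")
    n = 200_000
    mc = M.estimate_misclassification_mc(chrom_pool, "fcgr2c", n=n, seed=7)
    sd = (exact * (1 - exact) / n) ** 0.5
    assert abs(mc - exact) < 3 * sd + 1e-9
    assert 0.0 < exact < 0.05  # small error rate under European defaults


def test_promoter_misclassification_zero_under_defaults(eur_pool):
    """The default pool keeps 2B.2 in FCGR2C and 2B.4 in FCGR2B, so the
    allocation rule is always right."""
    pool = M.promoter_chromosome_pool(eur_pool)
    assert M.estimate_misclassification(pool, "promoter") == 0.0


# ---------------------------------------------------------------------------
# round trips through the full caller
# ---------------------------------------------------------------------------

def _dosage_sets(g, locus):
    return {
        v.id: {a: d for a, d in g.dosages.get(v.id, {}).items() if d}
        for v in locus.variants
    }


def test_noise_free_round_trip_recovers_genotypes(locus, eur_pool):
    cohort = S.sample_population(eur_pool, 300, seed=17)
    probes = S.simulate_mlpa(cohort, noise_sd=0.0, seed=0, locus=locus)
    called, flags = M.call_genotypes(probes, locus=locus)
    assert len(called) == len(cohort)
    truth = {g.id: g for g in cohort}
    for g in called:
        t = truth[g.id]
        assert g.cnr_copies == t.cnr_copies
        assert _dosage_sets(g, locus) == _dosage_sets(t, locus)


def test_noisy_round_trip_copy_number_accuracy(locus, eur_pool):
    """At probe noise 0.05 at least 99% of CNV-region copy-number calls
    are correct (no-calls count as incorrect)."""
    cohort = S.sample_population(eur_pool, 1000, seed=19)
    probes = S.simulate_mlpa(cohort, noise_sd=0.05, seed=23, locus=locus)
    truth = {g.id: g for g in cohort}
    total = correct = 0
    for (ind, target), grp in probes.groupby(["individual_id", "target"]):
        if target not in ("CNR1", "CNR2", "CNR3"):
            continue
        total += 1
        try:
            got = M.call_copy_number(grp["ratio"].to_numpy())
        except M.NoCall:
            continue
        correct += got == truth[ind].cnr_copies[target]
    assert total == 3000
    assert correct / total >= 0.99
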