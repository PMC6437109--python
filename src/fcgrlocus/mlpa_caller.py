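"""Interpretation of MLPA-style dosage ratios at the FCGR2/3 locus.

MLPA yields per-probe ratios normalized so that 1.0 corresponds to two
target copies.  This module turns those ratios into genotype calls:

* copy number per CNV region (``round(2 x median ratio)`` with a no-call
  margin);
* allele dosages for the directly probed SNP systems;
* FCGR2C haplotype resolution.  The assay measures two sites on FCGR2C —
  the Q57X stop codon (rs759550223; the ``ORFsite`` probe counts copies
  with an open reading frame) and the intron-7 splice mutation
  (rs76277413) — so four internal per-copy states exist: classic ORF
  (open frame, intact splice), nonclassic ORF (open frame, splice mutant),
  Stop(1) (stop codon, intact splice) and Stop(2) (stop codon, splice
  mutant).  Stop(1)/Stop(2) are functionally identical pseudogenes and are
  collapsed to ``Stop`` on output; dosage combinations consistent with more
  than one multiset of states are resolved by maximum posterior under
  population priors and flagged as ambiguous;
* allocation of the sequence-identical promoter haplotypes 2B.2 and 2B.4
  between FCGR2B and FCGR2C (2B.2 belongs to FCGR2C, 2B.4 to FCGR2B;
  overflow spills to the other gene and is flagged);
* exact misclassification-rate estimation for the two rules above by
  frequency-weighted enumeration of all diplotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .locus_model import (
    HaplotypeFrequencyTable,
    IndividualGenotype,
    LocusDefinition,
    default_locus,
)

__all__ = [
    "NoCall",
    "Fcgr2cCall",
    "PromoterAllocation",
    "call_copy_number",
    "resolve_fcgr2c",
    "allocate_promoter",
    "call_genotypes",
    "fcgr2c_chromosome_pool",
    "promoter_chromosome_pool",
    "estimate_misclassification",
    "estimate_misclassification_mc",
    "DEFAULT_FCGR2C_PRIORS",
]

#: internal per-copy FCGR2C states
ORF, NC_ORF, STOP1, STOP2 = "ORF", "NC-ORF", "Stop(1)", "Stop(2)"
_STATES = (ORF, NC_ORF, STOP1, STOP2)

#: European-style default priors over the internal states
DEFAULT_FCGR2C_PRIORS = {ORF: 0.11, NC_ORF: 0.05, STOP1: 0.823, STOP2: 0.017}


class NoCall(Exception):
    """Raised when a dosage ratio is too far from an integer grid point."""


def call_copy_number(ratios: Sequence[float], margin: float = 0.2) -> int:
    """Copy number from dosage ratios: ``round(2 x median)``.

    Raises :class:`NoCall` when the median is farther than ``margin``
    (in copy units) from the nearest integer.
    """
    if len(ratios) == 0:
        raise ValueError("at least one probe ratio is required")
    copies_scale = 2.0 * float(np.median(ratios))
    nearest = round(copies_scale)
    if abs(copies_scale - nearest) > margin:
        raise NoCall(
            f"median dosage {copies_scale / 2:.3f} is {abs(copies_scale - nearest):.2f} "
            f"copies from the nearest integer (margin {margin})"
        )
    return max(int(nearest), 0)


# ---------------------------------------------------------------------------
# FCGR2C haplotype resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fcgr2cCall:
    """Resolved FCGR2C haplotype counts (collapsed Stop)."""

    counts: tuple[tuple[str, int], ...]  # (("ORF", a), ("Stop", s), ("NC-ORF", b))
    ambiguous: bool
    posterior: float

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


def _fcgr2c_configs(n_copies: int, orf_dosage: int, splice_dosage: int):
    """All internal state multisets (a=ORF, b=NC, c=Stop1, d=Stop2) matching
    the observed dosages."""
    configs = []
    for b in range(max(0, orf_dosage + splice_dosage - n_copies), min(orf_dosage, splice_dosage) + 1):
        a = orf_dosage - b
        d = splice_dosage - b
        c = n_copies - a - b - d
        if c >= 0:
            configs.append((a, b, c, d))
    return configs


def _multinomial_weight(cfg: tuple[int, int, int, int], priors: Mapping[str, float]) -> float:
    a, b, c, d = cfg
    n = a + b + c + d
    w = math.factorial(n) / (
        math.factorial(a) * math.factorial(b) * math.factorial(c) * math.factorial(d)
    )
    return (
        w
        * priors.get(ORF, 0.0) ** a
        * priors.get(NC_ORF, 0.0) ** b
        * priors.get(STOP1, 0.0) ** c
        * priors.get(STOP2, 0.0) ** d
    )


def resolve_fcgr2c(
    n_copies: int,
    orf_dosage: int,
    splice_dosage: int,
    priors: Mapping[str, float] | None = None,
) -> Fcgr2cCall:
    """Resolve FCGR2C haplotype counts from the two probed sites.

    Enumerates every multiset of internal per-copy states consistent with
    the gene copy number, the open-reading-frame dosage and the splice-
    mutation dosage.  A unique solution is returned with posterior 1;
    otherwise the maximum-posterior configuration under ``priors`` is
    returned with the ambiguity flag set (ties broken toward more Stop
    copies, the majority haplotype).
    """
    if orf_dosage > n_copies or splice_dosage > n_copies:
        raise ValueError(
            f"dosages (ORF {orf_dosage}, splice {splice_dosage}) exceed "
            f"{n_copies} gene copies"
        )
    if min(n_copies, orf_dosage, splice_dosage) < 0:
        raise ValueError("copy number and dosages must be non-negative")
    priors = dict(priors) if priors else dict(DEFAULT_FCGR2C_PRIORS)
    configs = _fcgr2c_configs(n_copies, orf_dosage, splice_dosage)
    if not configs:  # unreachable for valid dosages; guard anyway
        raise ValueError("no haplotype configuration matches the dosages")

    def collapsed(cfg):
        a, b, c, d = cfg
        return (("ORF", a), ("Stop", c + d), ("NC-ORF", b))

    if len(configs) == 1 or n_copies == 0:
        return Fcgr2cCall(collapsed(configs[0]), ambiguous=False, posterior=1.0)
    weights = [_multinomial_weight(cfg, priors) for cfg in configs]
    total = sum(weights)
    if total <= 0:  # priors exclude every configuration: fall back to uniform
        weights = [1.0] * len(configs)
        total = float(len(configs))
    # maximum posterior; ties toward more Stop copies (smaller b)
    order = sorted(
        range(len(configs)),
        key=lambda i: (-weights[i], configs[i][1], collapsed(configs[i])),
    )
    best = order[0]
    return Fcgr2cCall(
        collapsed(configs[best]), ambiguous=True, posterior=weights[best] / total
    )


# ---------------------------------------------------------------------------
# Promoter allocation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterAllocation:
    fcgr2c: tuple[tuple[str, int], ...]
    fcgr2b: tuple[tuple[str, int], ...]
    ambiguous: bool

    def as_dicts(self) -> tuple[dict[str, int], dict[str, int]]:
        return dict(self.fcgr2c), dict(self.fcgr2b)


def allocate_promoter(
    total_2b2: int,
    total_2b4: int,
    fcgr2b_copies: int = 2,
    fcgr2c_copies: int = 2,
) -> PromoterAllocation:
    """Allocate combined 2B.2/2B.4 promoter dosage between the two genes.

    2B.2 is assigned to FCGR2C and 2B.4 to FCGR2B (the genes in which these
    promoter haplotypes are essentially always found); remaining copies are
    2B.1.  Overflow beyond the target gene's copy number spills to the other
    gene and sets the ambiguity flag.
    """
    if min(total_2b2, total_2b4, fcgr2b_copies, fcgr2c_copies) < 0:
        raise ValueError("counts must be non-negative")
    if total_2b2 + total_2b4 > fcgr2b_copies + fcgr2c_copies:
        raise ValueError(
            f"promoter dosage {total_2b2 + total_2b4} exceeds combined copy "
            f"number {fcgr2b_copies + fcgr2c_copies}"
        )
    c2 = {"2B.1": 0, "2B.2": 0, "2B.4": 0}
    b2 = {"2B.1": 0, "2B.2": 0, "2B.4": 0}
    flagged = False

    c2["2B.2"] = min(total_2b2, fcgr2c_copies)
    spill = total_2b2 - c2["2B.2"]
    if spill:
        b2["2B.2"] = spill
        flagged = True
    room_b = fcgr2b_copies - b2["2B.2"]
    b2["2B.4"] = min(total_2b4, room_b)
    spill = total_2b4 - b2["2B.4"]
    if spill:
        c2["2B.4"] = spill
        flagged = True
    if c2["2B.2"] + c2["2B.4"] > fcgr2c_copies or b2["2B.2"] + b2["2B.4"] > fcgr2b_copies:
        raise ValueError("promoter dosage cannot be placed on the available copies")
    c2["2B.1"] = fcgr2c_copies - c2["2B.2"] - c2["2B.4"]
    b2["2B.1"] = fcgr2b_copies - b2["2B.2"] - b2["2B.4"]
    return PromoterAllocation(
        fcgr2c=tuple(sorted(c2.items())),
        fcgr2b=tuple(sorted(b2.items())),
        ambiguous=flagged,
    )


# ---------------------------------------------------------------------------
# Full calling pipeline over a probe-ratio table
# ---------------------------------------------------------------------------

def call_genotypes(
    probe_table,
    *,
    locus: LocusDefinition | None = None,
    priors: Mapping[str, float] | None = None,
    margin: float = 0.2,
):
    """Call genotypes from a probe-ratio table (``simulate_mlpa`` layout).

    Returns ``(genotypes, flags)`` where ``flags`` maps individual id to a
    list of strings recording no-calls and ambiguity.  Individuals with a
    no-call on any CNV region are skipped entirely (their dosage-sum
    invariants cannot be checked).
    """
    locus = locus or default_locus()
    genotypes: list[IndividualGenotype] = []
    flags: dict[str, list[str]] = {}

    for ind, sub in probe_table.groupby("individual_id", sort=True):
        notes: list[str] = []
        by_target = {t: g["ratio"].to_numpy() for t, g in sub.groupby("target")}

        def dose(target: str) -> int:
            return call_copy_number(by_target.get(target, ()), margin)

        try:
            cnr = {c.id: dose(c.id) for c in locus.cnrs}
        except (NoCall, ValueError) as exc:
            flags[str(ind)] = [f"CNV no-call: {exc}"]
            continue
        probe_geno = IndividualGenotype(id=str(ind), cnr_copies=cnr, dosages={})
        ok = True
        dosages: dict[str, dict[str, int]] = {}
        for vid in ("FCGR2A_H131R", "FCGR2A_Q27W", "FCGR3A_V158F", "FCGR3B_NA", "FCGR2B_I232T"):
            v = locus.variant(vid)
            try:
                d = {a: dose(f"{vid}:{a}") for a in v.alleles}
            except NoCall as exc:
                notes.append(f"{vid} no-call: {exc}")
                ok = False
                continue
            want = probe_geno.gene_copy_number(v.gene, locus)
            if sum(d.values()) != want:
                notes.append(
                    f"{vid} dosages sum to {sum(d.values())}, expected {want}"
                )
                ok = False
            dosages[vid] = d
        n2c = probe_geno.gene_copy_number("FCGR2C", locus)
        try:
            call = resolve_fcgr2c(n2c, dose("FCGR2C:ORFsite"), dose("FCGR2C:splice"), priors)
            if call.ambiguous:
                notes.append(
                    f"FCGR2C ambiguous (posterior {call.posterior:.3f})"
                )
            dosages["FCGR2C"] = dict(call.counts)
        except (NoCall, ValueError) as exc:
            notes.append(f"FCGR2C no-call: {exc}")
            ok = False
        try:
            alloc = allocate_promoter(
                dose("prom:2B.2"), dose("prom:2B.4"), 2, n2c
            )
            if alloc.ambiguous:
                notes.append("promoter allocation ambiguous (overflow)")
            c2, b2 = alloc.as_dicts()
            dosages["FCGR2C_prom"] = c2
            dosages["FCGR2B_prom"] = b2
        except (NoCall, ValueError) as exc:
            notes.append(f"promoter no-call: {exc}")
            ok = False
        if notes:
            flags[str(ind)] = notes
        if not ok:
            continue
        g = IndividualGenotype(id=str(ind), cnr_copies=cnr, dosages=dosages)
        g.validate(locus)
        genotypes.append(g)
    return genotypes, flags


# ---------------------------------------------------------------------------
# Misclassification-rate estimation by exact enumeration
# ---------------------------------------------------------------------------

def fcgr2c_chromosome_pool(
    pool: HaplotypeFrequencyTable, stop_splice_fraction: float = 0.0
) -> list[tuple[tuple[str, ...], float]]:
    """Project a chromosome pool onto internal FCGR2C per-copy states.

    Each collapsed ``Stop`` copy carries the splice mutation (Stop(2)) with
    probability ``stop_splice_fraction``, independently.
    """
    if not 0.0 <= stop_splice_fraction < 1.0:
        raise ValueError("stop_splice_fraction must be in [0, 1)")
    out: dict[tuple[str, ...], float] = {}
    for hap, f in pool:
        alleles = hap.alleles["FCGR2C"]
        stops = [i for i, a in enumerate(alleles) if a == "Stop"]
        others = [ORF if a == "ORF" else NC_ORF for a in alleles if a != "Stop"]
        for k in range(len(stops) + 1):
            w = (
                math.comb(len(stops), k)
                * stop_splice_fraction ** k
                * (1 - stop_splice_fraction) ** (len(stops) - k)
            )
            key = tuple(sorted(others + [STOP2] * k + [STOP1] * (len(stops) - k)))
            if w > 0:
                out[key] = out.get(key, 0.0) + f * w
    return sorted(out.items())


def promoter_chromosome_pool(
    pool: HaplotypeFrequencyTable,
) -> list[tuple[tuple[tuple[str, ...], tuple[str, ...]], float]]:
    """Project a chromosome pool onto (FCGR2C promoter, FCGR2B promoter)."""
    out: dict = {}
    for hap, f in pool:
        key = (hap.alleles["FCGR2C_prom"], hap.alleles["FCGR2B_prom"])
        out[key] = out.get(key, 0.0) + f
    return sorted(out.items())


def _fcgr2c_truth_vs_call(states: tuple[str, ...], priors) -> bool:
    """True if the caller recovers the collapsed truth for these copies."""
    n = len(states)
    orf_dosage = sum(s in (ORF, NC_ORF) for s in states)
    splice = sum(s in (NC_ORF, STOP2) for s in states)
    truth = (
        ("ORF", sum(s == ORF for s in states)),
        ("Stop", sum(s in (STOP1, STOP2) for s in states)),
        ("NC-ORF", sum(s == NC_ORF for s in states)),
    )
    call = resolve_fcgr2c(n, orf_dosage, splice, priors)
    return call.counts == truth


def _promoter_truth_vs_call(c_proms, b_proms) -> bool:
    tot = list(c_proms) + list(b_proms)
    alloc = allocate_promoter(
        tot.count("2B.2"), tot.count("2B.4"), len(b_proms), len(c_proms)
    )
    c2, b2 = alloc.as_dicts()
    truth_c = {a: list(c_proms).count(a) for a in ("2B.1", "2B.2", "2B.4")}
    truth_b = {a: list(b_proms).count(a) for a in ("2B.1", "2B.2", "2B.4")}
    return c2 == truth_c and b2 == truth_b


def estimate_misclassification(
    chrom_pool: Sequence[tuple],
    rule: str = "fcgr2c",
    priors: Mapping[str, float] | None = None,
) -> float:
    """Exact misclassification rate of a calling rule over a diplotype pool.

    ``chrom_pool`` comes from :func:`fcgr2c_chromosome_pool` (``rule=
    'fcgr2c'``) or :func:`promoter_chromosome_pool` (``rule='promoter'``).
    The rate is the exact frequency-weighted probability, over all ordered
    chromosome pairs, that the rule output differs from the true collapsed
    configuration.
    """
    if rule == "fcgr2c" and priors is None:
        # derive per-copy priors from the pool itself
        marg = {s: 0.0 for s in _STATES}
        copies = 0.0
        for states, f in chrom_pool:
            for s in states:
                marg[s] += f
            copies += f * len(states)
        priors = {s: marg[s] / copies for s in _STATES} if copies else DEFAULT_FCGR2C_PRIORS
    rate = 0.0
    for states1, f1 in chrom_pool:
        for states2, f2 in chrom_pool:
            w = f1 * f2
            if w == 0.0:
                continue
            if rule == "fcgr2c":
                good = _fcgr2c_truth_vs_call(tuple(states1) + tuple(states2), priors)
            elif rule == "promoter":
                good = _promoter_truth_vs_call(
                    states1[0] + states2[0], states1[1] + states2[1]
                )
            else:
                raise ValueError(f"unknown rule {rule!r}")
            if not good:
                rate += w
    return rate


def estimate_misclassification_mc(
    chrom_pool,
    rule: str = "fcgr2c",
    priors: Mapping[str, float] | None = None,
    n: int = 100_000,
    seed=None,
) -> float:
    """Monte-Carlo twin of :func:`estimate_misclassification`."""
    rng = np.random.default_rng(seed)
    keys = [k for k, _ in chrom_pool]
    freqs = np.array([f for _, f in chrom_pool])
    freqs = freqs / freqs.sum()
    if rule == "fcgr2c" and priors is None:
        marg = {s: 0.0 for s in _STATES}
        copies = 0.0
        for states, f in chrom_pool:
            for s in states:
                marg[s] += f
            copies += f * len(states)
        priors = {s: marg[s] / copies for s in _STATES}
    idx = rng.choice(len(keys), size=(n, 2), p=freqs)
    bad = 0
    for i, j in idx:
        if rule == "fcgr2c":
            good = _fcgr2c_truth_vs_call(tuple(keys[i]) + tuple(keys[j]), priors)
        else:
            good = _promoter_truth_vs_call(
                keys[i][0] + keys[j][0], keys[i][1] + keys[j][1]
            )
        bad += not good
    return bad / n
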