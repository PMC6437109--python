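"""Synthetic cohorts with the statistical structure of the FCGR2/3 locus.

The generator produces chromosome-level haplotype pools whose copy-number-
aware allele frequencies match requested marginals and whose pairwise
linkage disequilibrium on the CNV-free background matches requested r²
values, then samples diploid populations, case-control datasets (additive
logistic disease model), parent-offspring trios ascertained on an affected
child, and noisy MLPA probe-ratio tables.

Pool construction
-----------------
The allele background of a no-CNV chromosome is a joint distribution over
the eight variant systems, fitted by iterative proportional fitting (IPF):
marginal constraints per system plus a 2x2 constraint per requested r²
target (allele-vs-rest collapse, positive-D orientation).  CNV chromosomes
are attached as separate classes — at most one aberrant CNV region per
chromosome, a good approximation at the observed CNV rates — with the
allele content of the extra copy of a duplicated region drawn from a
configurable profile.  The default European profile puts the nonclassic
FCGR2C-ORF haplotype and FCGR3B-SH preferentially on duplicated CNR1
chromosomes, reproducing the strong association between increased CNR1
copy number and those alleles.  Base-copy allele frequencies are corrected
for the CNV classes so that the copy-number-aware marginals of the full
pool match the requested values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import yaml

from .locus_model import (
    ChromosomeHaplotype,
    HaplotypeFrequencyTable,
    IndividualGenotype,
    LocusDefinition,
    combine_chromosomes,
    default_locus,
)

__all__ = [
    "LDTarget",
    "DiseaseModel",
    "build_pool",
    "default_pool",
    "load_population_config",
    "sample_population",
    "sample_case_control",
    "sample_trios",
    "simulate_mlpa",
    "PROBE_TARGETS",
]


@dataclass(frozen=True)
class LDTarget:
    """Pairwise r² target between two allele-vs-rest collapses (D > 0)."""

    variant_a: str
    allele_a: str
    variant_b: str
    allele_b: str
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 target must be in [0, 1]")


@dataclass
class DiseaseModel:
    """Additive log-odds disease model.

    ``log_or`` maps ``(variant_id, allele)`` to the per-copy log odds ratio;
    disease probability is ``expit(logit(prevalence) + sum(dose * logOR))``.
    """

    log_or: dict[tuple[str, str], float] = field(default_factory=dict)
    prevalence: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        for k, b in self.log_or.items():
            if not math.isfinite(b):
                raise ValueError(f"non-finite log odds ratio for {k}")

    @property
    def is_null(self) -> bool:
        return all(b == 0.0 for b in self.log_or.values())

    def risk(self, genotype: IndividualGenotype) -> float:
        eta = math.log(self.prevalence / (1.0 - self.prevalence))
        for (vid, allele), b in self.log_or.items():
            eta += genotype.dosage(vid, allele) * b
        return 1.0 / (1.0 + math.exp(-eta))


# ---------------------------------------------------------------------------
# Feasibility / closed-form two-locus haplotype frequency
# ---------------------------------------------------------------------------

def _target_pab(p_a: float, p_b: float, r2: float, clamp: bool) -> tuple[float, float]:
    """Return (pAB, attained r²) for a positive-D r² target.

    Solves r² = D²/(pA qA pB qB) with D = pAB - pA pB > 0.  If the target
    exceeds the Lewontin maximum, either raise (default) or clamp to the
    D' = 1 boundary.
    """
    qa, qb = 1.0 - p_a, 1.0 - p_b
    if min(p_a, qa, p_b, qb) <= 0.0:
        if r2 == 0.0:
            return p_a * p_b, 0.0
        raise ValueError("r2 target involves a monomorphic collapse")
    denom = p_a * qa * p_b * qb
    d_max = min(p_a, p_b) - p_a * p_b
    r2_max = d_max * d_max / denom
    if r2 > r2_max + 1e-12:
        if not clamp:
            raise ValueError(
                f"r2 target {r2:.4g} infeasible for marginals "
                f"({p_a:.4g}, {p_b:.4g}); feasible maximum is {r2_max:.4g}"
            )
        return p_a * p_b + d_max, r2_max
    d = math.sqrt(r2 * denom)
    return p_a * p_b + d, r2


# ---------------------------------------------------------------------------
# IPF over the no-CNV allele background
# ---------------------------------------------------------------------------

def _ipf_joint(
    locus: LocusDefinition,
    marginals: dict[str, dict[str, float]],
    targets: Sequence[LDTarget],
    clamp: bool,
    max_iter: int,
    tol: float,
) -> np.ndarray:
    vids = [v.id for v in locus.variants]
    shapes = [len(v.alleles) for v in locus.variants]
    margs = []
    for v in locus.variants:
        m = np.array([marginals[v.id].get(a, 0.0) for a in v.alleles], float)
        if abs(m.sum() - 1.0) > 1e-6 or (m < 0).any():
            raise ValueError(f"marginals for {v.id} must be non-negative and sum to 1")
        margs.append(m / m.sum())

    joint = np.ones(shapes)
    for ax, m in enumerate(margs):
        joint *= m.reshape([-1 if i == ax else 1 for i in range(len(shapes))])

    # resolve each target to a 2x2 block-mass constraint
    pair_specs = []
    for t in targets:
        ax_a, ax_b = vids.index(t.variant_a), vids.index(t.variant_b)
        ia = locus.variants[ax_a].alleles.index(t.allele_a)
        ib = locus.variants[ax_b].alleles.index(t.allele_b)
        p_a, p_b = margs[ax_a][ia], margs[ax_b][ib]
        pab, r2_eff = _target_pab(p_a, p_b, t.r2, clamp)
        want = np.array(
            [[1.0 - p_a - p_b + pab, p_b - pab], [p_a - pab, pab]], float
        )
        pair_specs.append((ax_a, ia, ax_b, ib, want, r2_eff, p_a, p_b))

    def block_masses(ax_a, ia, ax_b, ib):
        out = np.empty((2, 2))
        for sa in (0, 1):
            for sb in (0, 1):
                sub = joint
                idx_a = [ia] if sa else [k for k in range(shapes[ax_a]) if k != ia]
                idx_b = [ib] if sb else [k for k in range(shapes[ax_b]) if k != ib]
                sub = np.take(sub, idx_a, axis=ax_a)
                sub = np.take(sub, idx_b, axis=ax_b)
                out[sa, sb] = sub.sum()
        return out

    axes_all = tuple(range(len(shapes)))
    for _ in range(max_iter):
        for ax_a, ia, ax_b, ib, want, _, _, _ in pair_specs:
            have = block_masses(ax_a, ia, ax_b, ib)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(have > 0, want / np.where(have > 0, have, 1.0), 0.0)
            if ((have <= 0) & (want > 1e-12)).any():
                raise ValueError("IPF: a required haplotype class has zero support")
            sel_a = np.zeros(shapes[ax_a], dtype=int)
            sel_a[ia] = 1
            sel_b = np.zeros(shapes[ax_b], dtype=int)
            sel_b[ib] = 1
            fa = sel_a.reshape([-1 if i == ax_a else 1 for i in range(len(shapes))])
            fb = sel_b.reshape([-1 if i == ax_b else 1 for i in range(len(shapes))])
            joint *= ratio[fa, fb]
        for ax, m in enumerate(margs):
            cur = joint.sum(axis=tuple(a for a in axes_all if a != ax))
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(cur > 0, m / np.where(cur > 0, cur, 1.0), 0.0)
            joint *= f.reshape([-1 if i == ax else 1 for i in range(len(shapes))])
        # convergence on attained r2 and on marginal accuracy (sequential
        # marginal fits perturb earlier axes)
        worst = 0.0
        for ax, m in enumerate(margs):
            cur = joint.sum(axis=tuple(a for a in axes_all if a != ax))
            worst = max(worst, float(np.abs(cur - m).max()) * (tol / 1e-7))
        for ax_a, ia, ax_b, ib, _, r2_eff, _, _ in pair_specs:
            have = block_masses(ax_a, ia, ax_b, ib)
            p_a, p_b = have[1].sum(), have[:, 1].sum()
            d = have[1, 1] - p_a * p_b
            denom = p_a * (1 - p_a) * p_b * (1 - p_b)
            r2_cur = d * d / denom if denom > 0 else 0.0
            worst = max(worst, abs(r2_cur - r2_eff))
        if worst < tol:
            break
    else:
        raise RuntimeError(
            f"IPF did not reach r2 tolerance {tol} within {max_iter} iterations "
            f"(residual {worst:.3g}); targets may be jointly infeasible"
        )
    return joint / joint.sum()


# ---------------------------------------------------------------------------
# CNV classes and base-copy marginal correction
# ---------------------------------------------------------------------------

def _cnv_classes(
    locus: LocusDefinition, cnr_freqs: Mapping[str, Mapping[int, float]] | None
):
    """(cnr_copies, weight, dup_cnr) per chromosome class; one aberrant CNR max."""
    baseline = {c.id: 1 for c in locus.cnrs}
    if not cnr_freqs:
        return [(dict(baseline), 1.0, None)]
    classes = []
    w_aberrant = 0.0
    for cnr in locus.cnrs:
        dist = cnr_freqs.get(cnr.id, {1: 1.0})
        for copies, w in sorted(dist.items()):
            copies = int(copies)
            if copies == 1 or w <= 0:
                continue
            if not 0 <= copies <= 2:
                raise ValueError(f"per-chromosome copies of {cnr.id} must be 0..2")
            cc = dict(baseline)
            cc[cnr.id] = copies
            classes.append((cc, float(w), cnr.id if copies == 2 else None))
            w_aberrant += w
    if w_aberrant >= 1.0:
        raise ValueError("aberrant-chromosome frequencies sum to >= 1")
    classes.insert(0, (dict(baseline), 1.0 - w_aberrant, None))
    return classes


def _chrom_gene_copies(locus: LocusDefinition, cnr_copies: Mapping[str, int], gene: str) -> int:
    return 1 + sum(cnr_copies[c.id] - 1 for c in locus.cnrs_containing(gene))


def _correct_marginals(
    locus: LocusDefinition,
    marginals: dict[str, dict[str, float]],
    classes,
    dup_profiles: Mapping[str, Mapping[str, Mapping[str, float]]],
) -> dict[str, dict[str, float]]:
    """Solve base-copy allele frequencies so that the copy-number-aware
    marginals of the assembled pool equal the requested values."""
    out: dict[str, dict[str, float]] = {}
    for v in locus.variants:
        w_base = e_copies = 0.0
        extra = {a: 0.0 for a in v.alleles}
        for cnr_copies, w, dup_cnr in classes:
            n = _chrom_gene_copies(locus, cnr_copies, v.gene)
            e_copies += w * n
            if n >= 1:
                w_base += w
            if n == 2 and dup_cnr is not None:
                profile = dup_profiles.get(dup_cnr, {}).get(v.id)
                if profile is None:
                    profile = marginals[v.id]
                tot = sum(profile.values())
                for a, p in profile.items():
                    extra[a] += w * p / tot
        corrected = {}
        for a in v.alleles:
            t = marginals[v.id].get(a, 0.0)
            j = (t * e_copies - extra[a]) / w_base
            if j < -1e-9:
                raise ValueError(
                    f"duplication profile for {v.id}:{a} exceeds the requested "
                    f"overall frequency {t}"
                )
            corrected[a] = max(j, 0.0)
        out[v.id] = corrected
    return out


# ---------------------------------------------------------------------------
# build_pool
# ---------------------------------------------------------------------------

def build_pool(
    marginals: Mapping[str, Mapping[str, float]],
    ld_targets: Sequence[LDTarget] = (),
    cnr_freqs: Mapping[str, Mapping[int, float]] | None = None,
    *,
    dup_profiles: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None,
    locus: LocusDefinition | None = None,
    clamp_infeasible: bool = False,
    max_iter: int = 1000,
    tol: float = 1e-4,
    prune: float = 1e-15,
) -> HaplotypeFrequencyTable:
    """Construct a chromosome-level haplotype pool.

    Parameters
    ----------
    marginals
        Copy-number-aware allele frequencies per variant system (each sums
        to 1).
    ld_targets
        Pairwise r² targets on the CNV-free background; infeasible targets
        raise (reporting the feasible maximum) unless ``clamp_infeasible``.
    cnr_freqs
        Per-chromosome CNV-region copy distributions (1 = no CNV).
    dup_profiles
        ``{cnr: {variant: {allele: prob}}}`` allele distribution of the
        extra gene copy on duplicated chromosomes; defaults to the variant's
        marginal distribution.
    """
    locus = locus or default_locus()
    marginals = {k: dict(v) for k, v in marginals.items()}
    for v in locus.variants:
        if v.id not in marginals:
            raise ValueError(f"missing marginals for variant {v.id}")
    targets = [t if isinstance(t, LDTarget) else LDTarget(*t) for t in ld_targets]
    dup_profiles = dup_profiles or {}

    classes = _cnv_classes(locus, cnr_freqs)
    base_marg = (
        _correct_marginals(locus, marginals, classes, dup_profiles)
        if len(classes) > 1
        else marginals
    )
    joint = _ipf_joint(locus, base_marg, targets, clamp_infeasible, max_iter, tol)

    vids = [v.id for v in locus.variants]
    allele_lists = [v.alleles for v in locus.variants]
    entries: dict[ChromosomeHaplotype, float] = {}
    nz = np.argwhere(joint > prune)
    for cnr_copies, w_class, dup_cnr in classes:
        # variants needing an extra-copy allele on this class
        extra_vars: list[tuple[int, list[tuple[str, float]]]] = []
        for i, v in enumerate(locus.variants):
            if _chrom_gene_copies(locus, cnr_copies, v.gene) == 2:
                profile = (dup_profiles.get(dup_cnr, {}) or {}).get(v.id) or marginals[v.id]
                tot = sum(profile.values())
                extra_vars.append(
                    (i, [(a, p / tot) for a, p in profile.items() if p > 0])
                )
        for idx in nz:
            base_f = float(joint[tuple(idx)]) * w_class
            base_alleles = [allele_lists[i][idx[i]] for i in range(len(vids))]
            for combo in product(*[opts for _, opts in extra_vars]):
                f = base_f
                alleles: dict[str, tuple[str, ...]] = {}
                extras = {extra_vars[k][0]: combo[k] for k in range(len(combo))}
                for i, v in enumerate(locus.variants):
                    n = _chrom_gene_copies(locus, cnr_copies, v.gene)
                    if n == 0:
                        alleles[v.id] = ()
                    elif n == 1:
                        alleles[v.id] = (base_alleles[i],)
                    else:
                        a_extra, p = extras[i]
                        f *= p
                        alleles[v.id] = (base_alleles[i], a_extra)
                if f <= prune:
                    continue
                hap = ChromosomeHaplotype(cnr_copies, alleles, locus)
                entries[hap] = entries.get(hap, 0.0) + f
    return HaplotypeFrequencyTable.normalized(entries)


# ---------------------------------------------------------------------------
# Packaged population defaults
# ---------------------------------------------------------------------------

_POP_CACHE: dict[str, HaplotypeFrequencyTable] = {}


def load_population_config(population: str = "EUR") -> dict:
    with resources.files("fcgrlocus.data").joinpath("populations.yaml").open("rt") as fh:
        cfgs = yaml.safe_load(fh)
    if population not in cfgs:
        raise KeyError(f"unknown population {population!r}; choose from {sorted(cfgs)}")
    return cfgs[population]


def default_pool(population: str = "EUR") -> HaplotypeFrequencyTable:
    """The packaged default pool for ``EUR``, ``CHN`` or ``AFR``.

    Published r² values that sit marginally above the Lewontin maximum at
    the published rounded allele frequencies are clamped to the D'=1
    boundary.
    """
    if population not in _POP_CACHE:
        cfg = load_population_config(population)
        _POP_CACHE[population] = build_pool(
            cfg["marginals"],
            [LDTarget(*t) for t in cfg.get("ld_targets", [])],
            cfg.get("cnr_chrom_freqs"),
            dup_profiles=cfg.get("dup_profiles"),
            clamp_infeasible=True,
        )
    return _POP_CACHE[population]


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_population(
    pool: HaplotypeFrequencyTable,
    n: int,
    seed=None,
    *,
    locus: LocusDefinition | None = None,
    keep_truth: bool = False,
    id_prefix: str = "S",
):
    """Sample ``n`` diploid individuals (two independent chromosomes each)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(pool) == 0:
        raise ValueError("empty pool")
    locus = locus or default_locus()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = pool.sample(rng, 2 * n)
    genotypes, truth = [], []
    for i in range(n):
        h1, h2 = chroms[2 * i], chroms[2 * i + 1]
        genotypes.append(combine_chromosomes(h1, h2, f"{id_prefix}{i + 1:05d}", locus))
        if keep_truth:
            truth.append((h1, h2))
    return (genotypes, truth) if keep_truth else genotypes


def sample_case_control(
    pool: HaplotypeFrequencyTable,
    model: DiseaseModel,
    n_case: int,
    n_control: int,
    seed=None,
    *,
    locus: LocusDefinition | None = None,
    max_draw_factor: int = 2000,
):
    """Rejection-sample cases and controls under the additive model.

    Individuals are drawn from the pool; each is a case with probability
    ``model.risk`` and a control otherwise, until both quotas are filled.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("case and control counts must be >= 1")
    locus = locus or default_locus()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cases: list[IndividualGenotype] = []
    controls: list[IndividualGenotype] = []
    max_draws = max_draw_factor * (n_case + n_control)
    drawn = 0
    batch = max(256, n_case + n_control)
    while len(cases) < n_case or len(controls) < n_control:
        if drawn >= max_draws:
            raise RuntimeError(
                f"case-control sampling did not fill quotas within {max_draws} "
                "draws; prevalence too extreme for the requested counts"
            )
        m = min(batch, max_draws - drawn)
        drawn += m
        inds = sample_population(pool, m, rng, locus=locus, id_prefix="T")
        u = rng.random(m)
        for g, ui in zip(inds, u):
            if ui < model.risk(g):
                if len(cases) < n_case:
                    g.id = f"CASE{len(cases) + 1:05d}"
                    cases.append(g)
            elif len(controls) < n_control:
                g.id = f"CTRL{len(controls) + 1:05d}"
                controls.append(g)
    return cases, controls


def sample_trios(
    pool: HaplotypeFrequencyTable,
    model: DiseaseModel | None,
    n_trios: int,
    seed=None,
    *,
    locus: LocusDefinition | None = None,
    max_draw_factor: int = 2000,
):
    """Sample parent-offspring trios ascertained on an affected child.

    Parents are two random pool chromosomes each; the child receives one
    uniformly chosen chromosome per parent and is retained with probability
    equal to its disease probability.  Under a null model transmissions are
    unbiased, so ascertainment is skipped for speed.

    Returns a list of :class:`fcgrlocus.family_tdt.Trio` with true phase
    retained in :attr:`truth`.
    """
    from .family_tdt import Trio, TrioTruth

    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    locus = locus or default_locus()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = model is None or model.is_null
    trios: list[Trio] = []
    attempts = 0
    max_attempts = max_draw_factor * n_trios
    while len(trios) < n_trios:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"trio sampling did not reach {n_trios} affected children within "
                f"{max_attempts} attempts"
            )
        m = min(max(256, n_trios), max_attempts - attempts)
        attempts += m
        chroms = pool.sample(rng, 4 * m)
        pick = rng.integers(0, 2, size=(m, 2))
        u = rng.random(m)
        for i in range(m):
            if len(trios) >= n_trios:
                break
            f1, f2, m1, m2 = chroms[4 * i: 4 * i + 4]
            tf, tm = int(pick[i, 0]), int(pick[i, 1])
            child = combine_chromosomes((f1, f2)[tf], (m1, m2)[tm], "", locus)
            if not null and u[i] >= (model.risk(child) if model else 1.0):
                continue
            k = len(trios) + 1
            fam = f"FAM{k:04d}"
            father = combine_chromosomes(f1, f2, f"{fam}_F", locus)
            mother = combine_chromosomes(m1, m2, f"{fam}_M", locus)
            child.id = f"{fam}_C"
            trios.append(
                Trio(
                    family_id=fam,
                    father=father,
                    mother=mother,
                    child=child,
                    truth=TrioTruth(
                        father_haplotypes=(f1, f2),
                        mother_haplotypes=(m1, m2),
                        transmitted=(tf, tm),
                    ),
                )
            )
    return trios


# ---------------------------------------------------------------------------
# MLPA probe-ratio simulation
# ---------------------------------------------------------------------------

#: variant systems read out directly by allele-specific probes
_DIRECT_VARIANTS = ("FCGR2A_H131R", "FCGR2A_Q27W", "FCGR3A_V158F",
                    "FCGR3B_NA", "FCGR2B_I232T")

PROBE_TARGETS = (
    "CNR1", "CNR2", "CNR3",
    "FCGR2A_H131R:H", "FCGR2A_H131R:R",
    "FCGR2A_Q27W:Q", "FCGR2A_Q27W:W",
    "FCGR3A_V158F:V", "FCGR3A_V158F:F",
    "FCGR3B_NA:NA1", "FCGR3B_NA:NA2", "FCGR3B_NA:SH",
    "FCGR2B_I232T:I", "FCGR2B_I232T:T",
    "FCGR2C:ORFsite", "FCGR2C:splice",
    "prom:2B.1", "prom:2B.2", "prom:2B.4",
)


def simulate_mlpa(
    individuals: Sequence[IndividualGenotype],
    noise_sd: float = 0.0,
    seed=None,
    *,
    locus: LocusDefinition | None = None,
    splice_on_stop: Mapping[str, int] | None = None,
    probes_per_cnr: int = 2,
    probes_per_allele: int = 2,
):
    """Simulate normalized MLPA probe ratios (1.0 = two target copies).

    Probes mirror the real assay's information content: copy-number
    reference probes per CNV region; allele-specific probes for the SNP
    systems; an open-reading-frame probe (counting classic plus nonclassic
    ORF copies) and a splice-site-mutation probe (counting nonclassic ORF
    plus any Stop(2) copies, see ``splice_on_stop``) for FCGR2C; and
    promoter probes that see the combined FCGR2B+FCGR2C dosage, since the
    paralogous promoters are sequence-identical.

    Returns a :class:`pandas.DataFrame` with columns
    ``individual_id, probe_id, target, ratio``.
    """
    import pandas as pd

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    locus = locus or default_locus()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    splice_on_stop = splice_on_stop or {}

    rows: list[tuple[str, str, str, float]] = []
    for g in individuals:
        def emit(probe_id: str, target: str, dosage: float, n_probes: int) -> None:
            for k in range(n_probes):
                rows.append((g.id, f"{probe_id}_{k + 1}", target, dosage / 2.0))

        for cnr in locus.cnrs:
            emit(f"{cnr.id}_ref", cnr.id, g.cnr_copies.get(cnr.id, 2), probes_per_cnr)
        for vid in _DIRECT_VARIANTS:
            v = locus.variant(vid)
            for a in v.alleles:
                emit(f"{vid}_{a}", f"{vid}:{a}", g.dosage(vid, a), probes_per_allele)
        orf_site = g.dosage("FCGR2C", "ORF") + g.dosage("FCGR2C", "NC-ORF")
        splice = g.dosage("FCGR2C", "NC-ORF") + splice_on_stop.get(g.id, 0)
        emit("FCGR2C_ORFsite", "FCGR2C:ORFsite", orf_site, probes_per_allele)
        emit("FCGR2C_splice", "FCGR2C:splice", splice, probes_per_allele)
        for a in ("2B.1", "2B.2", "2B.4"):
            total = g.dosage("FCGR2C_prom", a) + g.dosage("FCGR2B_prom", a)
            emit(f"prom_{a}", f"prom:{a}", total, probes_per_allele)

    df = pd.DataFrame(rows, columns=["individual_id", "probe_id", "target", "ratio"])
    if noise_sd > 0:
        df["ratio"] = df["ratio"] + rng.normal(0.0, noise_sd, size=len(df))
    return df
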