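"""Abstract model of the FCGR2/3 locus.

The low-affinity Fc-gamma-receptor locus at 1q23.3 carries five genes
(FCGR2A, FCGR3A, FCGR2C, FCGR3B, FCGR2B) inside a segmental duplication.
Copy number variation at the locus occurs in blocks of genes called copy
number regions (CNRs): CNR1 spans FCGR3B+FCGR2C, CNR2 and CNR3 each span
FCGR3A+FCGR2C.  The locus is modelled abstractly as genes, CNRs and variant
systems; base-pair coordinates play no role.

Two levels of description are used throughout the package:

* :class:`ChromosomeHaplotype` — one parental chromosome: how many copies of
  each CNR it carries (0, 1 or 2; 1 is the no-CNV baseline) and which allele
  each gene copy carries for every variant system.
* :class:`IndividualGenotype` — the unphased sum over the two chromosomes:
  total copy number per CNR and an integer allele-dosage map per variant.

The invariant linking the two is the dosage-sum rule: for every variant the
allele dosages sum to the gene copy number, which equals
``2 + sum over CNRs containing the gene of (CNR copies - 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import yaml

__all__ = [
    "VariantDef",
    "CNRDef",
    "LocusDefinition",
    "ChromosomeHaplotype",
    "IndividualGenotype",
    "HaplotypeFrequencyTable",
    "gene_copy_number",
    "combine_chromosomes",
    "haplotype_label",
    "default_locus",
    "load_locus",
]


# ---------------------------------------------------------------------------
# Locus definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantDef:
    """A variant system: a SNP or a small haplotype system within one gene.

    ``alleles`` is ordered; the order is used for canonical chromosome-level
    labels (e.g. ``V`` before ``F`` so a duplicated FCGR3A chromosome reads
    ``VF``, and ``NA1`` before ``NA2`` gives ``NA1-NA2``).
    """

    id: str
    gene: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) < 2:
            raise ValueError(f"variant {self.id!r} needs >=2 alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"variant {self.id!r} has duplicate allele labels")


@dataclass(frozen=True)
class CNRDef:
    """A copy number region: a block of genes deleted/duplicated as a unit."""

    id: str
    genes: frozenset[str]
    copy_range: tuple[int, int] = (0, 4)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"CNR {self.id!r} must contain at least one gene")
        if self.copy_range[0] < 0:
            raise ValueError(f"CNR {self.id!r} copy range lower bound must be >= 0")


@dataclass(frozen=True)
class LocusDefinition:
    genes: tuple[str, ...]
    cnrs: tuple[CNRDef, ...]
    variants: tuple[VariantDef, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene names must be unique")
        for cnr in self.cnrs:
            unknown = cnr.genes - set(self.genes)
            if unknown:
                raise ValueError(f"CNR {cnr.id} contains unknown genes {sorted(unknown)}")
        for v in self.variants:
            if v.gene not in self.genes:
                raise ValueError(f"variant {v.id} is on unknown gene {v.gene!r}")

    def variant(self, variant_id: str) -> VariantDef:
        for v in self.variants:
            if v.id == variant_id:
                return v
        raise KeyError(f"unknown variant {variant_id!r}")

    def cnr(self, cnr_id: str) -> CNRDef:
        for c in self.cnrs:
            if c.id == cnr_id:
                return c
        raise KeyError(f"unknown CNR {cnr_id!r}")

    def cnrs_containing(self, gene: str) -> tuple[CNRDef, ...]:
        if gene not in self.genes:
            raise KeyError(f"unknown gene {gene!r}")
        return tuple(c for c in self.cnrs if gene in c.genes)

    def variants_on(self, gene: str) -> tuple[VariantDef, ...]:
        return tuple(v for v in self.variants if v.gene == gene)


def load_locus(source) -> LocusDefinition:
    """Read a locus definition from a YAML mapping, path or file object."""
    if isinstance(source, Mapping):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    return LocusDefinition(
        genes=tuple(doc["genes"]),
        cnrs=tuple(
            CNRDef(
                id=c["id"],
                genes=frozenset(c["genes"]),
                copy_range=tuple(c.get("copy_range", (0, 4))),
            )
            for c in doc["cnrs"]
        ),
        variants=tuple(
            VariantDef(id=v["id"], gene=v["gene"], alleles=tuple(str(a) for a in v["alleles"]))
            for v in doc["variants"]
        ),
    )


_DEFAULT_LOCUS: LocusDefinition | None = None


def default_locus() -> LocusDefinition:
    """The packaged FCGR2/3 locus definition (5 genes, 3 CNRs, 8 systems)."""
    global _DEFAULT_LOCUS
    if _DEFAULT_LOCUS is None:
        with resources.files("fcgrlocus.data").joinpath("fcgr23_locus.yaml").open("rt") as fh:
            _DEFAULT_LOCUS = load_locus(fh)
    return _DEFAULT_LOCUS


# ---------------------------------------------------------------------------
# Chromosome-level haplotypes
# ---------------------------------------------------------------------------

class ChromosomeHaplotype:
    """One parental chromosome of the locus.

    Parameters
    ----------
    cnr_copies
        Copies of each CNR on this single chromosome (0, 1 or 2;
        1 = no CNV).  CNRs not listed default to 1.
    alleles
        Per variant system, the alleles carried by the gene copies on this
        chromosome, one label per copy (empty tuple if the gene is deleted).
    locus
        Used to canonicalise the allele order and validate copy counts.
    """

    __slots__ = ("cnr_copies", "alleles", "_key")

    def __init__(
        self,
        cnr_copies: Mapping[str, int],
        alleles: Mapping[str, Sequence[str]],
        locus: LocusDefinition | None = None,
    ) -> None:
        locus = locus or default_locus()
        self.cnr_copies: dict[str, int] = {c.id: int(cnr_copies.get(c.id, 1)) for c in locus.cnrs}
        for cid, n in self.cnr_copies.items():
            if not 0 <= n <= 2:
                raise ValueError(f"per-chromosome copies of {cid} must be 0..2, got {n}")
        self.alleles: dict[str, tuple[str, ...]] = {}
        for v in locus.variants:
            got = tuple(alleles.get(v.id, ()))
            bad = set(got) - set(v.alleles)
            if bad:
                raise ValueError(f"unknown alleles {sorted(bad)} for variant {v.id}")
            want = self.gene_copies(v.gene, locus)
            if len(got) != want:
                raise ValueError(
                    f"variant {v.id}: {len(got)} alleles given but gene {v.gene} "
                    f"has {want} copies on this chromosome"
                )
            order = {a: i for i, a in enumerate(v.alleles)}
            self.alleles[v.id] = tuple(sorted(got, key=order.__getitem__))
        self._key = (
            tuple(sorted(self.cnr_copies.items())),
            tuple(sorted(self.alleles.items())),
        )

    def gene_copies(self, gene: str, locus: LocusDefinition | None = None) -> int:
        """Copies of ``gene`` on this chromosome: 1 + sum(CNR copies - 1)."""
        locus = locus or default_locus()
        n = 1 + sum(self.cnr_copies[c.id] - 1 for c in locus.cnrs_containing(gene))
        if n < 0:
            raise ValueError(f"negative copy count for {gene}")
        return n

    def label(self, variant_id: str) -> str:
        """Chromosome-level allele label: ``–`` if deleted, ``VF`` / ``NA1-NA2``
        style concatenation for duplications."""
        return haplotype_label(self, variant_id)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromosomeHaplotype) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        cn = ",".join(f"{k}={v}" for k, v in sorted(self.cnr_copies.items()) if v != 1)
        al = ";".join(f"{k}:{self.label(k)}" for k in sorted(self.alleles))
        return f"ChromosomeHaplotype({cn or 'baseline'}; {al})"


DELETED_LABEL = "–"


def haplotype_label(hap: ChromosomeHaplotype, variant_id: str) -> str:
    """Label of a chromosome for one variant system, as used in TDT tables."""
    if variant_id in hap.cnr_copies:  # CNR copy count used as an allele itself
        return str(hap.cnr_copies[variant_id])
    alleles = hap.alleles[variant_id]
    if not alleles:
        return DELETED_LABEL
    sep = "" if all(len(a) == 1 for a in alleles) else "-"
    return sep.join(alleles)


# ---------------------------------------------------------------------------
# Unphased individual genotypes
# ---------------------------------------------------------------------------

@dataclass
class IndividualGenotype:
    """Unphased per-individual record: CNR totals plus allele-dosage maps."""

    id: str
    cnr_copies: dict[str, int]
    dosages: dict[str, dict[str, int]]

    def gene_copy_number(self, gene: str, locus: LocusDefinition | None = None) -> int:
        return gene_copy_number(self, gene, locus)

    def dosage(self, variant_id: str, allele: str) -> int:
        return self.dosages.get(variant_id, {}).get(allele, 0)

    def validate(self, locus: LocusDefinition | None = None) -> None:
        locus = locus or default_locus()
        for cid, n in self.cnr_copies.items():
            locus.cnr(cid)
            if n < 0:
                raise ValueError(f"{self.id}: negative copy number for {cid}")
        for v in locus.variants:
            dose = self.dosages.get(v.id, {})
            bad = set(dose) - set(v.alleles)
            if bad:
                raise ValueError(f"{self.id}: unknown alleles {sorted(bad)} for {v.id}")
            if any(d < 0 for d in dose.values()):
                raise ValueError(f"{self.id}: negative dosage for {v.id}")
            total = sum(dose.values())
            want = gene_copy_number(self, v.gene, locus)
            if total != want:
                raise ValueError(
                    f"{self.id}: dosages for {v.id} sum to {total} but gene "
                    f"{v.gene} has {want} copies"
                )


def gene_copy_number(
    genotype: IndividualGenotype, gene: str, locus: LocusDefinition | None = None
) -> int:
    """Total copies of ``gene`` in an individual.

    Equal to ``2 + sum over CNRs containing the gene of (CNR copies - 2)``;
    genes outside every CNR (FCGR2A, FCGR2B) always have 2 copies.
    """
    locus = locus or default_locus()
    if gene not in locus.genes:
        raise KeyError(f"unknown gene {gene!r}")
    n = 2
    for cnr in locus.cnrs_containing(gene):
        n += genotype.cnr_copies.get(cnr.id, 2) - 2
    if n < 0:
        raise ValueError(f"{genotype.id}: negative copy number for {gene}")
    return n


def combine_chromosomes(
    h1: ChromosomeHaplotype,
    h2: ChromosomeHaplotype,
    individual_id: str = "",
    locus: LocusDefinition | None = None,
) -> IndividualGenotype:
    """Element-wise sum of two chromosomes into an unphased genotype."""
    locus = locus or default_locus()
    if set(h1.alleles) != set(h2.alleles) or set(h1.cnr_copies) != set(h2.cnr_copies):
        raise ValueError("chromosomes are defined on different loci")
    cnr = {cid: h1.cnr_copies[cid] + h2.cnr_copies[cid] for cid in h1.cnr_copies}
    dosages: dict[str, dict[str, int]] = {}
    for v in locus.variants:
        d: dict[str, int] = {}
        for a in h1.alleles[v.id] + h2.alleles[v.id]:
            d[a] = d.get(a, 0) + 1
        dosages[v.id] = d
    g = IndividualGenotype(id=individual_id, cnr_copies=cnr, dosages=dosages)
    g.validate(locus)
    return g


# ---------------------------------------------------------------------------
# Haplotype frequency tables
# ---------------------------------------------------------------------------

class HaplotypeFrequencyTable:
    """Frequencies over haplotypes.

    Keys are either :class:`ChromosomeHaplotype` objects (chromosome-level
    pools) or plain tuples of allele labels (EM output over a fixed variant
    list, recorded in :attr:`variants`).
    """

    def __init__(self, entries: Mapping, variants: Sequence[str] | None = None,
                 tol: float = 1e-9) -> None:
        if any(f < -1e-12 for f in entries.values()):
            raise ValueError("negative haplotype frequency")
        self.entries = {h: float(f) for h, f in entries.items() if f > 0.0}
        self.variants = tuple(variants) if variants is not None else None
        total = sum(self.entries.values())
        if not self.entries:
            raise ValueError("empty frequency table")
        if abs(total - 1.0) > tol:
            raise ValueError(f"frequencies sum to {total}, not 1")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    @classmethod
    def normalized(cls, entries: Mapping, variants: Sequence[str] | None = None):
        total = sum(entries.values())
        if total <= 0:
            raise ValueError("cannot normalise: total frequency <= 0")
        return cls({h: f / total for h, f in entries.items()}, variants=variants)

    def sample(self, rng, size: int) -> list:
        haps = list(self.entries)
        freqs = [self.entries[h] for h in haps]
        idx = rng.choice(len(haps), size=size, p=freqs)
        return [haps[i] for i in idx]

    # -- chromosome-level helpers ------------------------------------------

    def marginal(self, variant_id: str) -> dict[str, float]:
        """Copy-number-aware allele frequencies: expected allele count over
        expected gene-copy count per chromosome."""
        counts: dict[str, float] = {}
        copies = 0.0
        for hap, f in self.entries.items():
            alleles = hap.alleles[variant_id]
            copies += f * len(alleles)
            for a in alleles:
                counts[a] = counts.get(a, 0.0) + f
        if copies == 0:
            raise ValueError(f"no gene copies carry variant {variant_id}")
        return {a: c / copies for a, c in counts.items()}

    def cnr_marginal(self, cnr_id: str) -> dict[int, float]:
        out: dict[int, float] = {}
        for hap, f in self.entries.items():
            c = hap.cnr_copies[cnr_id]
            out[c] = out.get(c, 0.0) + f
        return out

    def baseline_allele_table(self, variant_ids: Sequence[str]) -> "HaplotypeFrequencyTable":
        """Restrict to no-CNV chromosomes and re-key by allele tuples."""
        sub: dict[tuple[str, ...], float] = {}
        for hap, f in self.entries.items():
            if any(c != 1 for c in hap.cnr_copies.values()):
                continue
            key = tuple(hap.alleles[v][0] for v in variant_ids)
            sub[key] = sub.get(key, 0.0) + f
        if not sub:
            raise ValueError("pool contains no CNV-free chromosomes")
        return HaplotypeFrequencyTable.normalized(sub, variants=variant_ids)
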