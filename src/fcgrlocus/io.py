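"""Tab-separated dialects for genotypes, trios and probe ratios.

Genotype TSV: one row per individual; columns ``individual_id``, one per
CNV region (total copies), then one per variant-allele dosage named
``<variant>_<allele>`` (e.g. ``FCGR2C_Stop``, ``FCGR2C_prom_2B.2``).

Trio (PED-like) TSV: ``family_id, individual_id, father_id, mother_id,
affected`` followed by the genotype columns.  ``0`` marks a missing parent.

Probe-ratio TSV: ``individual_id, probe_id, target, ratio``.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .family_tdt import Trio
from .locus_model import IndividualGenotype, LocusDefinition, default_locus

__all__ = [
    "genotype_columns",
    "genotypes_to_frame",
    "frame_to_genotypes",
    "write_genotypes",
    "read_genotypes",
    "write_trios",
    "read_trios",
    "write_probe_ratios",
    "read_probe_ratios",
]


def genotype_columns(locus: LocusDefinition) -> list[str]:
    cols = ["individual_id"] + [c.id for c in locus.cnrs]
    for v in locus.variants:
        cols += [f"{v.id}_{a}" for a in v.alleles]
    return cols


def genotypes_to_frame(
    genotypes: Sequence[IndividualGenotype], locus: LocusDefinition | None = None
) -> pd.DataFrame:
    locus = locus or default_locus()
    rows = []
    for g in genotypes:
        row = {"individual_id": g.id}
        for c in locus.cnrs:
            row[c.id] = g.cnr_copies.get(c.id, 2)
        for v in locus.variants:
            for a in v.alleles:
                row[f"{v.id}_{a}"] = g.dosage(v.id, a)
        rows.append(row)
    return pd.DataFrame(rows, columns=genotype_columns(locus))


def frame_to_genotypes(
    df: pd.DataFrame, locus: LocusDefinition | None = None, *, validate: bool = True
) -> list[IndividualGenotype]:
    locus = locus or default_locus()
    out = []
    for _, row in df.iterrows():
        g = IndividualGenotype(
            id=str(row["individual_id"]),
            cnr_copies={c.id: int(row[c.id]) for c in locus.cnrs},
            dosages={
                v.id: {a: int(row[f"{v.id}_{a}"]) for a in v.alleles}
                for v in locus.variants
            },
        )
        if validate:
            g.validate(locus)
        out.append(g)
    return out


def write_genotypes(path, genotypes, locus: LocusDefinition | None = None) -> None:
    genotypes_to_frame(genotypes, locus).to_csv(path, sep="\t", index=False)


def read_genotypes(path, locus: LocusDefinition | None = None, *, validate: bool = True):
    return frame_to_genotypes(pd.read_csv(path, sep="\t"), locus, validate=validate)


def write_trios(path, trios: Sequence[Trio], locus: LocusDefinition | None = None) -> None:
    locus = locus or default_locus()
    rows = []
    for t in trios:
        members = [
            (t.father, "0", "0", 0),
            (t.mother, "0", "0", 0),
            (t.child, t.father.id if t.father else "0",
             t.mother.id if t.mother else "0", 1),
        ]
        for g, fid, mid, aff in members:
            if g is None:
                continue
            row = {
                "family_id": t.family_id,
                "individual_id": g.id,
                "father_id": fid,
                "mother_id": mid,
                "affected": aff,
            }
            for c in locus.cnrs:
                row[c.id] = g.cnr_copies.get(c.id, 2)
            for v in locus.variants:
                for a in v.alleles:
                    row[f"{v.id}_{a}"] = g.dosage(v.id, a)
            rows.append(row)
    cols = ["family_id", "individual_id", "father_id", "mother_id", "affected"]
    cols += genotype_columns(locus)[1:]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_trios(path, locus: LocusDefinition | None = None, *, validate: bool = True) -> list[Trio]:
    locus = locus or default_locus()
    df = pd.read_csv(path, sep="\t")

    def to_geno(row) -> IndividualGenotype:
        g = IndividualGenotype(
            id=str(row["individual_id"]),
            cnr_copies={c.id: int(row[c.id]) for c in locus.cnrs},
            dosages={
                v.id: {a: int(row[f"{v.id}_{a}"]) for a in v.alleles}
                for v in locus.variants
            },
        )
        if validate:
            g.validate(locus)
        return g

    by_id = {str(r["individual_id"]): to_geno(r) for _, r in df.iterrows()}
    trios = []
    for _, row in df[df["affected"] == 1].iterrows():
        child = by_id[str(row["individual_id"])]
        father = by_id.get(str(row["father_id"]))
        mother = by_id.get(str(row["mother_id"]))
        trios.append(
            Trio(family_id=str(row["family_id"]), father=father, mother=mother, child=child)
        )
    return trios


def write_probe_ratios(path, probe_table: pd.DataFrame) -> None:
    probe_table.to_csv(path, sep="\t", index=False)


def read_probe_ratios(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"individual_id", "probe_id", "target", "ratio"} - set(df.columns)
    if missing:
        raise ValueError(f"probe-ratio table missing columns {sorted(missing)}")
    return df
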