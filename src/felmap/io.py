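"""Reading and writing PLINK-style PED/MAP text files.

PED rows: family, individual, sire, dam, sex, phenotype, then two allele
columns per marker with alleles coded "1"/"2" and "0" for missing. MAP rows:
chromosome, marker id, genetic position (written as 0), physical bp (1-based).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, InputError, Pedigree

_GENO_TO_ALLELES = {MISSING: ("0", "0"), 0: ("1", "1"), 1: ("1", "2"), 2: ("2", "2")}


def read_map(path: str | Path) -> pd.DataFrame:
    markers = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "marker", "cm", "bp"],
        dtype={"chrom": str, "marker": str, "cm": float, "bp": int},
    )
    return markers[["marker", "chrom", "bp"]]


def write_map(markers: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": markers["chrom"],
            "marker": markers["marker"],
            "cm": 0,
            "bp": markers["bp"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_ped(ped_path: str | Path, map_path: str | Path) -> tuple[Pedigree, GenotypeMatrix]:
    """Read a PED/MAP pair into a pedigree and genotype matrix."""
    markers = read_map(map_path)
    n_mark = len(markers)
    fam_rows = []
    geno_rows = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_mark:
                raise InputError(
                    f"{ped_path}:{line_no}: expected {6 + 2 * n_mark} fields, got {len(fields)}"
                )
            fam_rows.append(fields[:6])
            alleles = np.array(fields[6:], dtype="U1").reshape(n_mark, 2)
            called = (alleles != "0").all(axis=1)
            dosage = (alleles == "2").sum(axis=1).astype(np.int8)
            dosage[~called] = MISSING
            geno_rows.append(dosage)
    table = pd.DataFrame(fam_rows, columns=["family", "id", "sire", "dam", "sex", "phenotype"])
    table["sex"] = table["sex"].astype(int)
    ped = Pedigree(table[["family", "id", "sire", "dam", "sex"]].copy())
    gm = GenotypeMatrix(
        individuals=list(table["id"]),
        markers=markers,
        geno=np.vstack(geno_rows) if geno_rows else np.empty((0, n_mark), dtype=np.int8),
        sex=table["sex"].to_numpy(dtype=np.int8),
    )
    return ped, gm


def write_ped(ped: Pedigree, gm: GenotypeMatrix, path: str | Path) -> None:
    sex = {i: s for i, s in zip(gm.individuals, gm.sex)}
    with open(path, "w") as fh:
        for _, row in ped.table.iterrows():
            ind = row["id"]
            lead = [row["family"], ind, row["sire"], row["dam"], str(sex.get(ind, row["sex"])), "0"]
            g = gm.geno[gm.row_of(ind)]
            alleles: list[str] = []
            for d in g:
                a, b = _GENO_TO_ALLELES[int(d)]
                alleles.append(a)
                alleles.append(b)
            fh.write("\t".join(str(x) for x in lead + alleles) + "\n")
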