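"""Per-meiosis transmitted-allele inference (shared by qc and linkage).

A meiosis is *informative* at a marker iff the transmitting parent is
heterozygous and the transmitted allele is unambiguously determined by the
offspring and other-parent genotypes. On the X outside the PAR there are no
male meioses, and a male offspring's (hemizygously coded) call directly names
the maternally transmitted allele.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FEMALE, MALE, MISSING, GenotypeMatrix, Pedigree, par_mask


def transmitted_alleles(
    gm: GenotypeMatrix,
    ped: Pedigree,
    x_chrom: str | None = None,
    par_bp: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Infer transmitted alleles for every meiosis with a genotyped parent.

    Returns (meioses frame with columns parent/offspring/parent_sex, int8
    array of shape (n_meioses, n_markers) holding the transmitted B-allele
    dosage contribution 0/1, or -1 where not informative).
    """
    rows = set(gm.individuals)
    mei = ped.meioses()
    mei = mei[mei["parent"].isin(rows) & mei["offspring"].isin(rows)].reset_index(drop=True)
    xh = par_mask(gm.markers, x_chrom, par_bp)  # hemizygous-male region
    n_mark = gm.n_markers
    trans = np.full((len(mei), n_mark), -1, dtype=np.int8)

    sire_dam = {i: ped.parents_of(i) for i in mei["offspring"].unique()}
    for k, row in mei.iterrows():
        parent, off = row["parent"], row["offspring"]
        sire, dam = sire_dam[off]
        other = dam if row["parent_sex"] == MALE else sire
        p = gm.geno[gm.row_of(parent)]
        o = gm.geno[gm.row_of(off)]
        q = (
            gm.geno[gm.row_of(other)]
            if other is not None and other in rows
            else np.full(n_mark, MISSING, dtype=np.int8)
        )
        t = np.full(n_mark, -1, dtype=np.int8)
        het = p == 1
        t[het & (o == 0)] = 0
        t[het & (o == 2)] = 1
        amb = het & (o == 1)
        t[amb & (q == 0)] = 1
        t[amb & (q == 2)] = 0
        if xh.any():
            if row["parent_sex"] == MALE:
                t[xh] = -1  # no paternal meiosis outside the PAR
            else:
                off_male = ped.sex_of(off) == MALE
                if off_male:
                    tx = np.full(n_mark, -1, dtype=np.int8)
                    tx[het & (o == 0)] = 0
                    tx[het & (o == 2)] = 1  # hemizygous call names the allele
                    t[xh] = tx[xh]
        trans[k] = t
    return mei, trans


def resolve_parent_phase(
    gm: GenotypeMatrix,
    ped: Pedigree,
    mei: pd.DataFrame,
    trans: np.ndarray,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Grandparent-based phase of each parent's heterozygous markers.

    For parent P heterozygous at marker m, phase is *known* when the
    parental origin of P's own alleles at m is resolved by P's parents'
    genotypes (P viewed as an offspring). Homolog 0 of P is defined as the
    homolog P inherited from its sire. Returns, per parent id, a pair
    (phase_known bool array, origin0_allele int8 array) over markers;
    origin0_allele is the allele carried by homolog 0 (valid where known).
    """
    key = {(row["parent"], row["offspring"], row["parent_sex"]): k for k, row in mei.iterrows()}
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_mark = trans.shape[1] if len(trans) else gm.n_markers
    for parent in mei["parent"].unique():
        p = gm.geno[gm.row_of(parent)]
        known = np.zeros(n_mark, dtype=bool)
        origin0 = np.full(n_mark, -1, dtype=np.int8)
        sire, dam = ped.parents_of(parent)
        from_sire = key.get((sire, parent, MALE)) if sire is not None else None
        from_dam = key.get((dam, parent, FEMALE)) if dam is not None else None
        het = p == 1
        if from_sire is not None:
            t = trans[from_sire]
            m = het & (t != -1)
            known |= m
            origin0[m] = t[m]
        if from_dam is not None:
            t = trans[from_dam]
            m = het & (t != -1) & ~known
            known |= m
            origin0[m] = 1 - t[m]
        out[parent] = (known, origin0)
    return out
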