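"""Genotype and sample quality control, and informative-meiosis accounting.

Filter precedence follows the mapping pipeline's narrative order: sample call
rate (>= 0.90 retained), marker call rate (> 0.95 retained, strict),
Mendelian-violation markers dropped, then markers below the informative
meiosis (IM) floor dropped. Missing calls never count as violations or as
informative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._transmission import transmitted_alleles
from .core import MALE, MISSING, GenotypeMatrix, InputError, Pedigree, par_mask

__all__ = [
    "QCReport",
    "filter_markers_by_call_rate",
    "filter_samples_by_call_rate",
    "mendelian_check",
    "drop_violating_markers",
    "count_informative_meioses",
    "replication_check",
    "run_qc",
]


@dataclass
class QCReport:
    """Counts and identities of everything QC removed, stage by stage."""

    samples_removed: list[str] = field(default_factory=list)
    markers_removed_call_rate: list[str] = field(default_factory=list)
    markers_removed_mendelian: list[str] = field(default_factory=list)
    markers_removed_low_im: list[str] = field(default_factory=list)
    markers_excluded: list[str] = field(default_factory=list)
    im: pd.DataFrame | None = None  # marker, im for the retained matrix

    def summary(self) -> dict:
        return {
            "samples_removed": len(self.samples_removed),
            "markers_removed_call_rate": len(self.markers_removed_call_rate),
            "markers_removed_mendelian": len(self.markers_removed_mendelian),
            "markers_removed_low_im": len(self.markers_removed_low_im),
            "markers_excluded": len(self.markers_excluded),
        }

    def write(self, outdir: str | Path, prefix: str = "qc") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / f"{prefix}_summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)
        rows = (
            [("sample_call_rate", s) for s in self.samples_removed]
            + [("marker_call_rate", m) for m in self.markers_removed_call_rate]
            + [("mendelian", m) for m in self.markers_removed_mendelian]
            + [("low_im", m) for m in self.markers_removed_low_im]
            + [("excluded", m) for m in self.markers_excluded]
        )
        pd.DataFrame(rows, columns=["stage", "item"]).to_csv(
            outdir / f"{prefix}_removed.tsv", sep="\t", index=False
        )
        if self.im is not None:
            self.im.to_csv(outdir / f"{prefix}_im.tsv", sep="\t", index=False)


def filter_markers_by_call_rate(
    gm: GenotypeMatrix, threshold: float = 0.95
) -> tuple[GenotypeMatrix, list[str]]:
    """Retain markers with call rate strictly greater than ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise InputError(f"marker call-rate threshold must be in (0, 1], got {threshold}")
    rate = gm.marker_call_rate()
    keep = rate > threshold
    removed = list(gm.markers.loc[~keep, "marker"])
    return gm.subset_markers(keep), removed


def filter_samples_by_call_rate(
    gm: GenotypeMatrix, threshold: float = 0.90
) -> tuple[GenotypeMatrix, list[str]]:
    """Retain samples with call rate at least ``threshold`` (inclusive)."""
    rate = gm.sample_call_rate()
    keep = rate >= threshold
    removed = [i for i, k in zip(gm.individuals, keep) if not k]
    return gm.subset_individuals(keep), removed


def mendelian_check(
    gm: GenotypeMatrix,
    ped: Pedigree,
    x_chrom: str | None = None,
    par_bp: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Trio-impossible genotype combinations, plus heterozygous male X calls.

    Returns a frame with columns marker, individual, kind. A trio is checked
    only where all three genotypes are called; a heterozygous male call on X
    outside the PAR is a violation on its own.
    """
    xh = par_mask(gm.markers, x_chrom, par_bp)
    markers = gm.markers["marker"].to_numpy()
    rows: list[tuple[str, str, str]] = []
    present = set(gm.individuals)

    if xh.any():
        for ind, sex in zip(gm.individuals, gm.sex):
            if sex == MALE:
                g = gm.geno[gm.row_of(ind)]
                for m in np.flatnonzero(xh & (g == 1)):
                    rows.append((markers[m], ind, "male_het_x"))

    for _, r in ped.table.iterrows():
        off, sire, dam = r["id"], r["sire"], r["dam"]
        if sire == "0" or dam == "0":
            continue
        if off not in present or sire not in present or dam not in present:
            continue
        o = gm.geno[gm.row_of(off)]
        s = gm.geno[gm.row_of(sire)]
        d = gm.geno[gm.row_of(dam)]
        called = (o != MISSING) & (s != MISSING) & (d != MISSING)

        minsum = (s == 2).astype(np.int8) + (d == 2).astype(np.int8)
        maxsum = (s >= 1).astype(np.int8) + (d >= 1).astype(np.int8)
        bad = called & ((o < minsum) | (o > maxsum)) & ~xh

        if xh.any():
            off_male = ped.sex_of(off) == MALE
            if off_male:
                # X from dam only; hemizygous call o in {0,2} names the allele.
                a = o // 2
                bad_x = called & (o != 1) & (((a == 0) & (d == 2)) | ((a == 1) & (d == 0)))
            else:
                # Sire passes his single X allele; skip where the sire call is
                # itself an (impossible) het, flagged separately.
                a_s = s // 2
                diff = o - a_s
                bad_x = (
                    called
                    & (s != 1)
                    & ((diff < 0) | (diff > 1) | ((diff == 0) & (d == 2)) | ((diff == 1) & (d == 0)))
                )
            bad = bad | (bad_x & xh)
        for m in np.flatnonzero(bad):
            rows.append((markers[m], off, "trio"))
    return pd.DataFrame(rows, columns=["marker", "individual", "kind"])


def drop_violating_markers(
    gm: GenotypeMatrix,
    ped: Pedigree,
    x_chrom: str | None = None,
    par_bp: tuple[int, int] | None = None,
) -> tuple[GenotypeMatrix, list[str], pd.DataFrame]:
    """Remove every marker with at least one Mendelian violation."""
    viol = mendelian_check(gm, ped, x_chrom=x_chrom, par_bp=par_bp)
    bad = set(viol["marker"])
    keep = ~gm.markers["marker"].isin(bad).to_numpy()
    return gm.subset_markers(keep), sorted(bad), viol


def count_informative_meioses(
    gm: GenotypeMatrix,
    ped: Pedigree,
    x_chrom: str | None = None,
    par_bp: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-marker count of informative meioses (IM)."""
    _, trans = transmitted_alleles(gm, ped, x_chrom=x_chrom, par_bp=par_bp)
    im = (trans != -1).sum(axis=0) if len(trans) else np.zeros(gm.n_markers, dtype=int)
    return pd.DataFrame({"marker": gm.markers["marker"], "im": im})


def replication_check(gm: GenotypeMatrix, duplicate_pairs: list[tuple[str, str]]) -> list[str]:
    """Markers with any discordant call between duplicate samples."""
    flagged = np.zeros(gm.n_markers, dtype=bool)
    for a, b in duplicate_pairs:
        ga = gm.geno[gm.row_of(a)]
        gb = gm.geno[gm.row_of(b)]
        flagged |= (ga != gb) & (ga != MISSING) & (gb != MISSING)
    return list(gm.markers.loc[flagged, "marker"])


def run_qc(
    gm: GenotypeMatrix,
    ped: Pedigree,
    *,
    marker_call_rate: float = 0.95,
    sample_call_rate: float = 0.90,
    min_im: int = 100,
    exclude_markers: list[str] | None = None,
    x_chrom: str | None = None,
    par_bp: tuple[int, int] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC pipeline: exclusion list, samples, marker call rate, Mendelian,
    IM floor. Returns the cleaned matrix and a stage-by-stage report."""
    report = QCReport()
    if exclude_markers:
        drop = gm.markers["marker"].isin(set(exclude_markers)).to_numpy()
        report.markers_excluded = list(gm.markers.loc[drop, "marker"])
        gm = gm.subset_markers(~drop)
    gm, report.samples_removed = filter_samples_by_call_rate(gm, sample_call_rate)
    gm, report.markers_removed_call_rate = filter_markers_by_call_rate(gm, marker_call_rate)
    gm, report.markers_removed_mendelian, _ = drop_violating_markers(
        gm, ped, x_chrom=x_chrom, par_bp=par_bp
    )
    im = count_informative_meioses(gm, ped, x_chrom=x_chrom, par_bp=par_bp)
    low = (im["im"] < min_im).to_numpy()
    report.markers_removed_low_im = list(gm.markers.loc[low, "marker"])
    gm = gm.subset_markers(~low)
    report.im = im.loc[~low].reset_index(drop=True)
    return gm, report
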