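"""Linkage-map-driven scaffold anchoring and structural-conflict detection.

Scaffolds are assigned to chromosomes by majority vote of their marker hits,
ordered by median genetic position, and oriented by the sign of the rank
correlation between scaffold coordinate and map position. Comparing the map
order against a reference (prior-assembly) marker order flags inversions,
translocations and chimeric (falsely joined) scaffolds. The resulting
chromosome builds are written as AGP 2.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core import InputError

__all__ = [
    "ScaffoldPlacement",
    "place_scaffolds",
    "orient_scaffolds",
    "detect_conflicts",
    "write_agp",
    "read_agp",
    "n50",
    "compare_assembly_stats",
]

AGP_COLUMNS = [
    "object",
    "object_beg",
    "object_end",
    "part_number",
    "component_type",
    "component_id",
    "component_beg",
    "component_end",
    "orientation",
]


@dataclass
class ScaffoldPlacement:
    scaffold: str
    chrom: str | None
    order: int | None
    orientation: str  # '+', '-', '?'
    n_markers: int
    median_cm: float
    tie: bool = False


def _best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One hit per (marker, scaffold): keep the first occurrence."""
    return hits.drop_duplicates(subset=["marker", "scaffold"], keep="first")


def place_scaffolds(
    hits: pd.DataFrame,
    map_positions: pd.DataFrame,
    scaffold_lengths: pd.DataFrame | dict[str, int],
) -> pd.DataFrame:
    """Assign scaffolds to chromosomes and order them by median cM.

    ``hits`` has columns marker, scaffold, scaffold_bp; ``map_positions``
    has marker, chrom, cm. Scaffolds without hits, or with a tied majority
    chromosome vote, land in the unplaced bin (chrom None). Equal medians
    break ties by scaffold id.
    """
    if isinstance(scaffold_lengths, dict):
        scaffold_lengths = pd.DataFrame(
            {"scaffold": list(scaffold_lengths), "length": list(scaffold_lengths.values())}
        )
    joined = _best_hits(hits).merge(map_positions[["marker", "chrom", "cm"]], on="marker", how="inner")
    rows = []
    for scaf in scaffold_lengths["scaffold"]:
        sub = joined[joined["scaffold"] == scaf]
        if sub.empty:
            rows.append((scaf, None, None, "?", 0, np.nan, False))
            continue
        counts = sub["chrom"].value_counts()
        tie = len(counts) > 1 and counts.iloc[0] == counts.iloc[1]
        if tie:
            rows.append((scaf, None, None, "?", len(sub), np.nan, True))
            continue
        chrom = counts.index[0]
        on = sub[sub["chrom"] == chrom]
        rows.append((scaf, chrom, None, "?", len(on), float(on["cm"].median()), False))
    out = pd.DataFrame(
        rows, columns=["scaffold", "chrom", "order", "orientation", "n_markers", "median_cm", "tie"]
    )
    for chrom, sub in out.groupby("chrom", dropna=True):
        ordered = sub.sort_values(["median_cm", "scaffold"], kind="stable")
        out.loc[ordered.index, "order"] = np.arange(len(ordered))
    return out


def orient_scaffolds(
    placements: pd.DataFrame, hits: pd.DataFrame, map_positions: pd.DataFrame
) -> pd.DataFrame:
    """Set orientation from the rank correlation of scaffold bp vs map cM.

    '+' for positive, '-' for negative, '?' when fewer than two distinct cM
    values support the scaffold or the correlation is zero.
    """
    joined = _best_hits(hits).merge(map_positions[["marker", "chrom", "cm"]], on="marker", how="inner")
    out = placements.copy()
    for i, row in out.iterrows():
        if row["chrom"] is None or row["n_markers"] < 2:
            continue
        sub = joined[(joined["scaffold"] == row["scaffold"]) & (joined["chrom"] == row["chrom"])]
        if sub["cm"].nunique() < 2:
            continue
        rho = spearmanr(sub["scaffold_bp"], sub["cm"]).statistic
        if np.isnan(rho) or rho == 0:
            continue
        out.loc[i, "orientation"] = "+" if rho > 0 else "-"
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) half-open runs of True."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_conflicts(
    map_positions: pd.DataFrame,
    reference: pd.DataFrame,
    hits: pd.DataFrame | None = None,
    min_block: int = 5,
    chimera_cm_gap: float = 25.0,
) -> tuple[pd.DataFrame, int]:
    """Structural differences between the linkage map and a reference order.

    ``map_positions`` (marker, chrom, cm, order within chrom) is compared to
    ``reference`` (marker, ref_chrom, ref_bp). Maximal runs of at least
    ``min_block`` markers whose reference coordinates run backwards against
    the map order are called inversions; contiguous blocks of at least
    ``min_block`` markers whose reference chromosome differs from the map
    chromosome are translocations. If ``hits`` is given, scaffolds whose
    hits split by scaffold coordinate into segments on different map
    chromosomes (or into cM clusters separated by more than
    ``chimera_cm_gap``) are flagged chimeric with the breakpoint interval
    between the flanking hits. Returns (conflict table, number of map
    markers missing from the reference).
    """
    ref = reference.set_index("marker")
    rows = []
    skipped = 0
    for chrom, sub in map_positions.groupby("chrom"):
        sub = sub.sort_values("order" if "order" in sub else "cm", kind="stable")
        have = sub["marker"].isin(ref.index)
        skipped += int((~have).sum())
        sub = sub[have]
        if len(sub) < 2:
            continue
        rchrom = ref.loc[sub["marker"], "ref_chrom"].to_numpy()
        rbp = ref.loc[sub["marker"], "ref_bp"].to_numpy(dtype=float)
        markers = sub["marker"].to_numpy()

        # Translocations: blocks whose reference chromosome differs.
        for i, j in _runs(rchrom != chrom):
            if j - i >= min_block:
                rows.append(
                    ("translocation", chrom, markers[i], markers[j - 1], j - i,
                     f"reference chromosome {rchrom[i]}")
                )
        # Inversions: runs of strictly decreasing reference bp on this chrom.
        same = rchrom == chrom
        idx = np.flatnonzero(same)
        if len(idx) >= 2:
            bp_s = rbp[idx]
            dec = np.diff(bp_s) < 0
            # Determine dominant direction; flag runs against it.
            if dec.mean() > 0.5:
                against = ~dec
            else:
                against = dec
            for i, j in _runs(against):
                if j - i + 1 >= min_block:  # markers spanned by the run
                    rows.append(
                        ("inversion", chrom, markers[idx[i]], markers[idx[j]],
                         j - i + 1, "reference order reversed")
                    )
    if hits is not None:
        pos = map_positions.set_index("marker")
        joined = _best_hits(hits)
        joined = joined[joined["marker"].isin(pos.index)]
        for scaf, sub in joined.groupby("scaffold"):
            sub = sub.sort_values("scaffold_bp", kind="stable")
            chroms = pos.loc[sub["marker"], "chrom"].to_numpy()
            cms = pos.loc[sub["marker"], "cm"].to_numpy(dtype=float)
            bps = sub["scaffold_bp"].to_numpy()
            if len(sub) < 2:
                continue
            split = (chroms[1:] != chroms[:-1]) | (
                (chroms[1:] == chroms[:-1]) & (np.abs(np.diff(cms)) > chimera_cm_gap)
            )
            for b in np.flatnonzero(split):
                rows.append(
                    ("chimera", scaf, sub["marker"].iloc[b], sub["marker"].iloc[b + 1], 2,
                     f"breakpoint {int(bps[b])}..{int(bps[b + 1])}")
                )
    out = pd.DataFrame(
        rows, columns=["type", "where", "start_marker", "end_marker", "n_markers", "detail"]
    )
    return out, skipped


def write_agp(
    placements: pd.DataFrame,
    scaffold_lengths: pd.DataFrame | dict[str, int],
    path: str | Path,
    gap_size: int = 100,
) -> None:
    """Write chromosome builds as AGP 2.0.

    Placed scaffolds become W components in order with 100-bp scaffold gaps
    (linkage yes, evidence map) between them; unplaced scaffolds are emitted
    as singleton objects named after themselves.
    """
    if isinstance(scaffold_lengths, dict):
        lengths = dict(scaffold_lengths)
    else:
        lengths = dict(zip(scaffold_lengths["scaffold"], scaffold_lengths["length"]))
    lines = ["##agp-version\t2.0"]

    def component(obj, beg, end, part, scaf, orientation):
        return "\t".join(
            str(x)
            for x in (obj, beg, end, part, "W", scaf, 1, lengths[scaf], orientation)
        )

    placed = placements.dropna(subset=["chrom"])
    for chrom in sorted(placed["chrom"].unique()):
        sub = placed[placed["chrom"] == chrom].sort_values("order")
        at = 1
        part = 1
        for i, (_, row) in enumerate(sub.iterrows()):
            ln = lengths[row["scaffold"]]
            if i > 0:
                lines.append(
                    "\t".join(
                        str(x)
                        for x in (
                            chrom, at, at + gap_size - 1, part, "N", gap_size,
                            "scaffold", "yes", "map",
                        )
                    )
                )
                at += gap_size
                part += 1
            end = at + ln - 1
            if end < at:
                raise InputError("non-monotone object coordinates in AGP build")
            lines.append(component(chrom, at, end, part, row["scaffold"], row["orientation"]))
            at = end + 1
            part += 1
    for _, row in placements[placements["chrom"].isna()].iterrows():
        scaf = row["scaffold"]
        lines.append(component(scaf, 1, lengths[scaf], 1, scaf, "?"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_agp(path: str | Path) -> pd.DataFrame:
    """Read an AGP file into a frame of component (W) and gap (N/U) rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append(f[:9])
    df = pd.DataFrame(rows, columns=AGP_COLUMNS)
    for c in ("object_beg", "object_end", "part_number"):
        df[c] = df[c].astype(int)
    return df


def n50(lengths) -> int:
    """N50: length L such that >= half the assembled bases are in pieces >= L."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise InputError("n50 of an empty length set")
    half = arr.sum() / 2.0
    return int(arr[np.searchsorted(np.cumsum(arr), half)])


def compare_assembly_stats(new: dict, old: dict, decimals: int = 1) -> dict:
    """Fold-change of assembly contiguity statistics (new over old).

    ``new`` and ``old`` map statistic names (e.g. "contig_n50",
    "scaffold_n50") to values in consistent units.
    """
    out = {}
    for key in new:
        if key in old and old[key]:
            out[f"{key}_ratio"] = round(new[key] / old[key], decimals)
    return out
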