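"""Recombination-landscape analysis: Marey maps, cM/Mb profiles, deserts.

A Marey map plots cumulative genetic position (cM) against physical position
(bp); its slope is the local recombination rate. Rates are computed from a
monotone piecewise-linear Marey interpolant rather than marker-pair deltas,
which is robust to uneven marker spacing. A recombination *desert* is a long
stretch of near-zero rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .core import InputError

__all__ = [
    "MareyMap",
    "marey_build",
    "windowed_rate",
    "detect_deserts",
    "summarize",
    "summarize_table",
    "marey_plot",
]

MB = 1e6


@dataclass
class MareyMap:
    """Monotone piecewise-linear cM-over-bp interpolant for one chromosome.

    ``cm`` maps column name ("avg", "female", "male") to isotonically
    adjusted cumulative cM aligned with ``bp``; ``conflicts`` lists markers
    whose input cM violated monotonicity (indicative of order conflicts).
    Outside the terminal markers the interpolant is clamped (rate 0).
    """

    chrom: str
    bp: np.ndarray
    cm: dict[str, np.ndarray]
    length_bp: float
    conflicts: pd.DataFrame

    def interp(self, x, column: str = "avg"):
        return np.interp(x, self.bp, self.cm[column])

    def total_cm(self, column: str = "avg") -> float:
        c = self.cm[column]
        return float(c[-1] - c[0])


def marey_build(
    positions: pd.DataFrame,
    chrom_length_bp: float | None = None,
    chrom: str | None = None,
) -> MareyMap:
    """Build a Marey map from positioned markers.

    ``positions`` needs columns marker, bp and cm_avg (cm_female / cm_male
    optional). Markers are sorted by bp; each cM column is made
    non-decreasing by isotonic (least-squares monotone) adjustment and the
    adjusted markers are reported as conflicts.
    """
    if len(positions) < 2:
        raise InputError("a Marey map needs at least 2 positioned markers")
    df = positions.sort_values("bp", kind="stable").reset_index(drop=True)
    bp = df["bp"].to_numpy(dtype=float)
    if chrom is None:
        chrom = str(df["chrom"].iloc[0]) if "chrom" in df else "NA"
    if chrom_length_bp is None:
        chrom_length_bp = float(bp[-1])
    cm: dict[str, np.ndarray] = {}
    conflict_rows = []
    for col, name in (("cm_avg", "avg"), ("cm_female", "female"), ("cm_male", "male")):
        if col not in df:
            continue
        y = df[col].to_numpy(dtype=float)
        fit = isotonic_regression(y).x
        moved = ~np.isclose(fit, y, atol=1e-9)
        for k in np.flatnonzero(moved):
            conflict_rows.append((df["marker"].iloc[k], name, y[k], fit[k]))
        cm[name] = fit
    conflicts = pd.DataFrame(conflict_rows, columns=["marker", "column", "cm_in", "cm_fit"])
    return MareyMap(chrom=chrom, bp=bp, cm=cm, length_bp=float(chrom_length_bp), conflicts=conflicts)


def windowed_rate(
    marey: MareyMap,
    window_mb: float = 5.0,
    step_mb: float = 1.0,
    column: str = "avg",
) -> pd.DataFrame:
    """Sliding-window local recombination rate (cM/Mb).

    Windows of ``window_mb`` step by ``step_mb`` across [0, chromosome
    length]; the rate is the Marey-interpolated cM difference across the
    window divided by the window size. A window larger than the chromosome
    collapses to a single whole-chromosome window.
    """
    L = marey.length_bp
    W = window_mb * MB
    S = step_mb * MB
    if W >= L:
        starts = np.array([0.0])
        W = L
    else:
        starts = np.arange(0.0, L - W + S / 2, S)
        if starts[-1] + W < L:
            starts = np.append(starts, L - W)
    ends = starts + W
    c0 = marey.interp(starts, column)
    c1 = marey.interp(ends, column)
    rate = (c1 - c0) / (W / MB)
    return pd.DataFrame(
        {"chrom": marey.chrom, "start": starts.astype(np.int64), "end": ends.astype(np.int64), "rate": rate}
    )


def detect_deserts(
    profile: pd.DataFrame,
    max_rate: float = 0.1,
    min_span_mb: float = 10.0,
) -> pd.DataFrame:
    """Recombination deserts: merged runs of sub-threshold windows.

    Windows with rate < ``max_rate`` cM/Mb are merged where they touch or
    overlap; merged intervals spanning at least ``min_span_mb`` are reported
    in BED convention (0-based half-open).
    """
    low = profile[profile["rate"] < max_rate].sort_values("start")
    merged: list[list] = []
    for _, w in low.iterrows():
        if merged and w["start"] <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], w["end"])
        else:
            merged.append([w["chrom"], int(w["start"]), int(w["end"])])
    rows = [
        (c, s, e, (e - s) / MB)
        for c, s, e in merged
        if (e - s) / MB >= min_span_mb
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "span_mb"])


def summarize_table(per_chrom: pd.DataFrame, x_chrom: str | None = "X") -> tuple[pd.DataFrame, dict]:
    """Chromosome and genome summary from per-chromosome map statistics.

    ``per_chrom`` needs columns chrom, length_mb, markers, map_cm and
    optionally female_cm / male_cm. Produces per-chromosome cM/Mb and
    markers/Mb (1 decimal, matching conventional map-table presentation) and
    genome totals over autosomes: total map length, rate, marker density and
    the female:male map-length ratio.
    """
    df = per_chrom.copy()
    missing = df["length_mb"].isna()
    if missing.any():
        warnings.warn(
            f"chromosomes without physical length omitted from genome rates: "
            f"{list(df.loc[missing, 'chrom'])}"
        )
    df["cm_per_mb"] = (df["map_cm"] / df["length_mb"]).round(1)
    df["markers_per_mb"] = (df["markers"] / df["length_mb"]).round(1)
    auto = df[(df["chrom"] != x_chrom) & ~missing]
    summary = {
        "total_markers": int(df["markers"].sum()),
        "autosomal_map_cm": float(auto["map_cm"].sum()),
        "autosomal_length_mb": float(auto["length_mb"].sum()),
        "autosomal_cm_per_mb": round(float(auto["map_cm"].sum() / auto["length_mb"].sum()), 1)
        if len(auto)
        else np.nan,
        "autosomal_markers_per_mb": round(float(auto["markers"].sum() / auto["length_mb"].sum()), 1)
        if len(auto)
        else np.nan,
    }
    if "female_cm" in df and "male_cm" in df:
        f = float(auto["female_cm"].sum())
        m = float(auto["male_cm"].sum())
        summary["female_map_cm"] = f
        summary["male_map_cm"] = m
        summary["female_male_ratio"] = round(f / m, 1) if m > 0 else np.nan
    return df, summary


def summarize(maps, lengths_mb: dict[str, float], x_chrom: str | None = "X") -> tuple[pd.DataFrame, dict]:
    """Summarize built :class:`~felmap.mapbuild.ChromosomeMap` objects.

    ``lengths_mb`` maps chromosome id to physical length in Mb; chromosomes
    absent from it are omitted from genome rates with a warning.
    """
    from .core import FEMALE, MALE

    rows = []
    for m in maps:
        rows.append(
            {
                "chrom": m.chrom,
                "length_mb": lengths_mb.get(m.chrom, np.nan),
                "markers": m.n,
                "map_cm": m.length(),
                "female_cm": m.length(FEMALE),
                "male_cm": m.length(MALE),
            }
        )
    return summarize_table(pd.DataFrame(rows), x_chrom=x_chrom)


def marey_plot(marey: MareyMap, out_path: str, column: str = "avg") -> None:
    """Write a Marey plot (cM vs bp) to ``out_path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(marey.bp / MB, marey.cm[column], ".-", ms=3, lw=0.8)
    ax.set_xlabel("physical position (Mb)")
    ax.set_ylabel("genetic position (cM)")
    ax.set_title(f"{marey.chrom} Marey map ({column})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
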