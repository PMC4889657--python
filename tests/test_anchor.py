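"""Scaffold placement, orientation, conflict detection, AGP round trips."""

import numpy as np
import pandas as pd
import pytest

from felmap.anchor import (
    compare_assembly_stats,
    detect_conflicts,
    n50,
    orient_scaffolds,
    place_scaffolds,
    read_agp,
    write_agp,
)


def simple_map(n=20, chrom="A1", cm_step=5.0):
    return pd.DataFrame(
        {
            "marker": [f"M{i}" for i in range(n)],
            "chrom": chrom,
            "cm": np.arange(n) * cm_step,
            "order": np.arange(n),
        }
    )


def test_place_order_by_median_cm():
    pos = simple_map(6)
    hits = pd.DataFrame(
        {
            "marker": ["M3", "M4", "M0", "M1", "M5"],
            "scaffold": ["B", "B", "A", "A", "C"],
            "scaffold_bp": [100, 200, 100, 200, 100],
        }
    )
    lengths = {"A": 1000, "B": 1000, "C": 1000, "D": 500}
    pl = place_scaffolds(hits, pos, lengths)
    placed = pl.dropna(subset=["chrom"]).sort_values("order")
    assert list(placed["scaffold"]) == ["A", "B", "C"]
    # zero hits -> unplaced
    assert pl.set_index("scaffold").loc["D", "chrom"] is None


def test_place_tie_rules():
    pos = pd.DataFrame(
        {"marker": ["M0", "M1"], "chrom": ["A1", "A2"], "cm": [0.0, 0.0], "order": [0, 0]}
    )
    hits = pd.DataFrame(
        {"marker": ["M0", "M1"], "scaffold": ["S", "S"], "scaffold_bp": [1, 2]}
    )
    pl = place_scaffolds(hits, pos, {"S": 10})
    assert pl.iloc[0]["tie"] and pl.iloc[0]["chrom"] is None
    # equal medians -> tie broken by scaffold id
    pos2 = simple_map(2)
    hits2 = pd.DataFrame(
        {"marker": ["M0", "M0"], "scaffold": ["Z", "Y"], "scaffold_bp": [1, 1]}
    )
    pl2 = place_scaffolds(hits2, pos2, {"Z": 10, "Y": 10})
    ordered = pl2.sort_values("order")
    assert list(ordered["scaffold"]) == ["Y", "Z"]


def test_orientation_sign():
    pos = simple_map(4)
    hits = pd.DataFrame(
        {
            "marker": ["M0", "M1", "M2", "M3"],
            "scaffold": ["F", "F", "R", "R"],
            "scaffold_bp": [1_000_000, 5_000_000, 1_000_000, 5_000_000],
        }
    )
    # R's map positions run backwards along the scaffold
    pos.loc[pos["marker"] == "M2", "cm"] = 14.0
    pos.loc[pos["marker"] == "M3", "cm"] = 10.0
    pl = place_scaffolds(hits, pos, {"F": 6_000_000, "R": 6_000_000})
    pl = orient_scaffolds(pl, hits, pos)
    o = pl.set_index("scaffold")["orientation"]
    assert o["F"] == "+" and o["R"] == "-"


def test_orientation_single_marker_unknown():
    pos = simple_map(2)
    hits = pd.DataFrame({"marker": ["M0"], "scaffold": ["S"], "scaffold_bp": [10]})
    pl = orient_scaffolds(place_scaffolds(hits, pos, {"S": 100}), hits, pos)
    assert pl.iloc[0]["orientation"] == "?"


def test_inversion_detection():
    pos = simple_map(20)
    ref = pd.DataFrame(
        {
            "marker": [f"M{i}" for i in range(20)],
            "ref_chrom": "A1",
            "ref_bp": np.arange(20) * 1_000_000,
        }
    )
    # reverse reference coordinates of the block M7..M12
    vals = ref["ref_bp"].to_numpy().copy()
    vals[7:13] = vals[7:13][::-1]
    ref["ref_bp"] = vals
    conf, skipped = detect_conflicts(pos, ref, min_block=5)
    inv = conf[conf["type"] == "inversion"]
    assert len(inv) == 1
    assert inv.iloc[0]["start_marker"] == "M7" and inv.iloc[0]["end_marker"] == "M12"
    assert skipped == 0


def test_translocation_detection():
    pos = simple_map(20)
    ref = pd.DataFrame(
        {
            "marker": [f"M{i}" for i in range(20)],
            "ref_chrom": ["A1"] * 5 + ["B2"] * 10 + ["A1"] * 5,
            "ref_bp": np.arange(20) * 1_000_000,
        }
    )
    conf, _ = detect_conflicts(pos, ref, min_block=5)
    tr = conf[conf["type"] == "translocation"]
    assert len(tr) == 1
    assert tr.iloc[0]["start_marker"] == "M5" and tr.iloc[0]["end_marker"] == "M14"


def test_chimera_detection():
    posA = simple_map(5, chrom="A1")
    posB = simple_map(5, chrom="B2")
    posB["marker"] = [f"N{i}" for i in range(5)]
    pos = pd.concat([posA, posB], ignore_index=True)
    ref = pd.DataFrame({"marker": pos["marker"], "ref_chrom": pos["chrom"], "ref_bp": pos["cm"] * 1e6})
    hits = pd.DataFrame(
        {
            "marker": ["M0", "M1", "N0", "N1"],
            "scaffold": "CHI",
            "scaffold_bp": [100, 200, 5000, 6000],
        }
    )
    conf, _ = detect_conflicts(pos, ref, hits=hits, min_block=5)
    chi = conf[conf["type"] == "chimera"]
    assert len(chi) == 1
    assert "200..5000" in chi.iloc[0]["detail"]


def test_missing_reference_rows_counted():
    pos = simple_map(6)
    ref = pd.DataFrame(
        {"marker": ["M0", "M1", "M2"], "ref_chrom": "A1", "ref_bp": [0, 1, 2]}
    )
    _, skipped = detect_conflicts(pos, ref)
    assert skipped == 3


def test_agp_arithmetic_and_roundtrip(tmp_path):
    pl = pd.DataFrame(
        {
            "scaffold": ["S1", "S2", "U1"],
            "chrom": ["A1", "A1", None],
            "order": [0, 1, None],
            "orientation": ["+", "-", "?"],
            "n_markers": [3, 2, 0],
            "median_cm": [1.0, 2.0, np.nan],
            "tie": False,
        }
    )
    lengths = {"S1": 1_000_000, "S2": 500_000, "U1": 1234}
    path = tmp_path / "out.agp"
    write_agp(pl, lengths, path)
    agp = read_agp(path)
    a1 = agp[agp["object"] == "A1"]
    assert int(a1["object_end"].max()) == 1_500_100  # two scaffolds + 100 bp gap
    comp = a1[a1["component_type"] == "W"]
    assert list(comp["component_id"]) == ["S1", "S2"]
    assert list(comp["orientation"]) == ["+", "-"]
    gaps = a1[a1["component_type"] == "N"]
    assert len(gaps) == 1 and gaps.iloc[0]["component_id"] == "100"
    # unplaced scaffold emitted as its own object
    u = agp[agp["object"] == "U1"]
    assert len(u) == 1 and int(u.iloc[0]["object_end"]) == 1234
    # object coordinates are gapless and non-overlapping
    prev_end = 0
    for _, row in a1.iterrows():
        assert row["object_beg"] == prev_end + 1
        prev_end = row["object_end"]


def test_n50():
    assert n50([10, 10, 10]) == 10
    assert n50([50, 30, 10, 10]) == 50  # 50 covers half of 100
    assert n50([40, 30, 20, 10]) == 30


def test_assembly_ratio_helper():
    new = {"contig_n50": 45, "scaffold_n50": 18.0}
    old = {"contig_n50": 21, "scaffold_n50": 4.7}
    out = compare_assembly_stats(new, old)
    assert out["contig_n50_ratio"] == 2.1
    assert out["scaffold_n50_ratio"] == 3.8


def test_simulated_scaffold_recovery(small_sim):
    """Scaffolds cut from a simulated chromosome are recovered in true order
    and orientation when anchored on the true genetic map."""
    tm = small_sim.truth_markers
    cm = (tm["female_cm"] + tm["male_cm"]) / 2
    pos = pd.DataFrame({"marker": tm["marker"], "chrom": "A1", "cm": cm})
    bp = tm["bp"].to_numpy()
    # cut into 5 scaffolds of 8 markers; flip orientation of scaffold 2
    n_scaf, per = 5, 8
    rows = []
    lengths = {}
    for s in range(n_scaf):
        lo, hi = s * per, (s + 1) * per
        start_bp = bp[lo] - 1
        length = bp[hi - 1] - start_bp + 25_000
        lengths[f"S{s}"] = int(length)
        for j in range(lo, hi):
            off = bp[j] - start_bp
            if s == 2:
                off = length - off + 1
            rows.append((tm["marker"].iloc[j], f"S{s}", int(off)))
    hits = pd.DataFrame(rows, columns=["marker", "scaffold", "scaffold_bp"])
    pl = orient_scaffolds(place_scaffolds(hits, pos, lengths), hits, pos)
    placed = pl.sort_values("order")
    assert list(placed["scaffold"]) == [f"S{s}" for s in range(n_scaf)]
    expect = ["+", "+", "-", "+", "+"]
    assert list(placed["orientation"]) == expect
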