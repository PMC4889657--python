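"""Two-point estimation, grouping, chromosome assignment."""

import numpy as np
import pandas as pd
import pytest

from felmap.linkage import (
    assign_chromosomes,
    autogroup,
    estimate_two_point,
    infer_meiosis_vectors,
    two_point_all,
)
from felmap.qc import count_informative_meioses

from conftest import symbol_mv, trio_matrix


def two_marker_mv(k, n, seed=0):
    """n phase-resolved meioses over 2 markers with exactly k recombinant."""
    sym = np.zeros((n, 2), dtype=np.int8)
    sym[:k, 1] = 1
    return symbol_mv(sym)


def test_two_point_closed_forms():
    t = estimate_two_point(two_marker_mv(10, 100), 0, 1)
    assert t.r == pytest.approx(0.10)
    expect = 10 * np.log10(0.1) + 90 * np.log10(0.9) + 100 * np.log10(2)
    assert t.lod == pytest.approx(expect, abs=1e-6)
    assert t.lod == pytest.approx(15.98, abs=0.01)

    t = estimate_two_point(two_marker_mv(50, 100), 0, 1)
    assert t.r == pytest.approx(0.5)
    assert t.lod == pytest.approx(0.0, abs=1e-9)

    t = estimate_two_point(two_marker_mv(0, 34), 0, 1)
    assert t.r == 0.0
    assert t.lod == pytest.approx(34 * np.log10(2), abs=1e-6)
    assert t.lod == pytest.approx(10.235, abs=0.001)


def test_two_point_grid_oracle_with_unresolved_phase():
    """r-hat equals the brute-force grid maximiser of the exact mixture
    likelihood (grid step 1e-4) within 1e-4."""
    rng = np.random.default_rng(4)
    for trial in range(8):
        n = 30
        sym = rng.integers(0, 2, size=(n, 2)).astype(np.int8)
        pk = np.ones((n, 2), dtype=bool)
        parent = np.arange(n)
        # two founder parents with unresolved phase, 4 offspring each
        parent[:4] = 100
        parent[4:8] = 101
        pk[:8] = False
        mv = symbol_mv(sym, phase_known=pk, parent_index=parent)
        t = estimate_two_point(mv, 0, 1)

        def loglik(r):
            r = min(max(r, 1e-12), 0.5)
            ll = 0.0
            x = (sym[8:, 0] != sym[8:, 1]).astype(int)
            ll += (x * np.log(r) + (1 - x) * np.log(1 - r)).sum()
            for rows in (range(4), range(4, 8)):
                x = np.array([sym[i, 0] != sym[i, 1] for i in rows], dtype=int)
                a = (x * np.log(r) + (1 - x) * np.log(1 - r)).sum()
                b = ((1 - x) * np.log(r) + x * np.log(1 - r)).sum()
                mx = max(a, b)
                ll += mx + np.log(0.5 * (np.exp(a - mx) + np.exp(b - mx)))
            return ll

        grid = np.arange(0.0, 0.5 + 1e-9, 1e-4)
        best = grid[np.argmax([loglik(r) for r in grid])]
        assert abs(t.r - best) <= 1e-4 + 1e-9, (trial, t.r, best)


def test_allele_relabel_invariance():
    """Flipping the allele coding at one marker leaves r-hat and LOD
    unchanged (the symbol frame absorbs the relabeling)."""
    rng = np.random.default_rng(1)
    sym = rng.integers(0, 2, size=(60, 2)).astype(np.int8)
    pk = np.ones((60, 2), dtype=bool)
    pk[:10] = False
    parent = np.arange(60)
    parent[:10] = 99
    mv1 = symbol_mv(sym, phase_known=pk, parent_index=parent)
    sym2 = sym.copy()
    # relabeling allele A<->B flips the allele-frame symbol at that marker for
    # unresolved rows; resolved rows keep their origin-frame symbol
    sym2[:10, 1] = 1 - sym2[:10, 1]
    mv2 = symbol_mv(sym2, phase_known=pk, parent_index=parent)
    t1 = estimate_two_point(mv1, 0, 1)
    t2 = estimate_two_point(mv2, 0, 1)
    assert t1.r == pytest.approx(t2.r, abs=1e-9)
    assert t1.lod == pytest.approx(t2.lod, abs=1e-9)


def test_pooled_r_between_sex_specific(small_mv):
    im = small_mv.im()
    top = np.argsort(-im)[:6]
    found = 0
    for i in top:
        for j in top:
            if i >= j:
                continue
            t = estimate_two_point(small_mv, int(i), int(j))
            if np.isnan(t.r_female) or np.isnan(t.r_male) or t.n < 10:
                continue
            lo, hi = sorted([t.r_female, t.r_male])
            assert lo - 1e-9 <= t.r <= hi + 1e-9
            found += 1
    assert found > 0


def test_meiosis_vector_examples():
    # offspring of AB x AA receiving B -> fixed symbol
    gm, ped = trio_matrix([1], [0], [1])
    mv = infer_meiosis_vectors(gm, ped)
    sire_row = mv.meioses["parent_sex"] == 1
    assert (mv.sym[sire_row.to_numpy()] != -1).all()
    # offspring AB of AB x AB -> unknown
    gm, ped = trio_matrix([1], [1], [1])
    mv = infer_meiosis_vectors(gm, ped)
    assert (mv.sym == -1).all()
    # ungenotyped parent -> that meiosis has no symbols
    gm, ped = trio_matrix([-1], [1], [0])
    mv = infer_meiosis_vectors(gm, ped)
    dam_row = (mv.meioses["parent_sex"] == 2).to_numpy()
    sire_row = (mv.meioses["parent_sex"] == 1).to_numpy()
    assert (mv.sym[dam_row] != -1).all()  # dam het, off hom -> informative
    assert (mv.sym[sire_row] == -1).all()


def test_im_matches_qc_count(small_sim, small_qc, small_mv):
    gm, _ = small_qc
    im_qc = count_informative_meioses(gm, small_sim.pedigree)["im"].to_numpy()
    assert np.array_equal(small_mv.im(), im_qc)


def test_autogroup_rules():
    tp = pd.DataFrame(
        {
            "marker_a": ["A", "B", "A", "D"],
            "marker_b": ["B", "C", "C", "E"],
            "lod": [9.0, 9.0, 2.0, 7.9],
        }
    )
    groups = autogroup(tp, ["A", "B", "C", "D", "E", "F"], lod_threshold=8.0)
    assert ["A", "B", "C"] in groups  # transitive closure
    assert ["D"] in groups and ["E"] in groups  # 7.9 below threshold
    assert ["F"] in groups  # singleton reported


def test_assign_chromosomes():
    table = pd.DataFrame(
        {
            "marker": [f"M{i}" for i in range(8)],
            "chrom": ["A1"] * 3 + ["A2"] * 1 + ["B1"] * 2 + ["B2"] * 2,
            "bp": range(8),
        }
    )
    groups = [["M0", "M1", "M2", "M3"], ["M4", "M5"], ["M6", "M7"]]
    gt, disc = assign_chromosomes(groups, table)
    assert gt.loc[0, "label"] == "A1" and not gt.loc[0, "tie"]
    assert list(disc["marker"]) == ["M3"]
    # 50/50 split -> tie, unlabeled
    gt2, _ = assign_chromosomes([["M4", "M5", "M6", "M7"]], table)
    assert gt2.loc[0, "label"] is None and gt2.loc[0, "tie"]


def test_two_point_all_matches_single(small_mv):
    im = small_mv.im()
    top = np.argsort(-im)[:4]
    pairs = [(int(top[0]), int(top[1])), (int(top[2]), int(top[3]))]
    fast = two_point_all(small_mv, pairs=pairs)
    exact = two_point_all(small_mv, pairs=pairs, exact=True)
    # the fast path uses resolved meioses only; counts must agree on k<=n
    assert (fast["k"] <= fast["n"]).all()
    assert list(fast["marker_a"]) == list(exact["marker_a"])
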