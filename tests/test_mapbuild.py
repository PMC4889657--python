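"""Map functions, framework build, flips, expanders, residuals, sex maps."""

import itertools

import numpy as np
import pytest

from felmap._hmm import MultipointEngine
from felmap.core import FEMALE, MALE, InputError
from felmap.mapbuild import (
    ChromosomeMap,
    build_framework,
    detect_and_remove_expanders,
    flips_refine,
    insert_markers_windowed,
    inverse_map_distance,
    map_distance,
    place_residual,
    sex_maps,
    _window_assignment,
)

from conftest import chain_mv


def test_map_distance_closed_forms():
    assert map_distance(0.0, "haldane") == 0.0
    assert map_distance(0.0, "kosambi") == 0.0
    assert map_distance(0.1, "haldane") == pytest.approx(11.157, abs=1e-3)
    assert map_distance(0.1, "kosambi") == pytest.approx(10.137, abs=1e-3)
    assert map_distance(0.25, "kosambi") == pytest.approx(25 * np.log(3), abs=1e-9)
    assert map_distance(0.25, "kosambi") == pytest.approx(27.465, abs=1e-3)


def test_map_distance_domain_and_inverse():
    with pytest.raises(InputError):
        map_distance(0.5, "haldane")
    with pytest.raises(InputError):
        map_distance(-0.01, "kosambi")
    r = np.linspace(0.0, 0.45, 20)
    for fn in ("haldane", "kosambi"):
        assert np.allclose(inverse_map_distance(map_distance(r, fn), fn), r, atol=1e-12)
    # kosambi <= haldane, equality only at 0
    rr = np.linspace(0.01, 0.49, 30)
    assert np.all(map_distance(rr, "kosambi") < map_distance(rr, "haldane"))


def test_three_marker_order_enumeration_oracle():
    """Strong data over 3 markers: the framework picks the order whose
    full-EM likelihood is highest among all distinct orders."""
    mv = chain_mv(np.array([0.1, 0.15]), 300, seed=8)
    eng = MultipointEngine(mv)
    best = None
    for order in ([0, 1, 2], [1, 0, 2], [0, 2, 1]):
        _, ll = eng.em(np.array(order), max_iter=300)
        if best is None or ll > best[1]:
            best = (order, ll)
    fw = build_framework(mv, np.arange(3), min_im=0, map_function="haldane")
    got = list(fw.idx)
    assert got == best[0] or got == best[0][::-1]


def test_framework_min_im_strict_boundary(small_mv):
    im = small_mv.im()
    cap = int(np.sort(im)[-3])  # exclude all but the top couple of markers
    fw = build_framework(small_mv, np.arange(small_mv.n_markers), min_im=cap)
    eligible = set(np.flatnonzero(im > cap))
    assert set(fw.idx) <= eligible  # markers at exactly the floor are excluded


def test_single_marker_group_trivial_map(small_mv):
    with pytest.warns(UserWarning):
        fw = build_framework(small_mv, np.arange(1), min_im=0)
    assert fw.length() == 0.0


def test_flips_equals_exhaustive_window_search():
    """On a map no wider than the window, flips must find the global best
    order (up to reversal) among all permutations by full-EM likelihood."""
    rng = np.random.default_rng(9)
    mv = chain_mv(np.array([0.12, 0.08, 0.15, 0.1]), 300, seed=9)
    eng = MultipointEngine(mv)
    scrambled = np.array([0, 2, 1, 3, 4])
    r0, _ = eng.em(scrambled)
    cmap = ChromosomeMap(mv, "1", scrambled, r0, ["LOD1.0"] * 5, "haldane")
    out = flips_refine(cmap, window=5, engine=eng)
    best = None
    for perm in itertools.permutations(range(5)):
        _, ll = eng.em(np.array(perm), max_iter=300)
        if best is None or ll > best[1] + 1e-9:
            best = (list(perm), ll)
    got = list(out.idx)
    assert got == best[0] or got == best[0][::-1]


def test_flips_idempotent_on_optimal_map():
    mv = chain_mv(np.full(4, 0.1), 300, seed=10)
    eng = MultipointEngine(mv)
    order = np.arange(5)
    r, _ = eng.em(order)
    cmap = ChromosomeMap(mv, "1", order, r, ["LOD1.0"] * 5, "haldane")
    out = flips_refine(cmap, window=5, engine=eng)
    assert list(out.idx) in ([0, 1, 2, 3, 4], [4, 3, 2, 1, 0])


def test_reverse_order_preserves_length():
    mv = chain_mv(np.full(7, 0.06), 350, keep=0.8, seed=11)
    eng = MultipointEngine(mv)
    fwd, _ = eng.em(np.arange(8), max_iter=300)
    rev, _ = eng.em(np.arange(8)[::-1], max_iter=300)
    d = lambda r: np.sum(map_distance(np.clip(r, 0, 0.4999), "haldane"))
    assert d(fwd) == pytest.approx(d(rev), rel=1e-6)


def test_expander_removal_boundary():
    """A marker inflating the map > 3 cM is removed; <= 3 cM retained."""
    mv = chain_mv(np.full(5, 0.05), 400, seed=12)
    # corrupt marker 2: random symbols -> spurious recombination around it
    rng = np.random.default_rng(0)
    sym = mv.sym.copy()
    sym[:, 2] = rng.integers(0, 2, len(sym))
    mv.sym = sym
    eng = MultipointEngine(mv)
    order = np.arange(6)
    r, _ = eng.em(order, max_iter=300)
    cmap = ChromosomeMap(mv, "1", order, r, ["framework", "LOD1.0", "LOD1.0", "LOD1.0", "LOD1.0", "framework"], "haldane")
    out, removed = detect_and_remove_expanders(cmap, inflation_threshold=3.0, engine=eng)
    assert "m2" in set(removed["marker"])
    assert (removed["delta_cm"] > 3.0).all()


def test_no_expanders_on_clean_data():
    mv = chain_mv(np.full(5, 0.05), 400, seed=13)
    eng = MultipointEngine(mv)
    order = np.arange(6)
    r, _ = eng.em(order, max_iter=300)
    cmap = ChromosomeMap(mv, "1", order, r, ["LOD1.0"] * 6, "haldane")
    _, removed = detect_and_remove_expanders(cmap, engine=eng)
    assert removed.empty


def test_place_residual_thresholds():
    mv = chain_mv(np.full(5, 0.1), 300, seed=14)
    eng = MultipointEngine(mv)
    order = np.array([0, 1, 2, 4, 5])
    r, _ = eng.em(order)
    cmap = ChromosomeMap(mv, "1", order, r, ["LOD1.0"] * 5, "haldane")
    res = place_residual(cmap, np.array([3]), min_lod=0.1, engine=eng)
    assert res["status"].iloc[0] == "interval-only"
    assert res["left"].iloc[0] == "m2" and res["right"].iloc[0] == "m4"
    # an impossible bar: nothing reaches a huge gap -> unplaced
    res2 = place_residual(cmap, np.array([3]), min_lod=1e6, engine=eng)
    assert res2["status"].iloc[0] == "unplaced"


def test_insertion_preserves_framework_order():
    mv = chain_mv(np.full(9, 0.07), 350, seed=15)
    fw_idx = np.array([0, 3, 6, 9])
    eng = MultipointEngine(mv)
    r, _ = eng.em(fw_idx)
    fw = ChromosomeMap(mv, "1", fw_idx, r, ["framework"] * 4, "haldane")
    out, leftovers = insert_markers_windowed(
        mv, fw, np.arange(10), min_im=0, engine=eng, tiers=(0.5,), flips_each_window=True
    )
    pos = {m: i for i, m in enumerate(out.idx)}
    fw_pos = [pos[m] for m in fw_idx]
    assert fw_pos == sorted(fw_pos) or fw_pos == sorted(fw_pos, reverse=True)


def test_window_assignment_centrality():
    wins = _window_assignment(12, window=6, overlap=2)
    all_assigned = sorted(np.concatenate(wins).tolist())
    assert all_assigned == list(range(12))  # each candidate exactly once


def test_sex_maps_pooled_between_sexes():
    rf, rm = 0.12, 0.06
    rng = np.random.default_rng(16)
    import pandas as pd

    from conftest import symbol_mv

    n = 600
    sym = np.zeros((n, 2), dtype=np.int8)
    sex = np.array([FEMALE] * (n // 2) + [MALE] * (n // 2))
    rec = np.concatenate(
        [rng.random(n // 2) < rf, rng.random(n // 2) < rm]
    )
    sym[:, 1] = rec.astype(np.int8)
    mv = symbol_mv(sym, parent_sex=list(sex))
    cmap = ChromosomeMap(mv, "1", np.arange(2), np.array([0.05]), ["framework"] * 2, "haldane")
    cmap = sex_maps(cmap)
    lo, hi = sorted([cmap.r_female[0], cmap.r_male[0]])
    assert lo - 1e-9 <= cmap.r[0] <= hi + 1e-9
    assert cmap.r_female[0] == pytest.approx(rec[: n // 2].mean(), abs=1e-4)
    assert cmap.r_male[0] == pytest.approx(rec[n // 2 :].mean(), abs=1e-4)
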