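"""Framework-map building, windowed multi-tier insertion, and refinement.

The map is built the way classic pedigree linkage packages do it: a
*framework* of highly informative markers is ordered first, accepting a
marker only when its best insertion position beats the second best by a LOD
threshold (default 3); remaining markers are then positioned against that
fixed backbone in sliding physical windows at successively weaker thresholds
(2.0, 1.0, 0.5); local order is polished by exhaustively permuting short
windows (*flips*); markers that inflate the local map (*expanders*) are
removed; and markers that cannot be positioned at LOD > 0.5 are assigned
their most likely flanking interval only (minimum LOD 0.1).

Interval recombination fractions come from the EM in
:mod:`felmap._hmm`; genetic distances use the Kosambi map function by
default (Haldane selectable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._hmm import R_CEIL, MultipointEngine, order_preserving_perms
from .core import FEMALE, MALE, InputError
from .linkage import MeiosisVectors, two_point_all

__all__ = [
    "map_distance",
    "inverse_map_distance",
    "ChromosomeMap",
    "multipoint_loglik",
    "fit_intervals",
    "build_framework",
    "insert_markers_windowed",
    "flips_refine",
    "detect_and_remove_expanders",
    "place_residual",
    "sex_maps",
    "build_chromosome_map",
]

TIER_FRAMEWORK = "framework"
TIER_INTERVAL = "interval-only"


def map_distance(r, function: str = "kosambi"):
    """Genetic distance (cM) for recombination fraction(s) r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise InputError("map functions are defined for r in [0, 0.5)")
    if function == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * r)
    elif function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    else:
        raise InputError(f"unknown map function {function!r}")
    return float(d) if d.ndim == 0 else d


def inverse_map_distance(d, function: str = "kosambi"):
    """Recombination fraction for genetic distance(s) d (cM)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise InputError("genetic distance must be non-negative")
    if function == "haldane":
        r = 0.5 * (1.0 - np.exp(-d / 50.0))
    elif function == "kosambi":
        r = 0.5 * np.tanh(d / 50.0)
    else:
        raise InputError(f"unknown map function {function!r}")
    return float(r) if r.ndim == 0 else r


@dataclass
class ChromosomeMap:
    """An ordered, positioned marker map for one chromosome.

    ``idx`` indexes the positioned markers into ``mv.markers``; ``r`` holds
    pooled (sex-averaged) interval recombination fractions; ``r_female`` /
    ``r_male`` are filled by :func:`sex_maps`. ``tier`` records placement
    support per positioned marker; ``residual`` holds interval-only
    assignments for markers without a map position.
    """

    mv: MeiosisVectors
    chrom: str
    idx: np.ndarray
    r: np.ndarray
    tier: list[str]
    map_function: str = "kosambi"
    r_female: np.ndarray | None = None
    r_male: np.ndarray | None = None
    sex_undefined: np.ndarray | None = None  # intervals with no sex-specific info
    residual: pd.DataFrame | None = None
    deferred: list[str] = field(default_factory=list)
    expanders: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.idx)

    @property
    def marker_names(self) -> list[str]:
        return list(self.mv.markers["marker"].iloc[self.idx])

    def _cum(self, r: np.ndarray | None) -> np.ndarray:
        if r is None or self.n == 0:
            return np.zeros(max(self.n, 0))
        d = map_distance(np.clip(np.nan_to_num(r, nan=0.0), 0.0, R_CEIL), self.map_function)
        return np.concatenate([[0.0], np.cumsum(d)])

    def cm(self, sex: int | None = None) -> np.ndarray:
        if sex is None:
            return self._cum(self.r)
        return self._cum(self.r_female if sex == FEMALE else self.r_male)

    def length(self, sex: int | None = None) -> float:
        c = self.cm(sex)
        return float(c[-1]) if len(c) else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        mk = self.mv.markers.iloc[self.idx]
        im = self.mv.im()[self.idx]
        out = pd.DataFrame(
            {
                "marker": mk["marker"].to_numpy(),
                "chrom": self.chrom,
                "order": np.arange(self.n),
                "bp": mk["bp"].to_numpy(),
                "cm_avg": self.cm(),
                "cm_female": self.cm(FEMALE),
                "cm_male": self.cm(MALE),
                "tier": self.tier,
                "im": im,
            }
        )
        return out


def multipoint_loglik(
    mv: MeiosisVectors, order: np.ndarray, r: np.ndarray, sex: int | None = None
) -> float:
    """log10 multipoint likelihood of ``order`` (indices into ``mv.markers``)
    at interval recombination fractions ``r``."""
    eng = MultipointEngine(mv, sex=sex)
    return eng.loglik(np.asarray(order), np.asarray(r))


def fit_intervals(
    mv: MeiosisVectors, order: np.ndarray, sex: int | None = None, r_init=None
) -> tuple[np.ndarray, float]:
    """EM-estimate interval recombination fractions for a fixed order."""
    eng = MultipointEngine(mv, sex=sex)
    return eng.em(np.asarray(order), r_init=r_init)


def _insert_r(r: np.ndarray, pos: int, sub: tuple[float, float], length: int) -> np.ndarray:
    ra, rb = sub
    if pos == 0:
        return np.concatenate([[rb], r])
    if pos == length:
        return np.concatenate([r, [ra]])
    return np.concatenate([r[: pos - 1], [ra, rb], r[pos - 1 :][1:]])


def build_framework(
    mv: MeiosisVectors,
    group: np.ndarray,
    lod_threshold: float = 3.0,
    min_im: int = 300,
    map_function: str = "kosambi",
    chrom: str | None = None,
    engine: MultipointEngine | None = None,
    polish_every: int = 10,
) -> ChromosomeMap:
    """Order highly informative markers with strong (LOD >= threshold) support.

    Only markers with IM strictly greater than ``min_im`` are eligible. The
    map is seeded with the most informative pair linked at the threshold;
    candidates are then taken in descending-IM order and accepted only when
    the best insertion position beats the runner-up by ``lod_threshold``
    log10 units; markers that fail are retried after each full pass and
    reported as deferred when no further progress is possible.
    """
    group = np.asarray(group)
    if chrom is None:
        chrom = str(mv.markers["chrom"].iloc[group[0]]) if len(group) else "NA"
    im = mv.im()
    names = mv.markers["marker"].to_numpy()
    eligible = group[im[group] > min_im]
    if len(eligible) < 2:
        warnings.warn(f"chromosome {chrom}: fewer than 2 framework-eligible markers")
        idx = eligible
        return ChromosomeMap(
            mv, chrom, idx, np.empty(0), [TIER_FRAMEWORK] * len(idx), map_function
        )
    order_key = sorted(range(len(eligible)), key=lambda k: (-im[eligible[k]], names[eligible[k]]))
    cands = list(eligible[order_key])
    if engine is None:
        engine = MultipointEngine(mv)

    # Seed with a strongly linked pair that spans a moderate distance. A
    # zero-length pair is left/right symmetric — no third marker could ever
    # distinguish the two ends — and a near-unlinked pair cannot
    # discriminate placement sides at all; a clearly linked pair ~5-30 cM
    # apart breaks the symmetry and lets the map grow outward.
    tp = two_point_all(mv, pairs=[(int(i), int(j)) for k, i in enumerate(eligible) for j in eligible[k + 1 :]])
    tp = tp.dropna(subset=["r"])
    if tp.empty or tp["lod"].max() < lod_threshold:
        warnings.warn(f"chromosome {chrom}: no linked seed pair at LOD {lod_threshold}")
        return ChromosomeMap(
            mv, chrom, np.array([cands[0]]), np.empty(0), [TIER_FRAMEWORK], map_function
        )
    spanning = tp[(tp["r"] >= 0.04) & (tp["r"] <= 0.35) & (tp["lod"] >= lod_threshold)]
    best = (spanning if not spanning.empty else tp).loc[lambda d: d["lod"].idxmax()]
    name_to_idx = {names[c]: c for c in eligible}
    seed_a, seed_b = name_to_idx[best["marker_a"]], name_to_idx[best["marker_b"]]
    order = np.array([seed_a, seed_b])
    cands = [c for c in cands if c not in (seed_a, seed_b)]
    r, _ = engine.em(order)

    deferred: list[int] = []
    placed_since_polish = 0
    while True:
        progressed = False
        todo, deferred = cands + deferred, []
        for c in todo:
            lls, subs = engine.scan_insert(order, r, int(c))
            top = np.argsort(lls)[::-1]
            gap = lls[top[0]] - lls[top[1]]
            if gap >= lod_threshold:
                pos = int(np.flatnonzero(lls == lls.max())[0])  # lowest index on ties
                r = _insert_r(r, pos, subs[pos], len(order))
                order = np.insert(order, pos, c)
                progressed = True
                placed_since_polish += 1
                if placed_since_polish >= polish_every:
                    r, _ = engine.em(order, r_init=r, max_iter=30)
                    placed_since_polish = 0
            else:
                deferred.append(c)
        cands = []
        if not progressed or not deferred:
            break
    r, _ = engine.em(order, r_init=r, max_iter=60)
    return ChromosomeMap(
        mv,
        chrom,
        order,
        r,
        [TIER_FRAMEWORK] * len(order),
        map_function,
        deferred=[names[c] for c in deferred],
    )


def _window_assignment(n: int, window: int, overlap: int) -> list[np.ndarray]:
    """Partition sorted candidate positions 0..n-1 into overlapping windows,
    assigning each candidate to the window whose edges it is farthest from."""
    if n == 0:
        return []
    step = max(window - overlap, 1)
    starts = list(range(0, max(n - overlap, 1), step))
    windows = [(s, min(s + window, n)) for s in starts]
    assign: list[list[int]] = [[] for _ in windows]
    for j in range(n):
        best_w, best_c = None, -1
        for wi, (s, e) in enumerate(windows):
            if s <= j < e:
                c = min(j - s, e - 1 - j)
                if c > best_c:
                    best_w, best_c = wi, c
        assign[best_w].append(j)
    return [np.array(a, dtype=np.int64) for a in assign if len(a)]


def insert_markers_windowed(
    mv: MeiosisVectors,
    framework: ChromosomeMap,
    candidates: np.ndarray,
    window: int = 500,
    overlap: int = 100,
    tiers: tuple[float, ...] = (2.0, 1.0, 0.5),
    min_im: int = 100,
    engine: MultipointEngine | None = None,
    flips_window: int = 6,
    flips_each_window: bool = True,
) -> tuple[ChromosomeMap, list[int]]:
    """Position candidate markers against the framework in physical windows.

    Candidates are partitioned by physical bp into ``window``-marker windows
    stepping by ``window - overlap`` (overlap markers go to the window whose
    edge they are farthest from); within each window, tiers are tried in
    descending order and a candidate is placed when its best-minus-second
    placement log10 likelihood gap reaches the tier. Placed markers join the
    scaffold immediately. Framework relative order is never altered.

    Returns the enlarged map plus the leftover candidate indices for
    :func:`place_residual`.
    """
    im = mv.im()
    names = mv.markers["marker"].to_numpy()
    candidates = np.asarray(candidates)
    candidates = candidates[~np.isin(candidates, framework.idx)]
    if framework.n < 2:
        warnings.warn(
            f"chromosome {framework.chrom}: no framework to insert into; "
            "all candidates left unpositioned"
        )
        return framework, [int(c) for c in candidates]
    skipped = list(candidates[im[candidates] < min_im])
    candidates = candidates[im[candidates] >= min_im]
    bp = mv.markers["bp"].to_numpy()
    srt = candidates[np.argsort(bp[candidates], kind="stable")]
    if engine is None:
        engine = MultipointEngine(mv)

    order = framework.idx.copy()
    r = framework.r.copy()
    tier_of: dict[int, str] = {int(i): TIER_FRAMEWORK for i in framework.idx}
    leftovers: list[int] = list(skipped)

    for win in _window_assignment(len(srt), window, overlap):
        wcands = list(srt[win])
        wcands.sort(key=lambda c: (-im[c], names[c]))
        unplaced = wcands
        for t in tiers:
            still = []
            for c in unplaced:
                if im[c] == 0:
                    leftovers.append(int(c))
                    continue
                lls, subs = engine.scan_insert(order, r, int(c))
                top = np.argsort(lls)[::-1]
                gap = lls[top[0]] - lls[top[1]]
                if gap >= t:
                    pos = int(np.flatnonzero(lls == lls.max())[0])
                    r = _insert_r(r, pos, subs[pos], len(order))
                    order = np.insert(order, pos, c)
                    tier_of[int(c)] = f"LOD{t}"
                else:
                    still.append(c)
            unplaced = still
        leftovers.extend(int(c) for c in unplaced)
        r, _ = engine.em(order, r_init=r, max_iter=30)
        if flips_each_window and len(order) >= 3:
            m = ChromosomeMap(
                mv,
                framework.chrom,
                order,
                r,
                [tier_of[int(i)] for i in order],
                framework.map_function,
            )
            m = flips_refine(m, window=flips_window, engine=engine, respect_framework=True)
            order, r = m.idx, m.r
    r, _ = engine.em(order, r_init=r, max_iter=60)
    out = ChromosomeMap(
        mv,
        framework.chrom,
        order,
        r,
        [tier_of[int(i)] for i in order],
        framework.map_function,
        deferred=framework.deferred,
    )
    return out, leftovers


def flips_refine(
    cmap: ChromosomeMap,
    window: int = 6,
    engine: MultipointEngine | None = None,
    respect_framework: bool = False,
    max_passes: int = 8,
    min_gain: float = 1e-6,
) -> ChromosomeMap:
    """Refine local order by exhaustive permutation of sliding windows.

    Every window of ``window`` consecutive markers (clamped to the map size)
    is permuted exhaustively; interval fractions inside the window are
    re-estimated for each permutation and the best order is adopted when it
    strictly improves the likelihood. Passes repeat until a full pass makes
    no change. With ``respect_framework`` the relative order of framework
    markers is held fixed.
    """
    if cmap.n < 3:
        return cmap
    if engine is None:
        engine = MultipointEngine(cmap.mv)
    order = cmap.idx.copy()
    r = cmap.r.copy()
    tiers = list(cmap.tier)
    w = min(window, cmap.n)
    for _ in range(max_passes):
        changed = False
        for start in range(0, cmap.n - w + 1):
            if respect_framework:
                fixed = np.array([tiers[start + j] == TIER_FRAMEWORK for j in range(w)])
            else:
                fixed = np.zeros(w, dtype=bool)
            perms = order_preserving_perms(w, fixed)
            if len(perms) < 2:
                continue
            vals = engine.scan_window_perms(order, r, start, w, perms, n_em=10)
            ident = int(np.flatnonzero((perms == np.arange(w)).all(axis=1))[0])
            best = int(np.argmax(vals))
            if best != ident and vals[best] > vals[ident] + min_gain:
                seg = order[start : start + w][perms[best]]
                order = order.copy()
                order[start : start + w] = seg
                seg_t = [tiers[start + j] for j in perms[best]]
                tiers[start : start + w] = seg_t
                r, _ = engine.em(order, r_init=r, max_iter=30)
                changed = True
        if not changed:
            break
    r, _ = engine.em(order, r_init=r, max_iter=60)
    return ChromosomeMap(
        cmap.mv,
        cmap.chrom,
        order,
        r,
        tiers,
        cmap.map_function,
        deferred=cmap.deferred,
        residual=cmap.residual,
        expanders=cmap.expanders,
    )


def detect_and_remove_expanders(
    cmap: ChromosomeMap,
    inflation_threshold: float = 3.0,
    engine: MultipointEngine | None = None,
    max_removed: int | None = None,
) -> tuple[ChromosomeMap, pd.DataFrame]:
    """Remove non-framework markers whose removal shrinks the map > threshold cM.

    For each non-framework marker the merged flanking interval is locally
    re-estimated; the marker with the largest map-length reduction is removed
    (one per rebuild, largest first) and the scan repeats to fixpoint.
    """
    if engine is None:
        engine = MultipointEngine(cmap.mv)
    order = cmap.idx.copy()
    r = cmap.r.copy()
    tiers = list(cmap.tier)
    names = cmap.mv.markers["marker"].to_numpy()
    removed: list[tuple[str, float]] = []
    while len(order) >= 3:
        if max_removed is not None and len(removed) >= max_removed:
            break
        best_delta, best_pos, best_rm = 0.0, None, None
        d = map_distance(np.clip(r, 0, R_CEIL), cmap.map_function)
        # Terminal markers only truncate the map; inflation is an interior
        # notion (larger-than-average flanking intervals on both sides).
        for pos in range(1, len(order) - 1):
            if tiers[pos] == TIER_FRAMEWORK:
                continue
            rm = engine.merged_interval(order, r, pos)
            delta = d[pos - 1] + d[pos] - map_distance(min(rm, R_CEIL), cmap.map_function)
            if delta > best_delta:
                best_delta, best_pos, best_rm = delta, pos, rm
        if best_pos is None or best_delta <= inflation_threshold:
            break
        removed.append((names[order[best_pos]], float(best_delta)))
        r = np.concatenate([r[: best_pos - 1], [best_rm], r[best_pos + 1 :]])
        order = np.delete(order, best_pos)
        del tiers[best_pos]
        r, _ = engine.em(order, r_init=r, max_iter=20)
    exp = pd.DataFrame(removed, columns=["marker", "delta_cm"])
    out = ChromosomeMap(
        cmap.mv,
        cmap.chrom,
        order,
        r,
        tiers,
        cmap.map_function,
        deferred=cmap.deferred,
        residual=cmap.residual,
        expanders=exp,
    )
    return out, exp


def place_residual(
    cmap: ChromosomeMap,
    leftovers: np.ndarray,
    min_lod: float = 0.1,
    engine: MultipointEngine | None = None,
) -> pd.DataFrame:
    """Assign leftover markers their most likely flanking interval.

    Markers whose best-vs-second interval log10 gap reaches ``min_lod`` get
    an interval (no cM position, tier "interval-only"); the rest are reported
    unplaced with a reason. The map itself is not modified.
    """
    if engine is None:
        engine = MultipointEngine(cmap.mv)
    names = cmap.mv.markers["marker"].to_numpy()
    order, r = cmap.idx, cmap.r
    rows = []
    im = cmap.mv.im()
    for c in np.asarray(leftovers):
        c = int(c)
        if cmap.n < 2:
            rows.append((names[c], None, None, np.nan, "unplaced", "no map to place against"))
            continue
        if im[c] == 0:
            rows.append((names[c], None, None, np.nan, "unplaced", "no informative meiosis"))
            continue
        lls, _ = engine.scan_insert(order, r, c)
        top = np.argsort(lls)[::-1]
        gap = float(lls[top[0]] - lls[top[1]])
        pos = int(np.flatnonzero(lls == lls.max())[0])
        left = names[order[pos - 1]] if pos > 0 else None
        right = names[order[pos]] if pos < len(order) else None
        if gap >= min_lod:
            rows.append((names[c], left, right, gap, TIER_INTERVAL, ""))
        else:
            rows.append((names[c], None, None, gap, "unplaced", f"gap {gap:.3f} < {min_lod}"))
    out = pd.DataFrame(
        rows, columns=["marker", "left", "right", "lod_gap", "status", "reason"]
    )
    cmap.residual = out
    return out


def sex_maps(
    cmap: ChromosomeMap,
    gm=None,
    ped=None,
    x_chrom: str | None = None,
    par_bp: tuple[int, int] | None = None,
    pair_engine=None,
    max_iter: int = 300,
) -> ChromosomeMap:
    """Estimate female, male, and pooled interval fractions for a fixed order.

    With trio genotypes (``gm``/``ped`` or a prebuilt
    :class:`~felmap._pairhmm.PairChainEngine`) the fractions come from the
    trio-genotype pair-chain EM — the pooled map ties the two sexes to one
    fraction per interval, the sex maps free them. Without genotypes, the
    (coarser) inheritance-symbol likelihood is used per parental sex.
    Intervals with no informative meiosis of a sex bracketing them get a
    0 cM increment for that sex and are flagged in ``sex_undefined``.
    """
    order = cmap.idx
    if cmap.n < 2:
        return cmap
    if pair_engine is None and gm is not None:
        from ._pairhmm import PairChainEngine

        pair_engine = PairChainEngine(gm, ped, x_chrom=x_chrom, par_bp=par_bp)
    if pair_engine is not None:
        r_init = np.clip(np.nan_to_num(cmap.r, nan=0.02), 1e-4, R_CEIL) if cmap.r.size else None
        cmap.r, _ = pair_engine.em(order, tied=True, r_init=r_init, max_iter=max_iter)
        rf, rm, _ = pair_engine.em(
            order, r_init=(cmap.r.copy(), cmap.r.copy()), max_iter=max_iter
        )
        cov_f, cov_m = pair_engine.interval_coverage(order)
        rf = np.asarray(rf, dtype=float)
        rm = np.asarray(rm, dtype=float)
        rf[cov_f == 0] = 0.0
        rm[cov_m == 0] = 0.0
        cmap.r_female, cmap.r_male = rf, rm
        cmap.sex_undefined = (cov_f == 0) | (cov_m == 0)
        return cmap

    mv = cmap.mv
    pooled_eng = MultipointEngine(mv)
    cmap.r, _ = pooled_eng.em(order, r_init=cmap.r, max_iter=max_iter)
    undef = np.zeros((2, cmap.n - 1), dtype=bool)
    for si, sex in enumerate((FEMALE, MALE)):
        eng = MultipointEngine(mv, sex=sex)
        cover = _interval_coverage(mv, order, sex)
        r_sex, _ = eng.em(order, r_init=np.clip(cmap.r, 1e-4, R_CEIL), max_iter=max_iter)
        if r_sex.size and np.isnan(r_sex).all():
            r_sex = np.zeros(cmap.n - 1)
        r_sex = np.asarray(r_sex, dtype=float)
        r_sex[cover == 0] = 0.0
        undef[si] = cover == 0
        if sex == FEMALE:
            cmap.r_female = r_sex
        else:
            cmap.r_male = r_sex
    cmap.sex_undefined = undef[0] | undef[1]
    return cmap


def _interval_coverage(mv: MeiosisVectors, order: np.ndarray, sex: int | None) -> np.ndarray:
    """Number of informative meioses of ``sex`` bracketing each interval."""
    rows = mv.sex_rows(sex)
    sym = mv.sym[np.ix_(rows, order)]
    inf = sym != -1
    cover = np.zeros(len(order) - 1, dtype=np.int64)
    for k in range(inf.shape[0]):
        pos = np.flatnonzero(inf[k])
        if len(pos) >= 2:
            cover[pos[0] : pos[-1]] += 1
    return cover


def build_chromosome_map(
    mv: MeiosisVectors,
    group: np.ndarray,
    *,
    map_function: str = "kosambi",
    framework_lod: float = 3.0,
    framework_min_im: int = 300,
    tiers: tuple[float, ...] = (2.0, 1.0, 0.5),
    min_im: int = 100,
    window: int = 500,
    overlap: int = 100,
    flips_window: int = 6,
    expander_cm: float = 3.0,
    residual_lod: float = 0.1,
    run_sex_maps: bool = True,
    gm=None,
    ped=None,
    x_chrom: str | None = None,
    par_bp: tuple[int, int] | None = None,
) -> ChromosomeMap:
    """Full single-chromosome pipeline: framework, windowed insertion, flips,
    expander removal, residual interval placement, sex-specific maps.

    Ordering decisions use the inheritance-symbol likelihood; when trio
    genotypes (``gm``/``ped``) are supplied, the final interval distances and
    sex maps are re-estimated with the trio-genotype pair-chain EM."""
    group = np.asarray(group)
    engine = MultipointEngine(mv)
    fw = build_framework(
        mv,
        group,
        lod_threshold=framework_lod,
        min_im=framework_min_im,
        map_function=map_function,
        engine=engine,
    )
    if fw.n >= 3:
        fw = flips_refine(fw, window=flips_window, engine=engine)
    cmap, leftovers = insert_markers_windowed(
        mv,
        fw,
        group,
        window=window,
        overlap=overlap,
        tiers=tiers,
        min_im=min_im,
        engine=engine,
        flips_window=flips_window,
    )
    cmap = flips_refine(cmap, window=flips_window, engine=engine, respect_framework=True)
    cmap, _ = detect_and_remove_expanders(cmap, inflation_threshold=expander_cm, engine=engine)
    place_residual(cmap, np.asarray(leftovers, dtype=np.int64), min_lod=residual_lod, engine=engine)
    if run_sex_maps:
        cmap = sex_maps(cmap, gm=gm, ped=ped, x_chrom=x_chrom, par_bp=par_bp)
    return cmap
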