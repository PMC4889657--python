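"""Meiosis inheritance vectors, two-point linkage, and linkage grouping.

The inheritance symbol of a meiosis at a marker says which parental homolog
was transmitted, relative to a per-parent phase reference. Where the parent's
own allele origins are resolved by grandparental genotypes, homolog 0 is the
homolog the parent inherited from its sire and the symbol is in that fixed
frame; elsewhere the symbol is recorded in an allele frame (homolog 0 carries
the A allele) and the marker's phase is treated as a latent variable with
prior 1/2, summed over in likelihoods. Phase is shared across all meioses of
the same parent, which is what lets founder meioses contribute linkage
information through the two-phase mixture likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._transmission import resolve_parent_phase, transmitted_alleles
from .core import FEMALE, MALE, GenotypeMatrix, InputError, Pedigree

__all__ = [
    "MeiosisVectors",
    "TwoPointResult",
    "infer_meiosis_vectors",
    "estimate_two_point",
    "two_point_all",
    "autogroup",
    "assign_chromosomes",
]

LOG10 = np.log(10.0)


@dataclass
class MeiosisVectors:
    """Inheritance symbols for a set of meioses over a marker panel.

    ``sym`` is (n_meioses, n_markers) int8 with -1 where the meiosis is not
    informative; ``phase_known`` marks, per meiosis, the markers where the
    symbol is in the grandparent-resolved frame (it is identical for rows
    sharing a parent). ``parent_index`` groups rows by parent.
    """

    meioses: pd.DataFrame  # parent, offspring, parent_sex
    markers: pd.DataFrame  # marker, chrom, bp
    sym: np.ndarray
    phase_known: np.ndarray
    parent_index: np.ndarray

    @property
    def n_meioses(self) -> int:
        return len(self.meioses)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def im(self) -> np.ndarray:
        """Informative-meiosis count per marker."""
        return (self.sym != -1).sum(axis=0)

    def subset_markers(self, idx: np.ndarray) -> "MeiosisVectors":
        idx = np.asarray(idx)
        return MeiosisVectors(
            meioses=self.meioses,
            markers=self.markers.iloc[idx].reset_index(drop=True),
            sym=self.sym[:, idx],
            phase_known=self.phase_known[:, idx],
            parent_index=self.parent_index,
        )

    def sex_rows(self, sex: int | None) -> np.ndarray:
        if sex is None:
            return np.arange(self.n_meioses)
        return np.flatnonzero(self.meioses["parent_sex"].to_numpy() == sex)


def infer_meiosis_vectors(
    gm: GenotypeMatrix,
    ped: Pedigree,
    x_chrom: str | None = None,
    par_bp: tuple[int, int] | None = None,
) -> MeiosisVectors:
    """Build inheritance vectors for all genotyped parent->offspring pairs."""
    if not set(gm.individuals) <= set(ped.ids):
        raise InputError("genotype matrix contains individuals absent from the pedigree")
    mei, trans = transmitted_alleles(gm, ped, x_chrom=x_chrom, par_bp=par_bp)
    phase = resolve_parent_phase(gm, ped, mei, trans)
    n_mei, n_mark = trans.shape
    sym = np.full((n_mei, n_mark), -1, dtype=np.int8)
    phase_known = np.zeros((n_mei, n_mark), dtype=bool)
    parents = list(dict.fromkeys(mei["parent"]))
    pindex = {p: k for k, p in enumerate(parents)}
    parent_index = np.array([pindex[p] for p in mei["parent"]], dtype=np.int64)
    for k in range(n_mei):
        known, origin0 = phase[mei["parent"].iloc[k]]
        t = trans[k]
        inf = t != -1
        resolved = inf & known
        sym[k, resolved] = (t[resolved] != origin0[resolved]).astype(np.int8)
        unresolved = inf & ~known
        sym[k, unresolved] = t[unresolved]  # allele frame: homolog 0 carries A
        phase_known[k] = known
    return MeiosisVectors(
        meioses=mei,
        markers=gm.markers.copy(),
        sym=sym,
        phase_known=phase_known,
        parent_index=parent_index,
    )


@dataclass
class TwoPointResult:
    marker_a: str
    marker_b: str
    n: int  # joint informative meioses
    k: int  # recombinants among phase-resolved meioses
    r: float
    r_female: float
    r_male: float
    lod: float
    informative: bool = True


def _pair_data(mv: MeiosisVectors, i: int, j: int, rows: np.ndarray):
    """Recombination indicators for one marker pair.

    Returns (x_resolved bool array, list of per-parent arrays of phase
    ambiguous indicators)."""
    si = mv.sym[rows, i]
    sj = mv.sym[rows, j]
    inf = (si != -1) & (sj != -1)
    resolved = inf & mv.phase_known[rows, i] & mv.phase_known[rows, j]
    x_res = (si != sj)[resolved]
    unres = inf & ~resolved
    groups: list[np.ndarray] = []
    if unres.any():
        pidx = mv.parent_index[rows][unres]
        x = (si != sj)[unres]
        for p in np.unique(pidx):
            groups.append(x[pidx == p].astype(np.int64))
    return x_res, groups


def _pair_loglik(r: float, k: int, n_res: int, groups: list[np.ndarray]) -> float:
    """Natural-log likelihood of a pair at recombination fraction r."""
    r = min(max(r, 1e-12), 0.5)
    ll = k * np.log(r) + (n_res - k) * np.log(1.0 - r) if n_res else 0.0
    for x in groups:
        kx = int(x.sum())
        nx = len(x)
        a = kx * np.log(r) + (nx - kx) * np.log(1.0 - r)
        b = (nx - kx) * np.log(r) + kx * np.log(1.0 - r)
        m = max(a, b)
        ll += m + np.log(0.5 * (np.exp(a - m) + np.exp(b - m)))
    return float(ll)


def _estimate_r(x_res: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float, int, int]:
    """Return (r_hat, lod, n, k) maximising the mixture likelihood."""
    k = int(x_res.sum())
    n_res = len(x_res)
    n = n_res + sum(len(g) for g in groups)
    if n == 0:
        return np.nan, 0.0, 0, k
    if not groups:
        r_hat = min(k / n_res, 0.5)
    else:
        res = minimize_scalar(
            lambda r: -_pair_loglik(r, k, n_res, groups),
            bounds=(1e-9, 0.5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        r_hat = float(res.x)
        # The bounded optimiser never lands exactly on the boundary.
        for cand in (1e-12, 0.5):
            if _pair_loglik(cand, k, n_res, groups) >= _pair_loglik(r_hat, k, n_res, groups):
                r_hat = cand
        if r_hat <= 1e-9:
            r_hat = 0.0
    lod = (_pair_loglik(max(r_hat, 1e-12), k, n_res, groups) - _pair_loglik(0.5, k, n_res, groups)) / LOG10
    return float(r_hat), max(float(lod), 0.0), n, k


def estimate_two_point(mv: MeiosisVectors, i: int, j: int) -> TwoPointResult:
    """Two-point recombination fraction and LOD for markers ``i`` and ``j``.

    Phase-resolved meioses contribute a binomial count; meioses with
    unresolved parental phase contribute through an exact two-phase mixture
    per parent. Sex-specific estimates use the corresponding meioses only.
    """
    all_rows = np.arange(mv.n_meioses)
    x_res, groups = _pair_data(mv, i, j, all_rows)
    r_hat, lod, n, k = _estimate_r(x_res, groups)
    r_sex = {}
    for sex in (FEMALE, MALE):
        xs, gs = _pair_data(mv, i, j, mv.sex_rows(sex))
        r_sex[sex], _, _, _ = _estimate_r(xs, gs)
    return TwoPointResult(
        marker_a=str(mv.markers["marker"].iloc[i]),
        marker_b=str(mv.markers["marker"].iloc[j]),
        n=n,
        k=k,
        r=r_hat,
        r_female=r_sex[FEMALE],
        r_male=r_sex[MALE],
        lod=lod,
        informative=n > 0,
    )


def two_point_all(
    mv: MeiosisVectors,
    pairs: list[tuple[int, int]] | None = None,
    *,
    max_bp_span: int | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Two-point results for many pairs.

    Without ``pairs``, all marker pairs are used (optionally banded to pairs
    within ``max_bp_span`` on the same physical chromosome, for speed at
    scale). With ``exact=False`` the estimates use the vectorised
    phase-resolved counts only; ``exact=True`` runs the full mixture per pair.
    """
    if pairs is None:
        m = mv.n_markers
        ii, jj = np.triu_indices(m, k=1)
        if max_bp_span is not None:
            bp = mv.markers["bp"].to_numpy()
            chrom = mv.markers["chrom"].to_numpy()
            keep = (np.abs(bp[ii] - bp[jj]) <= max_bp_span) & (chrom[ii] == chrom[jj])
            ii, jj = ii[keep], jj[keep]
        pairs = list(zip(ii.tolist(), jj.tolist()))
    if exact:
        rows = []
        for i, j in pairs:
            t = estimate_two_point(mv, i, j)
            rows.append((t.marker_a, t.marker_b, t.n, t.k, t.r, t.r_female, t.r_male, t.lod))
        return pd.DataFrame(
            rows, columns=["marker_a", "marker_b", "n", "k", "r", "r_female", "r_male", "lod"]
        )

    known = (mv.sym != -1) & mv.phase_known
    s1 = (mv.sym == 1) & known
    s0 = (mv.sym == 0) & known
    s1f = s1.astype(np.float64)
    s0f = s0.astype(np.float64)
    names = mv.markers["marker"].to_numpy()
    rows = []
    for i, j in pairs:
        n = int((known[:, i] & known[:, j]).sum())
        k = int((s1[:, i] & s0[:, j]).sum() + (s0[:, i] & s1[:, j]).sum())
        if n == 0:
            rows.append((names[i], names[j], 0, 0, np.nan, np.nan, np.nan, 0.0))
            continue
        r = min(k / n, 0.5)
        lod = _lod_binomial(k, n, r)
        rows.append((names[i], names[j], n, k, r, np.nan, np.nan, lod))
    return pd.DataFrame(
        rows, columns=["marker_a", "marker_b", "n", "k", "r", "r_female", "r_male", "lod"]
    )


def _lod_binomial(k: int, n: int, r: float) -> float:
    if n == 0 or r >= 0.5:
        return 0.0
    rr = max(r, 1e-12)
    return float(k * np.log10(rr) + (n - k) * np.log10(1 - rr) + n * np.log10(2.0))


def autogroup(two_point: pd.DataFrame, markers: list[str], lod_threshold: float = 8.0) -> list[list[str]]:
    """Linkage groups as connected components of the LOD >= threshold graph.

    Markers with no qualifying edge come back as singleton groups.
    """
    g = nx.Graph()
    g.add_nodes_from(markers)
    strong = two_point[two_point["lod"] >= lod_threshold]
    g.add_edges_from(zip(strong["marker_a"], strong["marker_b"]))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def assign_chromosomes(
    groups: list[list[str]], marker_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label groups by majority physical chromosome.

    Returns (group table with columns group/label/size/tie, discordance table
    listing markers whose physical chromosome disagrees with the group label).
    Tied majority votes leave the group unlabeled and flagged.
    """
    chrom_of = dict(zip(marker_table["marker"], marker_table["chrom"]))
    grows = []
    drows = []
    for gi, members in enumerate(groups):
        chroms = pd.Series([chrom_of.get(m) for m in members if chrom_of.get(m) is not None])
        if chroms.empty:
            grows.append((gi, None, len(members), False))
            continue
        counts = chroms.value_counts()
        tie = len(counts) > 1 and counts.iloc[0] == counts.iloc[1]
        label = None if tie else counts.index[0]
        grows.append((gi, label, len(members), tie))
        if label is not None:
            for m in members:
                c = chrom_of.get(m)
                if c is not None and c != label:
                    drows.append((gi, m, c, label))
    gt = pd.DataFrame(grows, columns=["group", "label", "size", "tie"])
    dt = pd.DataFrame(drows, columns=["group", "marker", "chrom", "label"])
    return gt, dt
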