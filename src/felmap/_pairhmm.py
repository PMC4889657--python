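"""Trio-genotype pair-chain likelihood for interval distance estimation.

Each offspring with genotyped parents is modelled as a four-state Markov
chain over ordered markers: the state is the pair (maternal transmitted
homolog, paternal transmitted homolog); the maternal bit switches with the
female interval recombination fraction r_f, the paternal bit with the male
r_m. The emission at a marker is the probability of the offspring's observed
genotype given the two transmitted homologs, marginalising each parent's
unresolved phase per marker with prior 1/2 and a missing parental call with
the sample allele frequency.

This models the trio genotypes themselves rather than pre-extracted
inheritance symbols, so markers where the transmitted allele is ambiguous
(for example het x het -> het) contribute their partial information instead
of being dropped — dropping them selects on the hidden states (the
ambiguity pattern depends on which homologs were transmitted) and biases
interval estimates. Interval fractions are estimated by EM, either
separately per sex or tied (r_f = r_m), the latter giving the sex-averaged
map.

On the X chromosome outside the pseudoautosomal region male offspring carry
a maternal bit only, and a father's hemizygous genotype pins his
transmitted allele for daughters; the paternal bit is then uninformative
and its fraction must be constrained by interval coverage (see
``interval_coverage``).
"""

from __future__ import annotations

import numpy as np

from ._transmission import resolve_parent_phase, transmitted_alleles
from .core import MALE, MISSING, GenotypeMatrix, InputError, Pedigree, par_mask

R_FLOOR = 1e-6
R_CEIL = 0.499999

_SWAP_MAT = np.array([1, 0, 3, 2])  # flip maternal bit
_SWAP_PAT = np.array([2, 3, 0, 1])  # flip paternal bit
_BIT_MAT = np.array([0, 1, 0, 1])
_BIT_PAT = np.array([0, 0, 1, 1])
_D_MAT = _BIT_MAT[:, None] != _BIT_MAT[None, :]
_D_PAT = _BIT_PAT[:, None] != _BIT_PAT[None, :]


def _parent_allele_dist(
    geno: np.ndarray,
    known: np.ndarray,
    origin0: np.ndarray,
    freq: np.ndarray,
) -> np.ndarray:
    """P(transmitted allele | transmitted homolog bit) per marker.

    Returns (M, 2 bits, 2 alleles). Homozygous markers are point masses for
    both bits; resolved heterozygous markers put homolog 0's allele on bit 0;
    unresolved heterozygous markers are 1/2-1/2 for either bit (per-marker
    phase prior); missing calls use the sample allele frequency.
    """
    M = len(geno)
    pi = np.empty((M, 2, 2))
    pi[:, :, 1] = (freq[:, None] if freq.ndim == 1 else freq)
    pi[:, :, 0] = 1.0 - pi[:, :, 1]
    hom0 = geno == 0
    pi[hom0] = [[1.0, 0.0], [1.0, 0.0]]
    hom2 = geno == 2
    pi[hom2] = [[0.0, 1.0], [0.0, 1.0]]
    het = geno == 1
    unres = het & ~known
    pi[unres] = [[0.5, 0.5], [0.5, 0.5]]
    res = het & known
    a0 = origin0[res]
    block = np.zeros((int(res.sum()), 2, 2))
    block[np.arange(len(a0)), 0, a0] = 1.0
    block[np.arange(len(a0)), 1, 1 - a0] = 1.0
    pi[res] = block
    return pi


class PairChainEngine:
    """EM estimation of per-interval r_f / r_m from trio genotypes.

    Chains are offspring with at least one genotyped parent (an ungenotyped
    parent is marginalised at the sample allele frequency, leaving its bit
    uninformative). ``marker_idx`` selects the marker universe; orders passed
    to :meth:`em` index into it.
    """

    def __init__(
        self,
        gm: GenotypeMatrix,
        ped: Pedigree,
        marker_idx: np.ndarray | None = None,
        x_chrom: str | None = None,
        par_bp: tuple[int, int] | None = None,
    ):
        if marker_idx is None:
            marker_idx = np.arange(gm.n_markers)
        self.marker_idx = np.asarray(marker_idx)
        midx = self.marker_idx
        geno = gm.geno
        called = geno != MISSING
        with np.errstate(invalid="ignore"):
            freq_all = np.where(
                called.sum(axis=0) > 0,
                (geno * called).sum(axis=0) / (2.0 * np.maximum(called.sum(axis=0), 1)),
                0.5,
            )
        mei, trans = transmitted_alleles(gm, ped, x_chrom=x_chrom, par_bp=par_bp)
        phase = resolve_parent_phase(gm, ped, mei, trans)
        xh = par_mask(gm.markers, x_chrom, par_bp)[midx]

        offspring = sorted(
            {o for o in ped.table.loc[ped.table["sire"] != "0", "id"] if o in set(gm.individuals)},
            key=gm.row_of,
        )
        M = len(midx)
        chains: list[np.ndarray] = []
        info_m: list[np.ndarray] = []
        info_p: list[np.ndarray] = []
        self.offspring: list[str] = []
        present = set(gm.individuals)
        freq = freq_all[midx]
        default_pi = np.empty((M, 2, 2))
        default_pi[:, :, 1] = freq[:, None]
        default_pi[:, :, 0] = 1.0 - freq[:, None]

        for off in offspring:
            sire, dam = ped.parents_of(off)
            if (sire not in present) and (dam not in present):
                continue
            g_o = geno[gm.row_of(off)][midx]

            def dist(parent: str | None) -> np.ndarray:
                if parent is None or parent not in present:
                    return default_pi
                g = geno[gm.row_of(parent)][midx]
                if parent in phase:
                    known, origin0 = phase[parent]
                    known, origin0 = known[midx], origin0[midx]
                else:
                    known = np.zeros(M, dtype=bool)
                    origin0 = np.full(M, -1, dtype=np.int8)
                return _parent_allele_dist(g, known, np.where(origin0 < 0, 0, origin0), freq)

            pi_d = dist(dam)
            pi_s = dist(sire)
            # e[m, s] = sum_{ad,as} pi_d[m, b0(s), ad] * pi_s[m, b1(s), as]
            #           * 1(ad + as == g_o[m])
            e = np.ones((M, 4))
            obs = g_o != MISSING
            for s in range(4):
                b0, b1 = _BIT_MAT[s], _BIT_PAT[s]
                p = np.zeros(M)
                for ad in (0, 1):
                    as_ = g_o - ad
                    valid = obs & (as_ >= 0) & (as_ <= 1)
                    p[valid] += (
                        pi_d[valid, b0, ad] * pi_s[valid, b1, np.clip(as_[valid], 0, 1)]
                    )
                e[obs, s] = p[obs]
            if xh.any():
                male_off = ped.sex_of(off) == MALE
                if male_off:
                    # X from dam only; coded genotype duplicates the allele.
                    for s in range(4):
                        b0 = _BIT_MAT[s]
                        ok = obs & xh & (g_o != 1)
                        e[ok & xh, s] = 1.0  # reset
                        sel = obs & xh & (g_o != 1)
                        e[sel, s] = pi_d[sel, b0, (g_o[sel] // 2)]
                    bad = obs & xh & (g_o == 1)  # impossible het call; ignore
                    e[bad] = 1.0
            # Inconsistent observations (surviving Mendelian errors): skip.
            zero = e.sum(axis=1) == 0
            e[zero] = 1.0
            chains.append(e)
            var_m = (np.abs(e[:, _SWAP_MAT] - e) > 1e-12).any(axis=1)
            var_p = (np.abs(e[:, _SWAP_PAT] - e) > 1e-12).any(axis=1)
            info_m.append(var_m)
            info_p.append(var_p)
            self.offspring.append(off)

        self.E = np.stack(chains) if chains else np.empty((0, M, 4))
        self.info_m = np.stack(info_m) if chains else np.empty((0, M), dtype=bool)
        self.info_p = np.stack(info_p) if chains else np.empty((0, M), dtype=bool)
        self.M = M

    @property
    def n_chains(self) -> int:
        return self.E.shape[0]

    @staticmethod
    def _apply_T(v: np.ndarray, rf, rm) -> np.ndarray:
        out = (1.0 - rf) * v + rf * v[..., _SWAP_MAT]
        return (1.0 - rm) * out + rm * out[..., _SWAP_PAT]

    def _active(self, order: np.ndarray) -> np.ndarray:
        inf = self.info_m[:, order] | self.info_p[:, order]
        return inf.sum(axis=1) >= 2

    def interval_coverage(self, order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Chains whose maternal / paternal informative span brackets each
        interval of ``order`` — intervals with zero coverage for a sex leave
        that sex's fraction unidentified."""
        order = np.asarray(order)
        cov = []
        for info in (self.info_m, self.info_p):
            sub = info[:, order]
            c = np.zeros(len(order) - 1, dtype=np.int64)
            for k in range(sub.shape[0]):
                pos = np.flatnonzero(sub[k])
                if len(pos) >= 2:
                    c[pos[0] : pos[-1]] += 1
            cov.append(c)
        return cov[0], cov[1]

    def em(
        self,
        order: np.ndarray,
        tied: bool = False,
        r_init: np.ndarray | tuple[np.ndarray, np.ndarray] | None = None,
        max_iter: int = 300,
        tol: float = 1e-10,
    ):
        """EM for interval recombination fractions over a fixed order.

        With ``tied`` the two sexes share one fraction per interval
        (sex-averaged map): returns (r, loglik). Otherwise returns
        (r_f, r_m, loglik). Intervals without informative coverage for a sex
        stay at their current value; callers should zero them using
        :meth:`interval_coverage`.
        """
        order = np.asarray(order)
        L = len(order)
        if L < 2:
            return (np.empty(0), 0.0) if tied else (np.empty(0), np.empty(0), 0.0)
        act = self._active(order)
        E = self.E[act][:, order, :]
        n = E.shape[0]
        if n == 0:
            nanv = np.full(L - 1, np.nan)
            return (nanv, 0.0) if tied else (nanv, nanv.copy(), 0.0)
        if tied:
            r = np.full(L - 1, 0.02) if r_init is None else np.asarray(r_init, dtype=float).copy()
            rf = rm = None
        else:
            if r_init is None:
                rf, rm = np.full(L - 1, 0.02), np.full(L - 1, 0.02)
            else:
                rf = np.asarray(r_init[0], dtype=float).copy()
                rm = np.asarray(r_init[1], dtype=float).copy()
        prev = -np.inf
        ll = 0.0
        for _ in range(max_iter):
            cur_f = r if tied else rf
            cur_m = r if tied else rm
            cur_f = np.clip(cur_f, R_FLOOR, R_CEIL)
            cur_m = np.clip(cur_m, R_FLOOR, R_CEIL)
            # forward
            alphas = np.empty((L, n, 4))
            a = E[:, 0, :].copy()
            s = a.sum(axis=1, keepdims=True)
            ll = np.log10(s).sum()
            a /= s
            alphas[0] = a
            for i in range(1, L):
                a = self._apply_T(a, cur_f[i - 1], cur_m[i - 1]) * E[:, i, :]
                s = a.sum(axis=1, keepdims=True)
                ll += np.log10(np.maximum(s, 1e-300)).sum()
                a /= np.maximum(s, 1e-300)
                alphas[i] = a
            # backward (d = e * beta, normalised)
            ds = np.empty((L, n, 4))
            d = E[:, L - 1, :] / np.maximum(E[:, L - 1, :].sum(axis=1, keepdims=True), 1e-300)
            ds[L - 1] = d
            for i in range(L - 2, -1, -1):
                d = E[:, i, :] * self._apply_T(d, cur_f[i], cur_m[i])
                d /= np.maximum(d.sum(axis=1, keepdims=True), 1e-300)
                ds[i] = d
            # E-step
            f_m = np.zeros(L - 1)
            f_p = np.zeros(L - 1)
            for i in range(L - 1):
                tf = np.array([[1 - cur_f[i], cur_f[i]], [cur_f[i], 1 - cur_f[i]]])
                tm = np.array([[1 - cur_m[i], cur_m[i]], [cur_m[i], 1 - cur_m[i]]])
                T = tf[_BIT_MAT[:, None], _BIT_MAT[None, :]] * tm[_BIT_PAT[:, None], _BIT_PAT[None, :]]
                AW = alphas[i] @ (T * _D_MAT)
                AP = alphas[i] @ (T * _D_PAT)
                AT = alphas[i] @ T
                den = np.maximum((AT * ds[i + 1]).sum(axis=1), 1e-300)
                f_m[i] = ((AW * ds[i + 1]).sum(axis=1) / den).sum()
                f_p[i] = ((AP * ds[i + 1]).sum(axis=1) / den).sum()
            if tied:
                r = np.clip((f_m + f_p) / (2.0 * n), R_FLOOR, R_CEIL)
            else:
                rf = np.clip(f_m / n, R_FLOOR, R_CEIL)
                rm = np.clip(f_p / n, R_FLOOR, R_CEIL)
            if abs(ll - prev) < tol * max(abs(ll), 1.0) + 1e-12:
                break
            prev = ll
        if tied:
            return r, float(ll)
        return rf, rm, float(ll)
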