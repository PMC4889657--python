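"""Multipoint inheritance-vector likelihood engine.

Model: per meiosis, the transmitted parental homolog along an ordered set of
markers is a two-state Markov chain whose transition probability on interval i
is the interval recombination fraction r_i. Observed inheritance symbols fix
the state where known. Meioses of a parent whose phase is grandparent-resolved
everywhere are independent chains; the remaining meioses are grouped per
parent into joint chains over all offspring (state space 2^K), because the
parent's unknown per-marker phase is shared across its offspring — the
emission at each unresolved marker sums over the two phases with prior 1/2,
which is exact since founder phases are independent across markers.

Likelihood convention: the per-chain likelihood starts from an all-ones state
vector (no initial 1/2 factor per offspring); a fully observed phase-known
meiosis with symbols s_1..s_m has likelihood prod_i P(s_i -> s_{i+1}).

Interval r's are estimated by EM (expected recombinations over expected
informative transitions). Insertion scans and window-permutation (flips)
scans re-estimate only the intervals they touch, against cached forward and
backward messages for the fixed part of the map.
"""

from __future__ import annotations

import itertools

import numpy as np

from .core import InputError
from .linkage import MeiosisVectors

LOG10 = np.log(10.0)
R_FLOOR = 1e-6
R_CEIL = 0.499999


def _as_r(r):
    """Shape r for broadcasting over (..., U, S) state arrays."""
    r = np.asarray(r, dtype=float)
    return r[..., None, None] if r.ndim else r


class _IndBlock:
    """Batch of independent (phase-resolved) meioses; state space {0, 1}."""

    def __init__(self, sym: np.ndarray):
        self.sym = sym  # (U, M) int8, -1 unknown
        self.U = sym.shape[0]
        self.S = 2
        self.K = 1
        self.n_trans_units = self.U

    def emis(self, m: int) -> np.ndarray:
        s = self.sym[:, m]
        e = np.ones((self.U, 2))
        e[s == 0, 1] = 0.0
        e[s == 1, 0] = 0.0
        return e

    def emis_batch(self, m_idx: np.ndarray) -> np.ndarray:
        # (P,) marker indices -> (P, U, 2)
        s = self.sym[:, m_idx].T  # (P, U)
        e = np.ones(s.shape + (2,))
        e[..., 1][s == 0] = 0.0
        e[..., 0][s == 1] = 0.0
        return e

    def ones(self) -> np.ndarray:
        return np.ones((self.U, 2))

    def apply_T(self, v: np.ndarray, r) -> np.ndarray:
        r = _as_r(r)
        return (1.0 - r) * v + r * v[..., ::-1]

    def exp_flips(self, alpha: np.ndarray, d: np.ndarray, r) -> np.ndarray:
        """Expected recombination count summed over units; leading dims kept."""
        r = np.asarray(r, dtype=float)
        rr = r[..., None] if r.ndim else r
        stay = (1.0 - rr) * (alpha[..., 0] * d[..., 0] + alpha[..., 1] * d[..., 1])
        flip = rr * (alpha[..., 0] * d[..., 1] + alpha[..., 1] * d[..., 0])
        tot = stay + flip
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, flip / np.where(tot > 0, tot, 1.0), 0.0)
        return p.sum(axis=-1)


class _FamBlock:
    """Joint chain over one parent's K phase-unresolved meioses; 2^K states."""

    def __init__(self, sym: np.ndarray, phase_known: np.ndarray):
        self.sym = sym  # (K, M)
        self.K = sym.shape[0]
        self.S = 1 << self.K
        self.U = 1
        self.n_trans_units = self.K
        states = np.arange(self.S)
        self.bits = ((states[:, None] >> np.arange(self.K)) & 1).astype(np.int8)  # (S, K)
        self.pc = (self.bits[:, None, :] != self.bits[None, :, :]).sum(axis=2)  # (S, S)
        self.flip_idx = [states ^ (1 << k) for k in range(self.K)]
        # Precompute emission table (M, S).
        M = sym.shape[1]
        E = np.ones((M, self.S))
        for m in range(M):
            inf = np.flatnonzero(sym[:, m] != -1)
            if len(inf) == 0:
                continue
            match0 = np.ones(self.S)
            match1 = np.ones(self.S)
            for k in inf:
                o = sym[k, m]
                match0 *= self.bits[:, k] == o
                match1 *= self.bits[:, k] == 1 - o
            if phase_known[m]:
                E[m] = match0
            else:
                E[m] = 0.5 * match0 + 0.5 * match1
        self.E = E

    def emis(self, m: int) -> np.ndarray:
        return self.E[m][None, :]

    def emis_batch(self, m_idx: np.ndarray) -> np.ndarray:
        return self.E[m_idx][:, None, :]  # (P, 1, S)

    def ones(self) -> np.ndarray:
        return np.ones((1, self.S))

    def apply_T(self, v: np.ndarray, r) -> np.ndarray:
        r = _as_r(r)
        out = v
        for k in range(self.K):
            out = (1.0 - r) * out + r * out[..., self.flip_idx[k]]
        return out

    def exp_flips(self, alpha: np.ndarray, d: np.ndarray, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        rr = r[..., None, None] if r.ndim else r
        T = np.power(rr, self.pc) * np.power(1.0 - rr, self.K - self.pc)
        xi = alpha[..., 0, :, None] * T * d[..., 0, None, :]
        tot = xi.sum(axis=(-1, -2))
        num = (xi * self.pc).sum(axis=(-1, -2))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, num / np.where(tot > 0, tot, 1.0), 0.0)


def _normalize(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = v.sum(axis=-1, keepdims=True)
    s = np.where(s > 0, s, 1.0)
    return v / s, np.log10(s[..., 0])


class MultipointEngine:
    """Likelihood, EM, and scan operations over a fixed meiosis data set.

    ``marker_idx`` selects the marker universe out of ``mv``; all orders
    passed to methods are integer arrays of positions within that universe.
    ``sex`` restricts to meioses of one parental sex (1 male / 2 female).

    By default each meiosis is an independent chain: symbols at markers whose
    parental phase is unresolved are treated as free, each contributing a
    constant factor 1/2 (the per-marker phase sum for a single offspring).
    With ``joint_families=True`` the offspring of a phase-unresolved parent
    are instead modelled jointly (state space 2^K), summing the shared
    per-marker phase exactly — slower, but it recovers linkage information
    from founder meioses; parents with more than ``max_family`` coupled
    offspring are split into chunks of that size.
    """

    def __init__(
        self,
        mv: MeiosisVectors,
        marker_idx: np.ndarray | None = None,
        sex: int | None = None,
        max_family: int = 6,
        joint_families: bool = False,
    ):
        if marker_idx is None:
            marker_idx = np.arange(mv.n_markers)
        self.marker_idx = np.asarray(marker_idx)
        rows = mv.sex_rows(sex)
        sym = mv.sym[np.ix_(rows, self.marker_idx)]
        pk = mv.phase_known[np.ix_(rows, self.marker_idx)]
        parent = mv.parent_index[rows]

        # A parent's offspring need joint treatment only when some
        # phase-unknown marker is informative in >= 2 of them; only then does
        # the shared phase couple the chains. Otherwise the per-marker phase
        # sum factorises across offspring exactly: each unresolved
        # informative call contributes a constant factor 1/2 and the symbol
        # is dropped from the (now independent) chain.
        inf = sym != -1
        unres = inf & ~pk
        fam_parents: set[int] = set()
        if joint_families:
            for p in np.unique(parent):
                rows_p = np.flatnonzero(parent == p)
                if len(rows_p) >= 2 and (unres[rows_p].sum(axis=0) >= 2).any():
                    fam_parents.add(int(p))
        is_fam = np.isin(parent, list(fam_parents))
        ind_sym = sym[~is_fam].copy()
        self.ind_half = unres[~is_fam]  # dropped phase-unknown informative calls
        ind_sym[self.ind_half] = -1
        self.ind = _IndBlock(ind_sym)
        self.fams: list[_FamBlock] = []
        fam_rows = np.flatnonzero(is_fam)
        for p in sorted(fam_parents):
            rows_p = fam_rows[parent[fam_rows] == p]
            # Parent-level phase flags (identical across the parent's rows).
            pk_p = pk[rows_p[0]]
            for start in range(0, len(rows_p), max_family):
                chunk = rows_p[start : start + max_family]
                self.fams.append(_FamBlock(sym[chunk], pk_p))
        self.M = len(self.marker_idx)

    # -- helpers ---------------------------------------------------------

    def _active_blocks(self, order: np.ndarray):
        """(blocks restricted to informative units, constant log10 term)."""
        order = np.asarray(order)
        counts = (self.ind.sym[:, order] != -1).sum(axis=1)
        active = counts >= 2
        const = np.log10(2.0) * int((counts == 0).sum())
        # Factored-out phase sums: 1/2 per dropped unresolved informative call.
        const -= np.log10(2.0) * int(self.ind_half[:, order].sum())
        blocks: list = []
        if active.any():
            blocks.append(_IndBlock(self.ind.sym[active]))
        for f in self.fams:
            n_inf = int((f.sym[:, order] != -1).sum())
            if n_inf >= 2:
                blocks.append(f)
            else:
                # Constant contribution of an uninformative family chain.
                const += np.log10(f.S) - (np.log10(2.0) if n_inf == 1 else 0.0)
        return blocks, const

    def n_transition_units(self, order: np.ndarray) -> int:
        blocks, _ = self._active_blocks(order)
        return sum(b.n_trans_units for b in blocks)

    # -- likelihood and EM ----------------------------------------------

    def loglik(self, order: np.ndarray, r: np.ndarray) -> float:
        """Total log10 likelihood of ``order`` with interval fractions ``r``."""
        order = np.asarray(order)
        r = np.asarray(r, dtype=float)
        if len(r) != len(order) - 1:
            raise InputError("need one recombination fraction per adjacent interval")
        blocks, const = self._active_blocks(order)
        total = const
        for b in blocks:
            alpha, clog = _normalize(b.emis(order[0]))
            tot = clog.sum()
            for i in range(1, len(order)):
                alpha = b.apply_T(alpha, r[i - 1]) * b.emis(order[i])
                alpha, clog = _normalize(alpha)
                tot += clog.sum()
            total += tot
        return float(total)

    def _fb(self, order: np.ndarray, r: np.ndarray, blocks):
        """Forward/backward messages per block.

        Returns (alphas, ds, loglik): alphas[b][i] normalized forward message
        after emission at position i; ds[b][i] normalized e*beta message at
        position i."""
        L = len(order)
        alphas, ds = [], []
        total = 0.0
        for b in blocks:
            al = [None] * L
            dl = [None] * L
            alpha, clog = _normalize(b.emis(order[0]))
            tot = clog.sum()
            al[0] = alpha
            for i in range(1, L):
                alpha = b.apply_T(alpha, r[i - 1]) * b.emis(order[i])
                alpha, clog = _normalize(alpha)
                tot += clog.sum()
                al[i] = alpha
            d, _ = _normalize(b.emis(order[L - 1]))
            dl[L - 1] = d
            for i in range(L - 2, -1, -1):
                d = b.emis(order[i]) * b.apply_T(d, r[i])
                d, _ = _normalize(d)
                dl[i] = d
            alphas.append(al)
            ds.append(dl)
            total += tot
        return alphas, ds, total

    def em(
        self,
        order: np.ndarray,
        r_init: np.ndarray | None = None,
        max_iter: int = 100,
        tol: float = 1e-8,
    ) -> tuple[np.ndarray, float]:
        """EM-estimate interval recombination fractions for a fixed order."""
        order = np.asarray(order)
        L = len(order)
        if L < 2:
            return np.empty(0), 0.0
        r = (
            np.full(L - 1, 0.05)
            if r_init is None
            else np.clip(np.asarray(r_init, dtype=float), R_FLOOR, R_CEIL)
        )
        blocks, const = self._active_blocks(order)
        n_units = sum(b.n_trans_units for b in blocks)
        if n_units == 0:
            return np.full(L - 1, np.nan), const
        prev = -np.inf
        ll = const
        for _ in range(max_iter):
            alphas, ds, ll = self._fb(order, r, blocks)
            ll += const
            flips = np.zeros(L - 1)
            for bi, b in enumerate(blocks):
                for i in range(L - 1):
                    flips[i] += b.exp_flips(alphas[bi][i], ds[bi][i + 1], r[i])
            r = np.clip(flips / n_units, R_FLOOR, R_CEIL)
            if abs(ll - prev) < tol * max(abs(ll), 1.0) + 1e-12:
                break
            prev = ll
        return r, float(ll)

    # -- insertion scan --------------------------------------------------

    def _cached_messages(self, order: np.ndarray, r: np.ndarray, blocks):
        """Per-block per-position forward/backward messages with running
        per-block cumulative log10 scale totals."""
        L = len(order)
        A, D = [], []
        SL = np.zeros(L)  # cumulative left log10 totals, after position i
        SR = np.zeros(L)
        for b in blocks:
            al = [None] * L
            dl = [None] * L
            alpha, clog = _normalize(b.emis(order[0]))
            cum = clog.sum()
            al[0] = alpha
            SL[0] += cum
            for i in range(1, L):
                alpha = b.apply_T(alpha, r[i - 1]) * b.emis(order[i])
                alpha, clog = _normalize(alpha)
                cum += clog.sum()
                al[i] = alpha
                SL[i] += cum
            d, clog = _normalize(b.emis(order[L - 1]))
            cum = clog.sum()
            dl[L - 1] = d
            SR[L - 1] += cum
            for i in range(L - 2, -1, -1):
                d = b.emis(order[i]) * b.apply_T(d, r[i])
                d, clog = _normalize(d)
                cum += clog.sum()
                dl[i] = d
                SR[i] += cum
            A.append(al)
            D.append(dl)
        return A, D, SL, SR

    def scan_insert(
        self,
        order: np.ndarray,
        r: np.ndarray,
        cand: int,
        n_em: int = 15,
    ) -> tuple[np.ndarray, list[tuple[float, float]]]:
        """Profile log10 likelihood of inserting marker ``cand`` at every
        position of ``order`` (0 = before the first marker, len(order) =
        after the last), re-estimating only the split interval's two
        sub-fractions against cached flanking messages.

        Returns (logliks, [(r_left, r_right)] per position); r_left is nan at
        position 0 and r_right nan at the end position.
        """
        order = np.asarray(order)
        L = len(order)
        blocks, const = self._active_blocks(np.append(order, cand))
        n_units = sum(b.n_trans_units for b in blocks)
        A, D, SL, SR = self._cached_messages(order, r, blocks)
        out = np.full(L + 1, -np.inf)
        subs: list[tuple[float, float]] = [(np.nan, np.nan)] * (L + 1)

        # Interior positions p = 1..L-1: between order[p-1] and order[p].
        if L >= 2:
            P = L - 1
            ra = np.full(P, 0.05)
            rb = np.full(P, 0.05)
            init = np.clip(r / 2.0, R_FLOOR, R_CEIL)
            ra[:] = init
            rb[:] = init
            # Per-block stacked messages (P, U, S).
            stacks = []
            for bi, b in enumerate(blocks):
                aL = np.stack([A[bi][p - 1] for p in range(1, L)])
                dR = np.stack([D[bi][p] for p in range(1, L)])
                eX = b.emis(cand)[None]  # (1, U, S)
                stacks.append((b, aL, dR, eX))
            for _ in range(n_em):
                fa = np.zeros(P)
                fb = np.zeros(P)
                for b, aL, dR, eX in stacks:
                    right = eX * b.apply_T(dR, rb)  # (P, U, S)
                    fa += b.exp_flips(aL, right, ra)
                    left = b.apply_T(aL, ra) * eX
                    fb += b.exp_flips(left, dR, rb)
                ra = np.clip(fa / n_units, R_FLOOR, R_CEIL)
                rb = np.clip(fb / n_units, R_FLOOR, R_CEIL)
            val = np.zeros(P)
            for b, aL, dR, eX in stacks:
                mid = b.apply_T(b.apply_T(aL, ra) * eX, rb)
                f = (mid * dR).sum(axis=-1)  # (P, U): per-unit segment value
                val += np.log10(np.maximum(f, 1e-300)).sum(axis=-1)
            for p in range(1, L):
                out[p] = SL[p - 1] + SR[p] + val[p - 1] + const
                subs[p] = (float(ra[p - 1]), float(rb[p - 1]))

        # End positions.
        for p, side in ((0, "left"), (L, "right")):
            rr = 0.05
            for _ in range(n_em):
                f = 0.0
                for bi, b in enumerate(blocks):
                    eX = b.emis(cand)
                    if side == "left":
                        f += b.exp_flips(eX, D[bi][0], rr)
                    else:
                        f += b.exp_flips(A[bi][L - 1], eX, rr)
                rr = float(np.clip(f / n_units, R_FLOOR, R_CEIL))
            val = 0.0
            for bi, b in enumerate(blocks):
                eX = b.emis(cand)
                if side == "left":
                    f = (b.apply_T(eX, rr) * D[bi][0]).sum(axis=-1)
                else:
                    f = (b.apply_T(A[bi][L - 1], rr) * eX).sum(axis=-1)
                val += float(np.log10(np.maximum(f, 1e-300)).sum())
            if side == "left":
                out[0] = val + SR[0] + const
                subs[0] = (np.nan, rr)
            else:
                out[L] = SL[L - 1] + val + const
                subs[L] = (rr, np.nan)
        return out, subs

    def merged_interval(
        self, order: np.ndarray, r: np.ndarray, pos: int, n_em: int = 20
    ) -> float:
        """Re-estimated recombination fraction of the interval obtained by
        deleting the marker at ``pos`` (interior positions only)."""
        order = np.asarray(order)
        L = len(order)
        if not 0 < pos < L - 1:
            raise InputError("merged_interval needs an interior position")
        new_order = np.delete(order, pos)
        blocks, _ = self._active_blocks(new_order)
        n_units = sum(b.n_trans_units for b in blocks)
        if n_units == 0:
            return np.nan
        A, D, _, _ = self._cached_messages(new_order, self._r_for(new_order, order, r), blocks)
        rr = float(np.clip(r[pos - 1] + r[pos], R_FLOOR, R_CEIL))
        for _ in range(n_em):
            f = 0.0
            for bi, b in enumerate(blocks):
                f += b.exp_flips(A[bi][pos - 1], D[bi][pos], rr)
            rr = float(np.clip(f / n_units, R_FLOOR, R_CEIL))
        return rr

    @staticmethod
    def _r_for(new_order: np.ndarray, order: np.ndarray, r: np.ndarray) -> np.ndarray:
        """Interval fractions for ``order`` with one marker deleted: the two
        intervals around the deleted marker are provisionally summed."""
        pos = int(np.flatnonzero(~np.isin(order, new_order))[0])
        rr = list(r)
        merged = min(rr[pos - 1] + rr[pos], R_CEIL) if 0 < pos < len(order) - 1 else None
        if pos == 0:
            del rr[0]
        elif pos == len(order) - 1:
            del rr[-1]
        else:
            rr[pos - 1 : pos + 1] = [merged]
        return np.asarray(rr)

    # -- window permutation (flips) scan ---------------------------------

    def scan_window_perms(
        self,
        order: np.ndarray,
        r: np.ndarray,
        start: int,
        width: int,
        perms: np.ndarray,
        n_em: int = 8,
        chunk: int = 180,
    ) -> np.ndarray:
        """Segment log10 likelihood for each permutation of the window
        ``order[start:start+width]``; interval fractions inside the window
        (plus the two flanking intervals) are re-estimated per permutation,
        everything outside is fixed. Values are comparable across
        permutations (the identity permutation included) — common boundary
        terms are included.
        """
        order = np.asarray(order)
        L = len(order)
        width = min(width, L)
        has_left = start > 0
        has_right = start + width < L
        blocks, const = self._active_blocks(order)
        n_units = sum(b.n_trans_units for b in blocks)
        if n_units == 0:
            return np.zeros(len(perms))
        A, D, SL, SR = self._cached_messages(order, r, blocks)
        window = order[start : start + width]
        out = np.empty(len(perms))
        base = const
        if has_left:
            base += SL[start - 1]
        if has_right:
            base += SR[start + width]
        for c0 in range(0, len(perms), chunk):
            pm = perms[c0 : c0 + chunk]  # (P, width) window-relative
            P = len(pm)
            seq = window[pm]  # (P, width) marker universe indices
            n_int = width - 1 + int(has_left) + int(has_right)
            q = np.full((P, n_int), 0.02)
            emis_cache = [
                [b.emis_batch(seq[:, j]) for j in range(width)] for b in blocks
            ]

            def segment_pass(q, want_flips):
                flips = np.zeros((P, n_int)) if want_flips else None
                val = np.zeros(P)
                for bi, b in enumerate(blocks):
                    e_all = emis_cache[bi]
                    if has_left:
                        aL0 = np.broadcast_to(
                            A[bi][start - 1], (P,) + A[bi][start - 1].shape
                        )
                        alpha = aL0
                    else:
                        alpha = None
                    cum = np.zeros(P)
                    qi = 0
                    pos_alphas = []
                    for j in range(width):
                        e = e_all[j]
                        if alpha is None:
                            alpha = e
                        else:
                            alpha = b.apply_T(alpha, q[:, qi]) * e
                            qi += 1
                        alpha, clog = _normalize(alpha)
                        cum += clog.sum(axis=-1)
                        pos_alphas.append(alpha)
                    if has_right:
                        dR = np.broadcast_to(
                            D[bi][start + width], (P,) + D[bi][start + width].shape
                        )
                        fin = (b.apply_T(alpha, q[:, qi]) * dR).sum(axis=-1)  # (P, U)
                        cum += np.log10(np.maximum(fin, 1e-300)).sum(axis=-1)
                    val += cum
                    if not want_flips:
                        continue
                    # backward within segment
                    pos_ds = [None] * width
                    if has_right:
                        d = e_all[width - 1] * b.apply_T(dR, q[:, n_int - 1])
                    else:
                        d = e_all[width - 1]
                    d, _ = _normalize(d)
                    pos_ds[width - 1] = d
                    qi_b = n_int - 1 - int(has_right)
                    for j in range(width - 2, -1, -1):
                        d = e_all[j] * b.apply_T(d, q[:, qi_b])
                        d, _ = _normalize(d)
                        pos_ds[j] = d
                        qi_b -= 1
                    qi = 0
                    if has_left:
                        flips[:, 0] += b.exp_flips(aL0, pos_ds[0], q[:, 0])
                        qi = 1
                    for j in range(width - 1):
                        flips[:, qi] += b.exp_flips(pos_alphas[j], pos_ds[j + 1], q[:, qi])
                        qi += 1
                    if has_right:
                        flips[:, qi] += b.exp_flips(pos_alphas[width - 1], dR, q[:, qi])
                return val, flips

            for _ in range(n_em):
                _, flips = segment_pass(q, want_flips=True)
                q = np.clip(flips / n_units, R_FLOOR, R_CEIL)
            val, _ = segment_pass(q, want_flips=False)
            out[c0 : c0 + P] = val + base
        return out


def order_preserving_perms(width: int, fixed: np.ndarray) -> np.ndarray:
    """All permutations of range(width) that keep the positions flagged in
    ``fixed`` in their original relative order."""
    fixed_idx = [i for i in range(width) if fixed[i]]
    perms = []
    for p in itertools.permutations(range(width)):
        sub = [x for x in p if x in fixed_idx]
        if sub == fixed_idx:
            perms.append(p)
    return np.array(perms, dtype=np.int64)
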