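"""Synthetic pedigrees and SNP genotypes under a known recombination landscape.

The generator emulates multigenerational cat-style mapping pedigrees genotyped
on a dense (~50 kb spaced) biallelic SNP array: sex-specific recombination with
a female:male autosomal map-length ratio near 1.7, telomere-elevated rates,
recombination deserts, a hemizygous-X male model with a pseudoautosomal region
(PAR), and configurable genotype missingness and error. Truth files (true
marker order and cumulative cM per sex, crossover positions per meiosis) make
every downstream stage testable by parameter recovery.

Crossovers are simulated as a Poisson process on the genetic scale (no
interference, i.e. the Haldane model): the number of crossovers on a region of
genetic length L Morgans is Poisson(L) and positions are drawn uniformly in cM
and mapped back to bp through the landscape's cumulative map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FEMALE, MALE, ConfigError, GenotypeMatrix, InputError, Pedigree
from .io import write_map, write_ped

__all__ = [
    "TrueLandscape",
    "SimConfig",
    "make_landscape",
    "simulate_pedigree",
    "simulate_gamete",
    "simulate_genotypes",
    "SimResult",
]


@dataclass
class TrueLandscape:
    """Sex-specific cumulative genetic map of one chromosome.

    The map is a piecewise-linear table of (bp, female cM, male cM) knots.
    On X, the male column accumulates cM only inside the PAR; desert intervals
    accumulate no cM for either sex.
    """

    chrom: str
    length_bp: int
    knots_bp: np.ndarray
    female_cm: np.ndarray
    male_cm: np.ndarray
    par_bp: tuple[int, int] | None = None
    deserts_bp: list[tuple[int, int]] = field(default_factory=list)
    is_x: bool = False

    def __post_init__(self) -> None:
        self.knots_bp = np.asarray(self.knots_bp, dtype=float)
        self.female_cm = np.asarray(self.female_cm, dtype=float)
        self.male_cm = np.asarray(self.male_cm, dtype=float)
        if not (len(self.knots_bp) == len(self.female_cm) == len(self.male_cm)):
            raise ConfigError("landscape knot columns must have equal length")
        if np.any(np.diff(self.knots_bp) <= 0):
            raise ConfigError("landscape bp knots must be strictly increasing")
        for name, cum in (("female", self.female_cm), ("male", self.male_cm)):
            if np.any(np.diff(cum) < -1e-12):
                raise ConfigError(f"{name} cumulative cM must be non-decreasing")
        if self.is_x:
            inc = np.diff(self.male_cm)
            mid = 0.5 * (self.knots_bp[:-1] + self.knots_bp[1:])
            outside = self._outside_par(mid)
            if np.any(inc[outside] > 1e-12):
                raise ConfigError("male cM must be flat outside the PAR on X")
        for lo, hi in self.deserts_bp:
            for sex in (FEMALE, MALE):
                if self.cm_at(hi, sex) - self.cm_at(lo, sex) > 1e-9:
                    raise ConfigError(f"desert [{lo}, {hi}] accumulates cM")

    def _outside_par(self, bp: np.ndarray) -> np.ndarray:
        if self.par_bp is None:
            return np.ones(len(bp), dtype=bool)
        return ~((bp >= self.par_bp[0]) & (bp <= self.par_bp[1]))

    def _column(self, sex: int) -> np.ndarray:
        return self.female_cm if sex == FEMALE else self.male_cm

    def total_cm(self, sex: int) -> float:
        return float(self._column(sex)[-1] - self._column(sex)[0])

    def cm_at(self, bp, sex: int):
        """Cumulative genetic position (cM) at physical position(s)."""
        return np.interp(bp, self.knots_bp, self._column(sex))

    def bp_at(self, cm, sex: int):
        """Physical position(s) for cumulative cM; plateaus map to their start."""
        cum = self._column(sex)
        cm = np.atleast_1d(np.asarray(cm, dtype=float))
        hi = np.clip(np.searchsorted(cum, cm, side="right"), 1, len(cum) - 1)
        lo = hi - 1
        denom = cum[hi] - cum[lo]
        frac = np.where(denom > 0, (cm - cum[lo]) / np.where(denom > 0, denom, 1.0), 0.0)
        return self.knots_bp[lo] + frac * (self.knots_bp[hi] - self.knots_bp[lo])


def make_landscape(
    chrom: str,
    length_bp: int,
    female_cm: float,
    male_cm: float,
    *,
    telomere_factor: float = 2.0,
    telomere_frac: float = 0.1,
    deserts_bp: list[tuple[int, int]] | None = None,
    par_bp: tuple[int, int] | None = None,
    is_x: bool = False,
    n_segments: int = 100,
) -> TrueLandscape:
    """Build a piecewise-linear landscape from summary features.

    The base rate is uniform, multiplied by ``telomere_factor`` within
    ``telomere_frac`` of either chromosome end, zeroed inside deserts, and (for
    X) zeroed for males outside the PAR; each sex column is then scaled so its
    total equals the requested map length.
    """
    deserts_bp = list(deserts_bp or [])
    edges = np.linspace(0.0, float(length_bp), n_segments + 1)
    # Refine edges so desert/PAR/telomere boundaries fall on knots exactly.
    extra = [length_bp * telomere_frac, length_bp * (1 - telomere_frac)]
    for lo, hi in deserts_bp:
        extra += [lo, hi]
    if par_bp is not None:
        extra += list(par_bp)
    edges = np.unique(np.concatenate([edges, np.array(extra, dtype=float)]))
    edges = edges[(edges >= 0) & (edges <= length_bp)]
    mid = 0.5 * (edges[:-1] + edges[1:])
    seg = np.diff(edges)

    weight = np.ones(len(mid))
    near_end = (mid < length_bp * telomere_frac) | (mid > length_bp * (1 - telomere_frac))
    weight[near_end] *= telomere_factor
    for lo, hi in deserts_bp:
        weight[(mid > lo) & (mid < hi)] = 0.0

    def column(total: float, male: bool) -> np.ndarray:
        w = weight.copy()
        if is_x and male:
            if par_bp is None:
                w[:] = 0.0
            else:
                w[(mid < par_bp[0]) | (mid > par_bp[1])] = 0.0
        raw = w * seg
        s = raw.sum()
        inc = raw * (total / s) if s > 0 else raw * 0.0
        return np.concatenate([[0.0], np.cumsum(inc)])

    return TrueLandscape(
        chrom=chrom,
        length_bp=length_bp,
        knots_bp=edges,
        female_cm=column(female_cm, male=False),
        male_cm=column(male_cm, male=True),
        par_bp=par_bp,
        deserts_bp=deserts_bp,
        is_x=is_x,
    )


@dataclass
class SimConfig:
    """Study design for the generator.

    ``founder_freq`` is the uniform range the per-marker B-allele frequency is
    drawn from; ``offspring_dist`` is "poisson" or "fixed" (exactly
    ``mean_offspring`` per mating). ``interference`` admits only "none"
    (Haldane crossover process).
    """

    n_founders: int = 8
    generations: int = 5
    mean_offspring: float = 4.0
    offspring_dist: str = "poisson"
    founder_freq: tuple[float, float] = (0.3, 0.7)  # array SNPs are ascertained common
    marker_spacing_bp: int = 50_000
    missing_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0
    interference: str = "none"

    def __post_init__(self) -> None:
        if self.generations < 2:
            raise ConfigError("generations must be >= 2")
        if self.n_founders < 2:
            raise ConfigError("need at least 2 founders")
        for name in ("missing_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.founder_freq[0] <= self.founder_freq[1] < 1.0:
            raise ConfigError("founder_freq range must lie strictly inside (0, 1)")
        if self.offspring_dist not in ("poisson", "fixed"):
            raise ConfigError("offspring_dist must be 'poisson' or 'fixed'")
        if self.interference != "none":
            raise ConfigError("only the no-interference (Haldane) crossover model is supported")


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Simulate a multigenerational pedigree.

    Founders (generation 0) alternate male/female. Each later generation is
    produced by mating every female of the previous generation to a male of
    that generation (males may serve several females, as in breeding
    colonies); each mating produces Poisson(``mean_offspring``) offspring (or
    exactly that number when ``offspring_dist`` is "fixed"). Offspring sexes
    alternate within each generation, keeping the colony sex-balanced so the
    realised number of meioses tracks the configured design instead of
    drifting with sex-ratio noise. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[tuple[str, str, str, str, int]] = []
    prev: list[tuple[str, int]] = []
    for k in range(config.n_founders):
        sex = MALE if k % 2 == 0 else FEMALE
        rows.append(("FAM1", f"G0I{k + 1}", "0", "0", sex))
        prev.append((f"G0I{k + 1}", sex))

    for g in range(1, config.generations):
        males = [i for i, s in prev if s == MALE]
        females = [i for i, s in prev if s == FEMALE]
        if not males or not females:
            raise ConfigError(f"generation {g - 1} has no opposite-sex pairs to mate")
        rng.shuffle(males)
        rng.shuffle(females)
        couples = [(males[i % len(males)], f) for i, f in enumerate(females)]
        counts = (
            rng.poisson(config.mean_offspring, size=len(couples))
            if config.offspring_dist == "poisson"
            else np.full(len(couples), int(round(config.mean_offspring)))
        )
        if counts.sum() == 0:
            counts[0] = 1
        cur: list[tuple[str, int]] = []
        k = 0
        for (sire, dam), n_off in zip(couples, counts):
            for _ in range(int(n_off)):
                k += 1
                sex = MALE if k % 2 == 0 else FEMALE
                name = f"G{g}I{k}"
                rows.append(("FAM1", name, sire, dam, sex))
                cur.append((name, sex))
        if g < config.generations - 1 and len(cur) >= 2:
            sexes = {s for _, s in cur}
            if len(sexes) == 1:
                name, s = cur[-1]
                flipped = FEMALE if s == MALE else MALE
                cur[-1] = (name, flipped)
                rows[-1] = rows[-1][:4] + (flipped,)
        prev = cur
    table = pd.DataFrame(rows, columns=["family", "id", "sire", "dam", "sex"])
    return Pedigree(table)


def simulate_gamete(
    haplotypes: np.ndarray,
    marker_bp: np.ndarray,
    landscape: TrueLandscape,
    sex: int,
    rng: np.random.Generator,
    *,
    end_state: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one gamete from a phased parent.

    ``haplotypes`` is (2, n_markers); ``sex`` selects the parent's cM column.
    The crossover count over genetic length L Morgans is Poisson(L); crossover
    bp positions are drawn by inverting the cumulative map. ``end_state``
    forces the transmitted homolog at the chromosome end (used for the male X,
    where the non-PAR tail must come from a fixed homolog); otherwise the
    starting homolog is uniform.

    Returns (gamete haplotype, crossover bp positions).
    """
    if haplotypes.shape != (2, len(marker_bp)):
        raise InputError("haplotypes must be (2, n_markers) over the landscape marker grid")
    if np.any(marker_bp > landscape.length_bp) or np.any(marker_bp < 0):
        raise InputError("marker positions fall outside the landscape chromosome")
    total = landscape.total_cm(sex)
    n_xo = rng.poisson(total / 100.0)
    xo_cm = np.sort(rng.uniform(0.0, total, size=n_xo))
    xo_bp = landscape.bp_at(xo_cm, sex) if n_xo else np.empty(0)
    if end_state is None:
        start = int(rng.integers(2))
    else:
        start = int(end_state) ^ (n_xo & 1)
    homolog = (start + np.searchsorted(xo_bp, marker_bp, side="left")) % 2
    return haplotypes[homolog, np.arange(len(marker_bp))], xo_bp


def _marker_grid(landscape: TrueLandscape, spacing: int) -> np.ndarray:
    bp = np.arange(1, landscape.length_bp + 1, spacing, dtype=np.int64)
    return bp


@dataclass
class SimResult:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    truth_markers: pd.DataFrame  # marker, chrom, bp, female_cm, male_cm
    crossovers: pd.DataFrame  # parent, offspring, chrom, bp
    founder_haplotypes: dict[str, dict[str, np.ndarray]]

    def write(self, outdir: str | Path, prefix: str = "sim") -> None:
        """Write PED/MAP plus truth files (TSV) to a directory.

        Truth files carry the true marker order and cumulative cM per sex,
        every crossover position per meiosis, and the founders' phased
        haplotypes (never exposed to downstream modules)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ped(self.pedigree, self.genotypes, outdir / f"{prefix}.ped")
        write_map(self.genotypes.markers, outdir / f"{prefix}.map")
        self.truth_markers.to_csv(outdir / f"{prefix}.truth_markers.tsv", sep="\t", index=False)
        self.crossovers.to_csv(outdir / f"{prefix}.truth_crossovers.tsv", sep="\t", index=False)
        rows = []
        for ind in sorted(self.founder_haplotypes):
            for chrom, h in sorted(self.founder_haplotypes[ind].items()):
                for k in (0, 1):
                    rows.append((ind, chrom, k, "".join(map(str, h[k]))))
        pd.DataFrame(rows, columns=["individual", "chrom", "homolog", "alleles"]).to_csv(
            outdir / f"{prefix}.truth_founder_haplotypes.tsv", sep="\t", index=False
        )


def simulate_genotypes(
    pedigree: Pedigree,
    landscapes: list[TrueLandscape] | TrueLandscape,
    config: SimConfig,
) -> SimResult:
    """Drop genotypes through a pedigree under the true landscape(s).

    Founder haplotypes are iid Bernoulli draws from per-marker allele
    frequencies; gametes follow :func:`simulate_gamete`. Males carry a single
    X haplotype outside the PAR, duplicated into a homozygous diploid call;
    inside the PAR they are diploid (X-PAR plus Y-PAR) and male meiosis
    recombines there. Genotype error is symmetric random replacement; missing
    calls are set independently at ``missing_rate``.
    """
    if isinstance(landscapes, TrueLandscape):
        landscapes = [landscapes]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9151]))
    order = pedigree.topological_order()
    sex = {i: pedigree.sex_of(i) for i in order}

    marker_frames = []
    hap: dict[str, dict[str, np.ndarray]] = {i: {} for i in order}  # id -> chrom -> (2, m)
    xo_rows: list[tuple[str, str, str, float]] = []
    founder_haps: dict[str, dict[str, np.ndarray]] = {}

    for ls in landscapes:
        bp = _marker_grid(ls, config.marker_spacing_bp)
        m = len(bp)
        freq = rng.uniform(config.founder_freq[0], config.founder_freq[1], size=m)
        marker_frames.append(
            pd.DataFrame(
                {
                    "marker": [f"{ls.chrom}_M{k + 1}" for k in range(m)],
                    "chrom": ls.chrom,
                    "bp": bp,
                    "female_cm": ls.cm_at(bp, FEMALE),
                    "male_cm": ls.cm_at(bp, MALE),
                }
            )
        )
        outside_par = np.ones(m, dtype=bool)
        if ls.is_x and ls.par_bp is not None:
            outside_par = ~((bp >= ls.par_bp[0]) & (bp <= ls.par_bp[1]))

        for ind in order:
            sire, dam = pedigree.parents_of(ind)
            if sire is None or dam is None:
                h = (rng.random((2, m)) < freq).astype(np.int8)
                if ls.is_x and sex[ind] == MALE:
                    # Single X (row 0); row 1 is Y: real only inside PAR,
                    # mirrored from the X outside it for diploid coding.
                    h[1, outside_par] = h[0, outside_par]
                hap[ind][ls.chrom] = h
                founder_haps.setdefault(ind, {})[ls.chrom] = h.copy()
                continue

            if ls.is_x:
                if sex[ind] == MALE:
                    mat, xo_m = simulate_gamete(hap[dam][ls.chrom], bp, ls, FEMALE, rng)
                    pat, xo_p = simulate_gamete(
                        hap[sire][ls.chrom], bp, ls, MALE, rng, end_state=1
                    )  # Y gamete: non-PAR tail is the sire's row-1 (Y) homolog
                    h = np.vstack([mat, pat])
                    h[1, outside_par] = h[0, outside_par]
                else:
                    mat, xo_m = simulate_gamete(hap[dam][ls.chrom], bp, ls, FEMALE, rng)
                    pat, xo_p = simulate_gamete(
                        hap[sire][ls.chrom], bp, ls, MALE, rng, end_state=0
                    )  # X gamete: non-PAR tail is the sire's single X (row 0)
                    h = np.vstack([mat, pat])
            else:
                mat, xo_m = simulate_gamete(hap[dam][ls.chrom], bp, ls, FEMALE, rng)
                pat, xo_p = simulate_gamete(hap[sire][ls.chrom], bp, ls, MALE, rng)
                h = np.vstack([mat, pat])
            hap[ind][ls.chrom] = h
            for x in xo_m:
                xo_rows.append((dam, ind, ls.chrom, float(x)))
            for x in xo_p:
                xo_rows.append((sire, ind, ls.chrom, float(x)))

    markers = pd.concat(marker_frames, ignore_index=True)
    geno = np.empty((len(order), len(markers)), dtype=np.int8)
    col0 = 0
    for ls, mf in zip(landscapes, marker_frames):
        m = len(mf)
        for r, ind in enumerate(order):
            h = hap[ind][ls.chrom]
            geno[r, col0 : col0 + m] = h[0] + h[1]
        col0 += m

    if config.error_rate > 0:
        err = rng.random(geno.shape) < config.error_rate
        geno[err] = rng.integers(0, 3, size=int(err.sum()), dtype=np.int8)
    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = -1

    # Re-order pedigree rows to the topological order used for the matrix.
    table = pedigree.table.set_index("id").loc[order].reset_index()
    table = table[["family", "id", "sire", "dam", "sex"]]
    ped = Pedigree(table)
    gm = GenotypeMatrix(
        individuals=order,
        markers=markers[["marker", "chrom", "bp"]].copy(),
        geno=geno,
        sex=np.array([sex[i] for i in order], dtype=np.int8),
    )
    xo = pd.DataFrame(xo_rows, columns=["parent", "offspring", "chrom", "bp"])
    return SimResult(
        pedigree=ped,
        genotypes=gm,
        truth_markers=markers,
        crossovers=xo,
        founder_haplotypes=founder_haps,
    )
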