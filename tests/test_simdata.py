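"""Generator checks: pedigree structure, crossover process, genotype rules."""

import numpy as np
import pytest

from felmap.core import FEMALE, MALE, ConfigError
from felmap.simdata import (
    SimConfig,
    TrueLandscape,
    make_landscape,
    simulate_gamete,
    simulate_genotypes,
    simulate_pedigree,
)

from conftest import FEMALE_CM, MALE_CM, small_landscape


def test_two_generation_counts():
    cfg = SimConfig(n_founders=2, generations=2, mean_offspring=4, offspring_dist="fixed", seed=0)
    ped = simulate_pedigree(cfg)
    assert len(ped) == 6
    assert len(ped.meioses()) == 8  # 4 maternal + 4 paternal


def test_five_generation_pedigree_depth():
    cfg = SimConfig(n_founders=10, generations=5, mean_offspring=3.6, seed=1)
    ped = simulate_pedigree(cfg)
    gens = {i.split("I")[0] for i in ped.ids}
    assert gens == {f"G{k}" for k in range(5)}
    # every non-founder has genotype-bearing sire and dam
    t = ped.table
    nonf = t[t["sire"] != "0"]
    assert (nonf["dam"] != "0").all()
    ids = set(t["id"])
    assert set(nonf["sire"]) <= ids and set(nonf["dam"]) <= ids


def test_pedigree_deterministic_and_files_identical(tmp_path):
    ls = small_landscape(10)
    outs = []
    for sub in ("a", "b"):
        cfg = SimConfig(n_founders=6, generations=3, mean_offspring=3, seed=7)
        sim = simulate_genotypes(simulate_pedigree(cfg), ls, cfg)
        d = tmp_path / sub
        sim.write(d)
        outs.append({p.name: p.read_bytes() for p in sorted(d.iterdir())})
    assert outs[0] == outs[1]


def test_config_validation():
    with pytest.raises(ConfigError):
        SimConfig(generations=1)
    with pytest.raises(ConfigError):
        SimConfig(n_founders=1)
    with pytest.raises(ConfigError):
        SimConfig(missing_rate=1.5)
    with pytest.raises(ConfigError):
        SimConfig(founder_freq=(0.0, 0.5))
    with pytest.raises(ConfigError):
        SimConfig(interference="gamma")


def test_landscape_invariants():
    ls = make_landscape(
        "X", 100_000_000, 100.0, 8.0, par_bp=(1, 6_000_000),
        deserts_bp=[(40_000_000, 60_000_000)], is_x=True,
    )
    assert np.all(np.diff(ls.female_cm) >= -1e-12)
    # male increment outside PAR is exactly zero
    mid = 0.5 * (ls.knots_bp[:-1] + ls.knots_bp[1:])
    outside = (mid < 1) | (mid > 6_000_000)
    assert np.all(np.diff(ls.male_cm)[outside] <= 1e-12)
    # desert accumulates nothing for either sex
    for sex in (FEMALE, MALE):
        assert ls.cm_at(60_000_000, sex) - ls.cm_at(40_000_000, sex) < 1e-9


def test_landscape_rejects_nonmonotone():
    with pytest.raises(ConfigError):
        TrueLandscape(
            chrom="A1", length_bp=100, knots_bp=[0, 50, 100],
            female_cm=[0, 2, 1], male_cm=[0, 1, 2],
        )


def test_desert_never_recombines():
    desert = (30_000_000, 50_000_000)
    ls = make_landscape("A1", 100_000_000, 120.0, 70.0, deserts_bp=[desert])
    rng = np.random.default_rng(0)
    bp_grid = np.arange(1, ls.length_bp, 500_000)
    haps = np.zeros((2, len(bp_grid)), dtype=np.int8)
    for _ in range(2000):
        _, xo = simulate_gamete(haps, bp_grid, ls, FEMALE, rng)
        assert not np.any((xo > desert[0]) & (xo < desert[1]))


def test_poisson_crossover_mean():
    # 1-Morgan chromosome: mean crossovers per gamete = 1.0 +- 3 SE
    ls = make_landscape("A1", 50_000_000, 100.0, 100.0, telomere_factor=1.0)
    rng = np.random.default_rng(1)
    bp_grid = np.arange(1, ls.length_bp, 500_000)
    haps = np.zeros((2, len(bp_grid)), dtype=np.int8)
    n = 10_000
    total = sum(len(simulate_gamete(haps, bp_grid, ls, MALE, rng)[1]) for _ in range(n))
    assert abs(total / n - 1.0) < 3 * np.sqrt(1.0 / n)


def test_haldane_recombinant_fraction_10cm():
    # two markers 10 cM apart: observed recombinant fraction ~ (1-e^-0.2)/2
    ls = make_landscape("A1", 10_000_000, 10.0, 10.0, telomere_factor=1.0)
    rng = np.random.default_rng(2)
    bp_grid = np.array([1, 9_999_999])
    haps = np.vstack([np.zeros(2, dtype=np.int8), np.ones(2, dtype=np.int8)])
    n = 10_000
    rec = 0
    for _ in range(n):
        g, _ = simulate_gamete(haps, bp_grid, ls, FEMALE, rng)
        rec += g[0] != g[1]
    expect = (1 - np.exp(-0.2)) / 2
    se = np.sqrt(expect * (1 - expect) / n)
    assert abs(rec / n - expect) < 3 * se


def test_clean_genotypes_are_mendelian_and_complete(small_sim):
    from felmap.qc import mendelian_check

    gm = small_sim.genotypes
    assert np.all(gm.geno != -1)
    viol = mendelian_check(gm, small_sim.pedigree)
    assert viol.empty


def test_missing_rate_calibration():
    ls = small_landscape(50)
    cfg = SimConfig(
        n_founders=8, generations=3, mean_offspring=4, marker_spacing_bp=50_000,
        missing_rate=0.05, seed=9,
    )
    sim = simulate_genotypes(simulate_pedigree(cfg), ls, cfg)
    frac = (sim.genotypes.geno == -1).mean()
    n = sim.genotypes.geno.size
    assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)


def test_male_x_never_het_outside_par():
    par = (1, 6_000_000)
    ls = make_landscape("X", 60_000_000, 80.0, 5.0, par_bp=par, is_x=True)
    cfg = SimConfig(n_founders=8, generations=4, mean_offspring=3.5, marker_spacing_bp=500_000, seed=5)
    ped = simulate_pedigree(cfg)
    sim = simulate_genotypes(ped, ls, cfg)
    gm = sim.genotypes
    outside = (gm.markers["bp"].to_numpy() < par[0]) | (gm.markers["bp"].to_numpy() > par[1])
    males = gm.sex == MALE
    assert not np.any(gm.geno[np.ix_(males, outside)] == 1)


def test_realized_sex_ratio_matches_design():
    ls = small_landscape(100)
    cfg = SimConfig(n_founders=14, generations=5, mean_offspring=4.0, marker_spacing_bp=50_000, seed=3)
    ped = simulate_pedigree(cfg)
    sim = simulate_genotypes(ped, ls, cfg)
    sex = dict(zip(ped.table["id"], ped.table["sex"]))
    xo = sim.crossovers
    by_sex = xo["parent"].map(sex).value_counts()
    n_off = (ped.table["sire"] != "0").sum()
    f_len = 100 * by_sex.get(FEMALE, 0) / n_off
    m_len = 100 * by_sex.get(MALE, 0) / n_off
    # Monte-Carlo tolerance: ~3 SE on each Poisson total at this size
    assert abs(f_len / m_len - FEMALE_CM / MALE_CM) < 0.35
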