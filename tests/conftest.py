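import numpy as np
import pandas as pd
import pytest

from felmap.core import GenotypeMatrix, Pedigree
from felmap.linkage import MeiosisVectors, infer_meiosis_vectors
from felmap.qc import run_qc
from felmap.simdata import SimConfig, make_landscape, simulate_genotypes, simulate_pedigree

SEX_RATIO = 1.7
AVG_CM = 100.0
FEMALE_CM = 2 * AVG_CM * SEX_RATIO / (1 + SEX_RATIO)
MALE_CM = 2 * AVG_CM / (1 + SEX_RATIO)


def small_landscape(n_markers=40, spacing=50_000):
    return make_landscape("A1", n_markers * spacing, FEMALE_CM, MALE_CM)


@pytest.fixture(scope="session")
def small_sim():
    """A modest autosome simulation shared across tests: 40 markers,
    ~150 meioses, clean genotypes."""
    ls = small_landscape()
    cfg = SimConfig(
        n_founders=8, generations=4, mean_offspring=3.5, marker_spacing_bp=50_000, seed=42
    )
    ped = simulate_pedigree(cfg)
    sim = simulate_genotypes(ped, ls, cfg)
    return sim


@pytest.fixture(scope="session")
def small_qc(small_sim):
    gm, report = run_qc(small_sim.genotypes, small_sim.pedigree, min_im=1)
    return gm, report


@pytest.fixture(scope="session")
def small_mv(small_sim, small_qc):
    gm, _ = small_qc
    return infer_meiosis_vectors(gm, small_sim.pedigree)


def trio_matrix(sire, dam, off, n_markers=None, chrom="A1", sex=(1, 2, 1)):
    """Build a 3-individual matrix from genotype code lists (-1,0,1,2)."""
    sire = np.asarray(sire, dtype=np.int8)
    n_markers = n_markers or len(sire)
    markers = pd.DataFrame(
        {
            "marker": [f"M{i + 1}" for i in range(n_markers)],
            "chrom": chrom,
            "bp": np.arange(n_markers) * 50_000 + 1,
        }
    )
    geno = np.vstack([sire, np.asarray(dam, dtype=np.int8), np.asarray(off, dtype=np.int8)])
    gm = GenotypeMatrix(
        individuals=["SIRE", "DAM", "KID"], markers=markers, geno=geno, sex=np.array(sex, dtype=np.int8)
    )
    ped = Pedigree(
        pd.DataFrame(
            {
                "family": "F",
                "id": ["SIRE", "DAM", "KID"],
                "sire": ["0", "0", "SIRE"],
                "dam": ["0", "0", "DAM"],
                "sex": list(sex),
            }
        )
    )
    return gm, ped


def symbol_mv(sym, phase_known=None, parent_index=None, parent_sex=None, bp=None):
    """MeiosisVectors straight from a symbol matrix (for engine-level tests)."""
    sym = np.asarray(sym, dtype=np.int8)
    n, m = sym.shape
    if phase_known is None:
        phase_known = np.ones((n, m), dtype=bool)
    if parent_index is None:
        parent_index = np.arange(n)
    if parent_sex is None:
        parent_sex = [1 + (i % 2) for i in range(n)]
    markers = pd.DataFrame(
        {
            "marker": [f"m{i}" for i in range(m)],
            "chrom": "1",
            "bp": (np.arange(m) * 1000 + 1) if bp is None else np.asarray(bp),
        }
    )
    mei = pd.DataFrame(
        {
            "parent": [f"P{parent_index[i]}" for i in range(n)],
            "offspring": [f"O{i}" for i in range(n)],
            "parent_sex": parent_sex,
        }
    )
    return MeiosisVectors(
        meioses=mei,
        markers=markers,
        sym=sym,
        phase_known=np.asarray(phase_known, dtype=bool),
        parent_index=np.asarray(parent_index),
    )


def chain_mv(r_intervals, n_meioses, keep=1.0, seed=0, parent_sex=None):
    """Simulate phase-known two-state chains at given interval fractions."""
    rng = np.random.default_rng(seed)
    m = len(r_intervals) + 1
    state = rng.integers(0, 2, n_meioses)
    sym = np.zeros((n_meioses, m), dtype=np.int8)
    sym[:, 0] = state
    for i, r in enumerate(r_intervals):
        state = state ^ (rng.random(n_meioses) < r)
        sym[:, i + 1] = state
    if keep < 1.0:
        sym[rng.random((n_meioses, m)) > keep] = -1
    return symbol_mv(sym, parent_sex=parent_sex)
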