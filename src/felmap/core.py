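"""Core containers: pedigree and genotype matrix.

Genotypes are stored as B-allele dosage: 0 (AA), 1 (AB), 2 (BB), and -1 for
missing. Sex coding follows PLINK: 1 = male, 2 = female.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
MALE = 1
FEMALE = 2

PED_COLUMNS = ["family", "id", "sire", "dam", "sex", "phenotype"]


class FelmapError(Exception):
    """Base class for felmap errors."""


class InputError(FelmapError):
    """Inconsistent or malformed input data."""


class ConfigError(FelmapError):
    """Invalid configuration."""


@dataclass
class Pedigree:
    """Directed acyclic pedigree.

    ``table`` has columns family, id, sire, dam, sex; founders carry sire and
    dam "0". A *meiosis* is one parent->offspring transmission; every
    non-founder contributes one maternal and one paternal meiosis.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ("family", "id", "sire", "dam", "sex") if c not in t.columns]
        if missing:
            raise InputError(f"pedigree table missing columns: {missing}")
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].iloc[0]
            raise InputError(f"duplicate individual id in pedigree: {dup!r}")
        ids = set(t["id"])
        for col in ("sire", "dam"):
            bad = set(t[col]) - ids - {"0"}
            if bad:
                raise InputError(f"unknown {col} ids in pedigree: {sorted(bad)[:5]}")
        self._index = {i: k for k, i in enumerate(t["id"])}

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def index_of(self, individual: str) -> int:
        return self._index[individual]

    def sex_of(self, individual: str) -> int:
        return int(self.table["sex"].iloc[self._index[individual]])

    def is_founder(self, individual: str) -> bool:
        row = self.table.iloc[self._index[individual]]
        return row["sire"] == "0" and row["dam"] == "0"

    @property
    def founders(self) -> list[str]:
        t = self.table
        return list(t.loc[(t["sire"] == "0") & (t["dam"] == "0"), "id"])

    def parents_of(self, individual: str) -> tuple[str | None, str | None]:
        row = self.table.iloc[self._index[individual]]
        sire = None if row["sire"] == "0" else row["sire"]
        dam = None if row["dam"] == "0" else row["dam"]
        return sire, dam

    def meioses(self) -> pd.DataFrame:
        """All parent->offspring transmissions with genotype-bearing parents.

        Returns a frame with columns parent, offspring, parent_sex.
        """
        rows = []
        for _, row in self.table.iterrows():
            if row["sire"] != "0":
                rows.append((row["sire"], row["id"], MALE))
            if row["dam"] != "0":
                rows.append((row["dam"], row["id"], FEMALE))
        return pd.DataFrame(rows, columns=["parent", "offspring", "parent_sex"])

    def topological_order(self) -> list[str]:
        """Individual ids ordered so parents precede offspring."""
        seen: dict[str, int] = {}
        order: list[str] = []

        def depth(i: str) -> int:
            if i in seen:
                return seen[i]
            sire, dam = self.parents_of(i)
            d = 0
            for p in (sire, dam):
                if p is not None:
                    d = max(d, depth(p) + 1)
            seen[i] = d
            order.append(i)
            return d

        for i in self.table["id"]:
            depth(i)
        order.sort(key=lambda i: (seen[i], self._index[i]))
        return order


@dataclass
class GenotypeMatrix:
    """Individuals x markers biallelic genotype calls.

    ``markers`` has columns marker, chrom, bp (1-based physical position);
    ``geno`` is an int8 array of B-allele dosages with -1 for missing, in the
    same row order as ``individuals`` and column order as ``markers``.
    """

    individuals: list[str]
    markers: pd.DataFrame
    geno: np.ndarray
    sex: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.individuals), len(self.markers)):
            raise InputError(
                f"genotype array shape {self.geno.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        if self.sex is None:
            self.sex = np.zeros(len(self.individuals), dtype=np.int8)
        self._row = {i: k for k, i in enumerate(self.individuals)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def row_of(self, individual: str) -> int:
        return self._row[individual]

    def marker_call_rate(self) -> np.ndarray:
        if self.n_individuals == 0:
            raise InputError("empty genotype matrix")
        return (self.geno != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        if self.n_markers == 0:
            raise InputError("empty genotype matrix")
        return (self.geno != MISSING).mean(axis=1)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            markers=self.markers.iloc[keep].reset_index(drop=True),
            geno=self.geno[:, keep],
            sex=self.sex,
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individuals=[self.individuals[k] for k in keep],
            markers=self.markers,
            geno=self.geno[keep],
            sex=self.sex[keep],
        )


def par_mask(markers: pd.DataFrame, x_chrom: str | None, par_bp: tuple[int, int] | None) -> np.ndarray:
    """Boolean mask of markers on the X chromosome *outside* the PAR.

    These are the positions where males are hemizygous. Autosomal markers and
    PAR markers are False.
    """
    if x_chrom is None:
        return np.zeros(len(markers), dtype=bool)
    on_x = (markers["chrom"] == x_chrom).to_numpy()
    if par_bp is None:
        return on_x
    bp = markers["bp"].to_numpy()
    in_par = (bp >= par_bp[0]) & (bp <= par_bp[1])
    return on_x & ~in_par
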