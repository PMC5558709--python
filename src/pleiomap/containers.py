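"""Core in-memory containers shared by all pipeline stages.

A :class:`Pedigree` is a thin wrapper over a pandas DataFrame with one row per
animal (columns ``animal, sire, dam, sex, generation, flock, Q, age``; 0 marks
an unknown parent).  A :class:`GenotypeMatrix` couples an animals x SNPs dosage
matrix (0/1/2 counts of the alternate allele, ``nan`` for missing) with a SNP
map (chromosome, 1-based bp position).

Coordinate conventions: SNP bp positions and gene spans are 1-based inclusive;
window tiles (250-kb local-GEBV windows, 1-Mb top-SNP windows) are 0-based
half-open ``[k*w, (k+1)*w)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "Pedigree",
    "GenotypeMatrix",
    "window_index",
    "window_span",
]


class ConfigError(ValueError):
    """Invalid configuration or inconsistent input."""


class Pedigree:
    """Pedigree table; parents must precede offspring in row order."""

    REQUIRED = ("animal", "sire", "dam")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ConfigError(f"pedigree table lacks columns {missing}")
        self.table = table.reset_index(drop=True)
        self._index = {int(a): i for i, a in enumerate(self.table["animal"])}
        sires = set(self.table["sire"]) - {0}
        dams = set(self.table["dam"]) - {0}
        unknown = (sires | dams) - set(self._index)
        if unknown:
            raise ConfigError(f"parents absent from pedigree: {sorted(unknown)[:5]}")
        # parents must appear before their offspring (acyclic by construction)
        for row in self.table.itertuples(index=False):
            i = self._index[int(row.animal)]
            for p in (int(row.sire), int(row.dam)):
                if p != 0 and self._index[p] >= i:
                    raise ConfigError(f"parent {p} does not precede animal {row.animal}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def animals(self) -> np.ndarray:
        return self.table["animal"].to_numpy()

    def rows_of(self, animals) -> np.ndarray:
        return np.asarray([self._index[int(a)] for a in animals])

    def parents_idx(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of (sire, dam) per animal, -1 for unknown."""
        s = np.asarray([self._index.get(int(x), -1) if x else -1 for x in self.table["sire"]])
        d = np.asarray([self._index.get(int(x), -1) if x else -1 for x in self.table["dam"]])
        return s, d

    def offspring(self) -> pd.DataFrame:
        """Rows of the youngest generation (the phenotyped cohort)."""
        if "generation" in self.table.columns:
            g = self.table["generation"].max()
            return self.table[self.table["generation"] == g]
        both = (self.table["sire"] != 0) & (self.table["dam"] != 0)
        return self.table[both]


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus SNP map.

    dosages : (n_animals, n_snps) float or int array, alternate-allele counts,
        ``nan`` for missing calls.
    animals : animal ids aligned with rows.
    snp_map : DataFrame with columns snp_id, chrom, bp (bp 1-based).
    """

    dosages: np.ndarray
    animals: np.ndarray
    snp_map: pd.DataFrame
    _row: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.dosages.shape != (len(self.animals), len(self.snp_map)):
            raise ConfigError("dosage matrix shape does not match animals x snp_map")
        if self.snp_map["snp_id"].duplicated().any():
            raise ConfigError("duplicate SNP ids in map")
        self._row = {int(a): i for i, a in enumerate(self.animals)}

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, animals) -> "GenotypeMatrix":
        rows = [self._row[int(a)] for a in animals]
        return GenotypeMatrix(self.dosages[rows], np.asarray(animals), self.snp_map)

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.dosages[:, mask], self.animals, self.snp_map.loc[mask].reset_index(drop=True)
        )

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def same_map(self, other: "GenotypeMatrix") -> bool:
        a, b = self.snp_map, other.snp_map
        return len(a) == len(b) and (a["snp_id"].to_numpy() == b["snp_id"].to_numpy()).all()


def window_index(bp: np.ndarray, window_bp: int) -> np.ndarray:
    """0-based tile index of each 1-based bp position for half-open tiles."""
    return (np.asarray(bp, dtype=np.int64) - 1) // int(window_bp)


def window_span(idx: int, window_bp: int) -> tuple[int, int]:
    """Half-open [start, end) span of tile ``idx`` (0-based coordinates)."""
    return int(idx) * int(window_bp), (int(idx) + 1) * int(window_bp)
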