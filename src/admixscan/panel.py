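"""Core in-memory containers: haplotype panels, population maps, genetic maps.

A :class:`HaplotypePanel` is the canonical carrier of phased, polarized
genotype data: an ``H x L`` binary matrix (rows are haplotypes, columns are
biallelic sites) coded 0 = ancestral allele, 1 = derived allele, together with
physical (1-based bp) and optional genetic (cM) coordinates.  Sites whose
ancestral state could not be resolved are kept but flagged unpolarized (their
column is coded against the REF allele) and are excluded from analyses that
require polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HaplotypePanel", "PopulationMap", "GeneticMap"]


@dataclass
class GeneticMap:
    """HapMap-format recombination map: position, rate (cM/Mb), cumulative cM."""

    positions_bp: np.ndarray
    rates_cM_per_Mb: np.ndarray
    cum_cM: np.ndarray

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.rates_cM_per_Mb = np.asarray(self.rates_cM_per_Mb, dtype=float)
        self.cum_cM = np.asarray(self.cum_cM, dtype=float)
        if len(self.positions_bp) < 2:
            raise ValueError("genetic map needs at least 2 points")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("map positions must be strictly increasing")
        bad = np.nonzero(np.diff(self.cum_cM) < 0)[0]
        if bad.size:
            raise ValueError(
                f"cumulative cM decreases at map line {bad[0] + 2} "
                f"(position {self.positions_bp[bad[0] + 1]})"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions_bp,
                "COMBINED_rate(cM/Mb)": self.rates_cM_per_Mb,
                "Genetic_Map(cM)": self.cum_cM,
            }
        )


@dataclass
class HaplotypePanel:
    """Phased binary haplotype matrix with site metadata.

    Attributes
    ----------
    haplotypes : (H, L) uint8 array, 0 = ancestral, 1 = derived (REF-coded at
        unpolarized sites).
    sites : DataFrame with columns chrom, pos (1-based), ref, alt, aa,
        polarized (bool).
    sample_ids : list of length H/2; haplotype ``2i`` is the left (first) GT
        allele of sample ``i``, haplotype ``2i + 1`` the right.
    genetic_pos_cM : optional (L,) float array of interpolated map positions.
    """

    haplotypes: np.ndarray
    sites: pd.DataFrame
    sample_ids: list[str]
    genetic_pos_cM: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[1] != len(self.sites):
            raise ValueError("site table and matrix disagree on L")
        if len(self.sample_ids) * 2 != self.haplotypes.shape[0]:
            raise ValueError("need exactly two haplotypes per sample")
        pos = self.positions_bp
        if np.any(np.diff(pos) <= 0):
            raise ValueError("site positions must be strictly increasing")
        if self.genetic_pos_cM is not None:
            self.genetic_pos_cM = np.asarray(self.genetic_pos_cM, dtype=float)
            if np.any(np.diff(self.genetic_pos_cM) < 0):
                raise ValueError("genetic positions must be non-decreasing")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def positions_bp(self) -> np.ndarray:
        return self.sites["pos"].to_numpy(dtype=np.int64)

    @property
    def haplotype_ids(self) -> list[str]:
        return [f"{s}_{k}" for s in self.sample_ids for k in (0, 1)]

    def derived_freq(self) -> np.ndarray:
        """Per-site derived (or ALT, if unpolarized) allele frequency."""
        return self.haplotypes.mean(axis=0)

    def diploid_genotype_counts(self) -> np.ndarray:
        """(L, 3) counts of diploid genotypes (0/0, het, 1/1) per site.

        Consecutive haplotype pairs form the diploids, matching the phased
        VCF representation the matrix came from.
        """
        a = self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2]
        out = np.empty((self.n_sites, 3), dtype=np.int64)
        for g in range(3):
            out[:, g] = (a == g).sum(axis=0)
        return out

    def subset_haplotypes(self, rows: np.ndarray) -> np.ndarray:
        return self.haplotypes[np.asarray(rows)]


@dataclass
class PopulationMap:
    """Assignment of samples to named populations.

    Samples present in a panel but absent from the mapping are dropped from
    per-population indexing (a warning is the caller's concern).
    """

    sample_to_pop: dict[str, str] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.sample_to_pop.values():
            seen.setdefault(p, None)
        return list(seen)

    def haplotype_indices(self, panel: HaplotypePanel, pop: str) -> np.ndarray:
        """Row indices into ``panel.haplotypes`` of the haplotypes of ``pop``."""
        rows = []
        for i, s in enumerate(panel.sample_ids):
            if self.sample_to_pop.get(s) == pop:
                rows.extend((2 * i, 2 * i + 1))
        return np.asarray(rows, dtype=np.int64)

    def sample_indices(self, panel: HaplotypePanel, pop: str) -> np.ndarray:
        return np.asarray(
            [i for i, s in enumerate(panel.sample_ids) if self.sample_to_pop.get(s) == pop],
            dtype=np.int64,
        )
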