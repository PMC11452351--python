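"""Phased, ancestrally polarized haplotype data container.

The whole package operates on a single in-memory representation: an n x m
matrix of 0/1 alleles (0 = ancestral, 1 = derived) with per-site physical
and genetic coordinates.  Phasing, polarization and missing-data handling
are the caller's problem (see :mod:`sweepscan.io` for VCF ingestion rules);
the container only enforces the invariants the statistics rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypeMatrix"]


@dataclass
class HaplotypeMatrix:
    """n haplotypes x m biallelic sites, coded 0 (ancestral) / 1 (derived).

    Parameters
    ----------
    alleles
        (n, m) array of 0/1.  Stored as uint8.
    phys_pos
        m physical positions in bp, strictly increasing.  May be fractional
        (continuous-genome simulator output); rounded only on export.
    gen_pos
        m genetic positions (cM by convention), non-decreasing.
    sample_labels
        Optional n haplotype identifiers.
    """

    alleles: np.ndarray
    phys_pos: np.ndarray
    gen_pos: np.ndarray
    sample_labels: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.phys_pos = np.asarray(self.phys_pos, dtype=np.float64)
        self.gen_pos = np.asarray(self.gen_pos, dtype=np.float64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (haplotype x site) array")
        n, m = self.alleles.shape
        if n < 2:
            raise ValueError(f"need n >= 2 haplotypes, got {n}")
        if self.phys_pos.shape != (m,) or self.gen_pos.shape != (m,):
            raise ValueError("position arrays must have one entry per site")
        if np.any(self.alleles > 1):
            raise ValueError("alleles must be 0/1 (missing data is not supported)")
        if np.any(np.diff(self.phys_pos) <= 0):
            raise ValueError("phys_pos must be strictly increasing")
        if np.any(np.diff(self.gen_pos) < 0):
            raise ValueError("gen_pos must be non-decreasing")
        if self.sample_labels is not None and len(self.sample_labels) != n:
            raise ValueError("sample_labels length must equal haplotype count")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_freq(self, site: int | None = None) -> np.ndarray | float:
        """Derived-allele frequency of one site, or of all sites."""
        if site is None:
            return self.alleles.mean(axis=0)
        return float(self.alleles[:, site].mean())

    def take_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        """Subset to the given (sorted) site indices."""
        return HaplotypeMatrix(
            self.alleles[:, index],
            self.phys_pos[index],
            self.gen_pos[index],
            self.sample_labels,
        )

    def take_haplotypes(self, index: np.ndarray) -> "HaplotypeMatrix":
        labels = None
        if self.sample_labels is not None:
            labels = [self.sample_labels[i] for i in np.asarray(index)]
        return HaplotypeMatrix(self.alleles[index], self.phys_pos, self.gen_pos, labels)

    def segregating(self) -> "HaplotypeMatrix":
        """Drop monomorphic sites."""
        f = self.alleles.mean(axis=0)
        keep = np.flatnonzero((f > 0) & (f < 1))
        return self.take_sites(keep)
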