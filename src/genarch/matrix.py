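"""Core genotype container.

The :class:`GenotypeMatrix` holds phased or pseudo-phased haplotypes at
ordered biallelic sites.  It is the substrate of every per-window statistic
in the package: rows are haplotypes, columns are sites, entries are 0
(reference/ancestral), 1 (alternate/derived) or -1 (missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Haplotypes x sites matrix of biallelic alleles with metadata.

    Parameters
    ----------
    alleles
        int8 array, shape (n_haplotypes, n_sites); values in {0, 1, -1}.
    positions
        1-based physical positions, strictly increasing, one per column.
    seq_length
        Total length in bp of the region the matrix spans (includes
        monomorphic sites that carry no column).
    pops
        Population label per haplotype (length n_haplotypes).
    chrom
        Chromosome / locus label.
    phased
        True when haplotypes are genuinely phased.  Statistics that need
        phase (e.g. the H-scan statistic) refuse unphased input.
    """

    alleles: np.ndarray
    positions: np.ndarray
    seq_length: int
    pops: list[str] = field(default_factory=list)
    chrom: str = "chr1"
    phased: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape[0] != self.alleles.shape[1]:
            raise ValueError("one position per site required")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.positions.size and (
            self.positions[0] < 1 or self.positions[-1] > self.seq_length
        ):
            raise ValueError("positions must lie in [1, seq_length]")
        if self.pops and len(self.pops) != self.alleles.shape[0]:
            raise ValueError("one population label per haplotype required")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("alleles must be 0, 1 or -1 (missing)")

    # -- basic shape -----------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p, None)
        return list(seen)

    # -- selection helpers ----------------------------------------------
    def haplotype_indices(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.pops) == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population {pop!r}")
        return idx

    def subset_pops(self, pops: list[str]) -> "GenotypeMatrix":
        idx = np.concatenate([self.haplotype_indices(p) for p in pops])
        return GenotypeMatrix(
            self.alleles[idx],
            self.positions.copy(),
            self.seq_length,
            [self.pops[i] for i in idx],
            self.chrom,
            self.phased,
        )

    def slice_sites(self, start: int, end: int) -> "GenotypeMatrix":
        """Columns with 0-based half-open physical coordinates [start, end)."""
        keep = (self.positions > start) & (self.positions <= end)
        return GenotypeMatrix(
            self.alleles[:, keep],
            self.positions[keep],
            self.seq_length,
            list(self.pops),
            self.chrom,
            self.phased,
        )

    # -- dosage view ------------------------------------------------------
    def dosages(self) -> np.ndarray:
        """Diploid dosage matrix (individuals x sites) in {0,1,2,-1}.

        Consecutive haplotype pairs form individuals; any missing haplotype
        call makes the individual's dosage missing at that site.
        """
        if self.n_haplotypes % 2:
            raise ValueError("odd haplotype count: cannot form individuals")
        a = self.alleles.reshape(self.n_haplotypes // 2, 2, self.n_sites)
        dos = a.sum(axis=1).astype(np.int8)
        dos[(a == MISSING).any(axis=1)] = MISSING
        return dos

    def individual_pops(self) -> list[str]:
        if self.n_haplotypes % 2:
            raise ValueError("odd haplotype count: cannot form individuals")
        return [self.pops[i] for i in range(0, self.n_haplotypes, 2)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.positions, other.positions)
            and self.seq_length == other.seq_length
            and list(self.pops) == list(other.pops)
            and self.chrom == other.chrom
            and self.phased == other.phased
        )
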