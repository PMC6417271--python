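"""Shared genotype-matrix container.

Genotypes are stored as alternate-allele dosage per (site, sample):
0, 1 or 2 for diploids (0 or 1 for haploids), with -1 marking a missing
call.  Site coordinates are 1-based, as in VCF.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites, stored site-major.

    Parameters
    ----------
    samples : list of str
        Sample identifiers (column order of ``dosage``).
    chrom : ndarray of str
        Chromosome name per site.
    pos : ndarray of int
        1-based position per site, strictly increasing within chromosome.
    dosage : ndarray, shape (n_sites, n_samples)
        Alt-allele dosage; ``-1`` = missing.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        if len(self.chrom) != len(self.pos):
            raise ValueError("chrom and pos length mismatch")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def sample_indices(self, ids) -> np.ndarray:
        """Column indices for a sequence of sample ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[mask_or_index],
            pos=self.pos[mask_or_index],
            dosage=self.dosage[mask_or_index],
            ploidy=self.ploidy,
        )

    def take_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            dosage=self.dosage[:, idx],
            ploidy=self.ploidy,
        )
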