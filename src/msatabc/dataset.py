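"""In-memory container for multi-population diploid microsatellite data.

An allele is a two-component state: an integer repeat count on the motif
ladder plus a signed single-nucleotide indel offset accumulated in the
flanking sequence.  Two alleles are identical only if both components
match; allele *length* in nucleotides is ``motif_length * repeat + offset``
(up to the constant flanking length, which cancels in every statistic
computed here).  Statistics identify alleles by length, the observable in
fragment analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = ["AlleleState", "MicrosatDataset"]


class AlleleState(NamedTuple):
    repeat_count: int
    indel_offset: int


@dataclass
class MicrosatDataset:
    """Diploid genotypes for P populations at L unlinked loci.

    Attributes
    ----------
    repeats, offsets : int arrays, shape (n_individuals, n_loci, 2)
        Repeat counts and indel offsets for the two gene copies of each
        individual, all populations stacked (population-major order).
    pop_index : int array, shape (n_individuals,)
        Population of each individual.
    pop_names : tuple of str
    motif_lengths : int array, shape (n_loci,)
        Repeat-motif length in nucleotides per locus (2 = dinucleotide).
    locus_names : tuple of str
    """

    repeats: np.ndarray
    offsets: np.ndarray
    pop_index: np.ndarray
    pop_names: tuple
    motif_lengths: np.ndarray = None
    locus_names: tuple = None

    def __post_init__(self):
        self.repeats = np.asarray(self.repeats, dtype=np.int64)
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.pop_index = np.asarray(self.pop_index, dtype=np.int64)
        if self.repeats.shape != self.offsets.shape or self.repeats.ndim != 3:
            raise ValueError("repeats/offsets must share shape (n_ind, n_loci, 2)")
        if self.motif_lengths is None:
            self.motif_lengths = np.full(self.n_loci, 2, dtype=np.int64)
        self.motif_lengths = np.asarray(self.motif_lengths, dtype=np.int64)
        if self.locus_names is None:
            self.locus_names = tuple(f"L{i+1:03d}" for i in range(self.n_loci))
        self.pop_names = tuple(self.pop_names)

    # -- shape ---------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.repeats.shape[0]

    @property
    def n_loci(self) -> int:
        return self.repeats.shape[1]

    @property
    def n_pops(self) -> int:
        return len(self.pop_names)

    @property
    def sample_sizes(self) -> np.ndarray:
        return np.bincount(self.pop_index, minlength=self.n_pops)

    # -- derived views -------------------------------------------------------
    def allele_sizes(self) -> np.ndarray:
        """Allele lengths in nucleotides, shape (n_ind, n_loci, 2)."""
        return self.motif_lengths[None, :, None] * self.repeats + self.offsets

    def allele_codes(self) -> np.ndarray:
        """Integer codes unique per (repeat, offset) pair, same shape.

        Strict two-component identity, for callers that need to separate
        equal-length alleles with different ladder decompositions; the
        standard statistics use :meth:`allele_sizes` instead.
        """
        return self.allele_sizes() * 1000 + self.offsets

    def population(self, p) -> "MicrosatDataset":
        """Single-population view (copy) by index or name."""
        if isinstance(p, str):
            p = self.pop_names.index(p)
        mask = self.pop_index == p
        return MicrosatDataset(
            repeats=self.repeats[mask],
            offsets=self.offsets[mask],
            pop_index=np.zeros(int(mask.sum()), dtype=np.int64),
            pop_names=(self.pop_names[p],),
            motif_lengths=self.motif_lengths,
            locus_names=self.locus_names,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MicrosatDataset)
            and self.pop_names == other.pop_names
            and np.array_equal(self.repeats, other.repeats)
            and np.array_equal(self.offsets, other.offsets)
            and np.array_equal(self.pop_index, other.pop_index)
            and np.array_equal(self.motif_lengths, other.motif_lengths)
        )

    @classmethod
    def from_copy_arrays(
        cls,
        repeats_by_copy: np.ndarray,
        offsets_by_copy: np.ndarray,
        sample_sizes: Sequence[int],
        pop_names: Sequence[str] | None = None,
        motif_lengths=None,
    ) -> "MicrosatDataset":
        """Build from (n_loci, n_copies) arrays as produced by the simulator.

        Gene copies are population-major, two consecutive copies per
        individual.
        """
        n_loci, n_copies = repeats_by_copy.shape
        n_ind = n_copies // 2
        if pop_names is None:
            pop_names = tuple(f"pop{i+1}" for i in range(len(sample_sizes)))
        pop_index = np.repeat(np.arange(len(sample_sizes)), sample_sizes)
        rep = repeats_by_copy.T.reshape(n_ind, 2, n_loci).transpose(0, 2, 1)
        off = offsets_by_copy.T.reshape(n_ind, 2, n_loci).transpose(0, 2, 1)
        return cls(
            repeats=rep,
            offsets=off,
            pop_index=pop_index,
            pop_names=tuple(pop_names),
            motif_lengths=motif_lengths,
        )
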