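"""mtDNA haplotype statistics: concatenation, collapsing, H and pi.

Sequences are handled as aligned equal-length strings (gaps ``-`` allowed).
Haplotype identity is indel-aware: two sequences are the same haplotype
only if they agree at every column, gap characters included.  For
nucleotide diversity, pairwise differences count only columns where both
sequences carry a base (gap sites are excluded from the difference count),
while the divisor defaults to the full alignment length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta_alignment",
    "write_fasta_alignment",
    "concatenate_regions",
    "HaplotypeTable",
    "collapse_haplotypes",
    "haplotype_diversity",
    "nucleotide_diversity",
    "pairwise_differences",
]

GAP = "-"


def read_fasta_alignment(path) -> dict:
    """FASTA file -> ordered ``{name: sequence}`` mapping (upper-cased)."""
    aln = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        aln[rec.id] = str(rec.seq).upper()
    if not aln:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError(f"unaligned sequences (lengths {sorted(lengths)}) in {path}")
    return aln


def write_fasta_alignment(alignment: Mapping[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in alignment.items()]
    SeqIO.write(recs, str(path), "fasta")


def concatenate_regions(fragments: Mapping[str, Mapping[str, str]]):
    """Concatenate per-region alignments sample-wise.

    Parameters
    ----------
    fragments : mapping of region name -> {sample: sequence}
        All regions must cover exactly the same sample set.

    Returns
    -------
    (alignment, boundaries) : ``{sample: concatenated sequence}`` plus a
        list of ``(region, start, end)`` half-open column ranges.
    """
    regions = list(fragments)
    if not regions:
        raise ValueError("no regions given")
    samples = list(fragments[regions[0]])
    sample_set = set(samples)
    for r in regions:
        missing = sample_set.symmetric_difference(fragments[r])
        if missing:
            raise ValueError(
                f"region {r!r}: sample set mismatch for {sorted(missing)}"
            )
    boundaries = []
    start = 0
    for r in regions:
        length = len(next(iter(fragments[r].values())))
        boundaries.append((r, start, start + length))
        start += length
    concat = {s: "".join(fragments[r][s] for r in regions) for s in samples}
    return concat, boundaries


@dataclass
class HaplotypeTable:
    """Unique haplotypes with their multiplicities.

    ``counts[i]`` is the number of carriers of ``haplotypes[i]``;
    ``members[i]`` lists their sample names.  Collapsing is idempotent:
    collapsing the haplotypes again yields the same table.
    """

    haplotypes: tuple
    counts: np.ndarray
    members: tuple

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


def collapse_haplotypes(alignment: Mapping[str, str], strict: bool = True) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes (indel-aware).

    With ``strict`` (default) ambiguity codes are ordinary characters and
    any mismatch separates haplotypes; haplotypes are ordered by
    decreasing count, ties by first appearance.
    """
    seen: dict = {}
    order: list = []
    for name, seq in alignment.items():
        key = seq.upper()
        if not strict:
            key = key.replace("N", "?")
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(name)
    first_seen = {k: i for i, k in enumerate(order)}
    order.sort(key=lambda k: (-len(seen[k]), first_seen[k]))
    return HaplotypeTable(
        haplotypes=tuple(order),
        counts=np.array([len(seen[k]) for k in order], dtype=np.int64),
        members=tuple(tuple(seen[k]) for k in order),
    )


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Unbiased haplotype diversity ``H = n/(n-1) (1 - sum p_i^2)``."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2 sequences")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - (p**2).sum()))


def pairwise_differences(a: str, b: str) -> int:
    """Nucleotide differences at columns where both sequences carry a base."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    return sum(1 for x, y in zip(a, b) if x != y and x != GAP and y != GAP)


def nucleotide_diversity(
    haplotypes: Sequence[str],
    counts: Sequence[int],
    length: int | None = None,
) -> float:
    """Unbiased nucleotide diversity per site.

    ``pi = n/(n-1) * sum_{i<j} 2 p_i p_j d_ij / L`` where ``d_ij`` is the
    pairwise difference count and ``L`` the alignment length (overridable
    via ``length``, e.g. to exclude gap columns).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("nucleotide diversity needs n >= 2 sequences")
    if len(haplotypes) != len(counts):
        raise ValueError("haplotypes and counts differ in length")
    L = length if length is not None else len(haplotypes[0])
    p = counts / n
    tot = 0.0
    for i in range(len(haplotypes)):
        for j in range(i + 1, len(haplotypes)):
            tot += 2.0 * p[i] * p[j] * pairwise_differences(haplotypes[i], haplotypes[j])
    return float(n / (n - 1.0) * tot / L)
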