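"""Genepop-format reader/writer for :class:`~msatabc.dataset.MicrosatDataset`.

Alleles are encoded as 3-digit codes equal to the allele length in
nucleotides, ``motif_length * repeat_count + indel_offset`` (plus an
optional constant flanking length).  The encoding is exactly invertible to
a canonical (repeat, offset) pair with ``0 <= offset < motif_length``; all
statistics in this package identify alleles by length, so a write/read
round trip preserves every statistic.

Locus motif lengths are carried as a ``-m<k>`` suffix on the written locus
names so the ladder can be reconstructed on read.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .dataset import MicrosatDataset

__all__ = ["write_genepop", "read_genepop"]

_MISSING = 0


def write_genepop(dataset: MicrosatDataset, path, title: str = "msatabc dataset",
                  offset_constant: int = 0) -> None:
    """Write a dataset to a Genepop (3-digit alleles) file."""
    sizes = dataset.allele_sizes() + offset_constant
    if sizes.min() < 1 or sizes.max() > 999:
        raise ValueError(
            "allele sizes outside the 3-digit Genepop range; "
            "adjust offset_constant"
        )
    lines = [title]
    for name, m in zip(dataset.locus_names, dataset.motif_lengths):
        lines.append(f"{name}-m{int(m)}")
    for p, pname in enumerate(dataset.pop_names):
        lines.append("Pop")
        idx = np.flatnonzero(dataset.pop_index == p)
        for j, i in enumerate(idx):
            genos = "".join(
                f" {sizes[i, l, 0]:03d}{sizes[i, l, 1]:03d}"
                for l in range(dataset.n_loci)
            )
            lines.append(f"{pname}_{j+1:03d} ,{genos}")
    Path(path).write_text("\n".join(lines) + "\n")


_LOCUS_MOTIF_RE = re.compile(r"^(?P<name>.*?)-m(?P<motif>\d+)$")


def read_genepop(path, offset_constant: int = 0) -> MicrosatDataset:
    """Read a Genepop file written with 3-digit (or 2-digit) allele codes."""
    raw = [ln.rstrip() for ln in Path(path).read_text().splitlines()]
    if not raw:
        raise ValueError("empty Genepop file")
    body = raw[1:]  # drop title
    locus_names: list = []
    motifs: list = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        line = body[i].strip()
        if line:
            # comma-separated locus list on one line is legal Genepop
            for tok in (t.strip() for t in line.split(",")):
                if not tok:
                    continue
                m = _LOCUS_MOTIF_RE.match(tok)
                if m:
                    locus_names.append(m.group("name"))
                    motifs.append(int(m.group("motif")))
                else:
                    locus_names.append(tok)
                    motifs.append(2)
        i += 1
    n_loci = len(locus_names)
    if n_loci == 0:
        raise ValueError("no locus names found")

    pops: list = []  # list of lists of (n_loci, 2) arrays
    current = None
    for line in body[i:]:
        s = line.strip()
        if not s:
            continue
        if s.lower() == "pop":
            current = []
            pops.append(current)
            continue
        if current is None:
            raise ValueError("genotype line before first 'Pop'")
        if "," not in s:
            raise ValueError(f"malformed genotype line: {s!r}")
        _, genos = s.split(",", 1)
        toks = genos.split()
        if len(toks) != n_loci:
            raise ValueError(
                f"expected {n_loci} genotypes, found {len(toks)}: {s!r}"
            )
        row = np.empty((n_loci, 2), dtype=np.int64)
        for l, tok in enumerate(toks):
            w = len(tok) // 2
            if len(tok) not in (4, 6):
                raise ValueError(f"bad genotype token {tok!r}")
            row[l, 0] = int(tok[:w])
            row[l, 1] = int(tok[w:])
        current.append(row)
    if not pops:
        raise ValueError("no populations found")

    sample_sizes = [len(p) for p in pops]
    all_rows = np.stack([r for p in pops for r in p])  # (n_ind, n_loci, 2)
    if np.any(all_rows == _MISSING):
        raise ValueError("missing genotypes are not supported")
    sizes = all_rows - offset_constant
    motif_arr = np.asarray(motifs, dtype=np.int64)
    repeats = sizes // motif_arr[None, :, None]
    offsets = sizes - repeats * motif_arr[None, :, None]
    pop_index = np.repeat(np.arange(len(pops)), sample_sizes)
    return MicrosatDataset(
        repeats=repeats,
        offsets=offsets,
        pop_index=pop_index,
        pop_names=tuple(f"pop{k+1}" for k in range(len(pops))),
        motif_lengths=motif_arr,
        locus_names=tuple(locus_names),
    )
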