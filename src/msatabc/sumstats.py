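"""Microsatellite summary statistics.

Two layers live here:

* descriptive per-population statistics as reported for observed data
  (observed/effective allele numbers, observed/unbiased expected
  heterozygosity, inbreeding coefficient F, Hardy-Weinberg tests);
* the ordered summary-statistic vector used as the ABC feature space:
  per population {mean number of alleles, mean genetic diversity, mean
  allele-size variance} and per population pair {pooled mean number of
  alleles, pooled mean genetic diversity, Weir-Cockerham Fst, shared-allele
  distance}, all averaged over loci.

Alleles are identified by their length in nucleotides (the quantity scored
in fragment analysis); genetic diversity is the unbiased expected
heterozygosity ``2n/(2n-1) * (1 - sum p^2)``; allele-size variance is the
``ddof=1`` sample variance of allele lengths across gene copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .dataset import MicrosatDataset

__all__ = [
    "DiversityReport",
    "diversity_report",
    "one_sample_stats",
    "pairwise_stats",
    "weir_cockerham_fst",
    "shared_allele_distance",
    "summary_vector",
    "summary_stat_names",
    "hwe_test",
]


def _copies(dataset: MicrosatDataset, pop: int | None = None) -> np.ndarray:
    """Allele lengths per gene copy, shape (2*n_ind, n_loci)."""
    sizes = dataset.allele_sizes()
    if pop is not None:
        sizes = sizes[dataset.pop_index == pop]
    return sizes.transpose(0, 2, 1).reshape(-1, sizes.shape[1])


def _allele_counts(copies: np.ndarray, vmin: int, n_vals: int) -> np.ndarray:
    """Per-locus allele counts, shape (n_vals, n_loci)."""
    n_loci = copies.shape[1]
    code = (copies - vmin) * n_loci + np.arange(n_loci)[None, :]
    return np.bincount(code.ravel(), minlength=n_vals * n_loci).reshape(
        n_vals, n_loci
    )


def _unbiased_he(counts: np.ndarray) -> np.ndarray:
    """Unbiased expected heterozygosity per locus from allele counts."""
    n2 = counts.sum(axis=0).astype(float)  # gene copies
    sum_p2 = (counts.astype(float) ** 2).sum(axis=0) / n2**2
    return n2 / (n2 - 1.0) * (1.0 - sum_p2)


# ---------------------------------------------------------------------------
# descriptive report
# ---------------------------------------------------------------------------

@dataclass
class DiversityReport:
    """Locus-averaged microsatellite variability of one population.

    ``F = 1 - Ho/He`` from the locus-averaged heterozygosities; ``nan``
    when the population is monomorphic overall (He = 0).
    """

    Ao: float
    Ae: float
    Ho: float
    He: float
    F: float
    n_individuals: int
    n_loci: int

    def as_dict(self) -> dict:
        return {
            "Ao": self.Ao, "Ae": self.Ae, "Ho": self.Ho, "He": self.He,
            "F": self.F, "n": self.n_individuals, "loci": self.n_loci,
        }


def diversity_report(dataset: MicrosatDataset, pop: int | str | None = None) -> DiversityReport:
    """Compute Ao, Ae, Ho, He and F for one population.

    Parameters
    ----------
    dataset : MicrosatDataset
    pop : optional population index or name; required when the dataset
        holds more than one population.
    """
    if pop is None:
        if dataset.n_pops > 1:
            raise ValueError("dataset has several populations; pass pop=")
        pop = 0
    elif isinstance(pop, str):
        pop = dataset.pop_names.index(pop)
    sizes = dataset.allele_sizes()[dataset.pop_index == pop]  # (n, L, 2)
    n, n_loci, _ = sizes.shape
    if n < 1 or n_loci < 1:
        raise ValueError("need at least one individual and one locus")
    copies = sizes.transpose(0, 2, 1).reshape(2 * n, n_loci)
    vmin, vmax = int(copies.min()), int(copies.max())
    counts = _allele_counts(copies, vmin, vmax - vmin + 1)
    k = (counts > 0).sum(axis=0)
    sum_p2 = (counts.astype(float) ** 2).sum(axis=0) / (2.0 * n) ** 2
    ho_l = (sizes[:, :, 0] != sizes[:, :, 1]).mean(axis=0)
    he_l = _unbiased_he(counts)
    ho = float(ho_l.mean())
    he = float(he_l.mean())
    return DiversityReport(
        Ao=float(k.mean()),
        Ae=float((1.0 / sum_p2).mean()),
        Ho=ho,
        He=he,
        F=(1.0 - ho / he) if he > 0 else float("nan"),
        n_individuals=n,
        n_loci=n_loci,
    )


# ---------------------------------------------------------------------------
# ABC one-sample and two-sample statistics
# ---------------------------------------------------------------------------

def _one_sample_from_copies(copies: np.ndarray) -> tuple:
    vmin, vmax = int(copies.min()), int(copies.max())
    counts = _allele_counts(copies, vmin, vmax - vmin + 1)
    mean_k = float((counts > 0).sum(axis=0).mean())
    mean_he = float(_unbiased_he(counts).mean())
    if copies.shape[0] > 1:
        mean_v = float(copies.var(axis=0, ddof=1).mean())
    else:
        mean_v = 0.0
    return mean_k, mean_he, mean_v


def one_sample_stats(dataset: MicrosatDataset, pop: int = 0) -> tuple:
    """(mean number of alleles, mean genetic diversity, mean size variance)."""
    return _one_sample_from_copies(_copies(dataset, pop))


def _het_counts(sizes: np.ndarray, vmin: int, n_vals: int) -> np.ndarray:
    """Per-locus count of heterozygous individuals carrying each allele."""
    n, n_loci, _ = sizes.shape
    het = sizes[:, :, 0] != sizes[:, :, 1]
    out = np.zeros(n_vals * n_loci, dtype=np.int64)
    locus_ix = np.broadcast_to(np.arange(n_loci), (n, n_loci))
    for c in (0, 1):
        code = (sizes[:, :, c] - vmin) * n_loci + locus_ix
        np.add.at(out, code[het], 1)
    return out.reshape(n_vals, n_loci)


def weir_cockerham_fst(dataset: MicrosatDataset, pop_a: int, pop_b: int):
    """Weir-Cockerham theta between two populations.

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are accumulated over every
    allele of every locus and combined as a ratio of sums,
    ``theta = sum(a) / sum(a + b + c)``.  Returns ``nan`` when the total
    variance is zero (both samples monomorphic for the same allele).
    """
    sizes = dataset.allele_sizes()
    sa = sizes[dataset.pop_index == pop_a]
    sb = sizes[dataset.pop_index == pop_b]
    n1, n_loci = sa.shape[0], sa.shape[1]
    n2 = sb.shape[0]
    ca = sa.transpose(0, 2, 1).reshape(2 * n1, n_loci)
    cb = sb.transpose(0, 2, 1).reshape(2 * n2, n_loci)
    vmin = int(min(ca.min(), cb.min()))
    vmax = int(max(ca.max(), cb.max()))
    n_vals = vmax - vmin + 1
    p1 = _allele_counts(ca, vmin, n_vals) / (2.0 * n1)
    p2 = _allele_counts(cb, vmin, n_vals) / (2.0 * n2)
    h1 = _het_counts(sa, vmin, n_vals) / float(n1)
    h2 = _het_counts(sb, vmin, n_vals) / float(n2)

    r = 2.0
    nbar = (n1 + n2) / 2.0
    if nbar <= 1:
        return float("nan")  # theta needs within-population replication
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    denom = (a + b + c).sum()
    if denom == 0.0:
        return float("nan")
    return float(a.sum() / denom)


def shared_allele_distance(dataset: MicrosatDataset, pop_a: int, pop_b: int) -> float:
    """DAS: 1 - mean shared-allele proportion between the two populations.

    For every inter-population pair of individuals and every locus the two
    diploid genotypes share 0, 1 or 2 alleles (counting multiplicity); the
    proportion shared/2 is averaged over pairs and loci.
    """
    sizes = dataset.allele_sizes()
    sa = sizes[dataset.pop_index == pop_a]  # (n1, L, 2)
    sb = sizes[dataset.pop_index == pop_b]
    a1 = sa[:, None, :, 0]
    a2 = sa[:, None, :, 1]
    b1 = sb[None, :, :, 0]
    b2 = sb[None, :, :, 1]
    m_ident = (a1 == b1).astype(np.int8) + (a2 == b2)
    m_cross = (a1 == b2).astype(np.int8) + (a2 == b1)
    shared = np.maximum(m_ident, m_cross)  # max over the two perfect matchings
    return float(1.0 - shared.mean() / 2.0)


def pairwise_stats(dataset: MicrosatDataset, pop_a: int, pop_b: int) -> tuple:
    """(pooled mean alleles, pooled mean diversity, Fst, DAS) for one pair."""
    pooled = np.concatenate(
        [_copies(dataset, pop_a), _copies(dataset, pop_b)], axis=0
    )
    mean_k, mean_he, _ = _one_sample_from_copies(pooled)
    fst = weir_cockerham_fst(dataset, pop_a, pop_b)
    das = shared_allele_distance(dataset, pop_a, pop_b)
    return mean_k, mean_he, fst, das


def summary_stat_names(pop_names: Sequence[str]) -> tuple:
    names = []
    for p in pop_names:
        names += [f"A_{p}", f"He_{p}", f"V_{p}"]
    for pa, pb in combinations(pop_names, 2):
        names += [
            f"A_{pa}+{pb}", f"He_{pa}+{pb}", f"Fst_{pa}-{pb}", f"DAS_{pa}-{pb}"
        ]
    return tuple(names)


def summary_vector(dataset: MicrosatDataset) -> np.ndarray:
    """The ordered ABC summary-statistic vector.

    Length ``3 P + 4 P(P-1)/2`` for ``P`` populations (21 for P = 3); the
    order follows :func:`summary_stat_names`.
    """
    out = []
    for p in range(dataset.n_pops):
        out.extend(one_sample_stats(dataset, p))
    for pa, pb in combinations(range(dataset.n_pops), 2):
        out.extend(pairwise_stats(dataset, pa, pb))
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# Hardy-Weinberg testing
# ---------------------------------------------------------------------------

def hwe_test(
    dataset: MicrosatDataset,
    pop: int = 0,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    bonferroni: bool = True,
):
    """Monte-Carlo Hardy-Weinberg test per locus (heterozygote deficit).

    Gene copies are permuted among individuals within each locus; the
    one-sided p-value is the proportion of permutations with observed
    heterozygosity at most the real one (+1 smoothing).  Returns an array
    of p-values (and, with ``bonferroni``, the per-locus significance
    threshold ``0.05 / n_loci``).
    """
    if rng is None:
        rng = np.random.default_rng()
    sizes = dataset.allele_sizes()[dataset.pop_index == pop]
    n, n_loci, _ = sizes.shape
    pvals = np.empty(n_loci)
    for l in range(n_loci):
        copies = sizes[:, l, :].ravel()
        obs_ho = (sizes[:, l, 0] != sizes[:, l, 1]).mean()
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(copies).reshape(n, 2)
            if (perm[:, 0] != perm[:, 1]).mean() <= obs_ho:
                hits += 1
        pvals[l] = (hits + 1) / (n_perm + 1)
    if bonferroni:
        return pvals, 0.05 / n_loci
    return pvals
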