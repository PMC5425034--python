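"""Pseudo-observed datasets and text fixtures.

The study design being emulated: three wolf populations sampled at 39, 20
and 40 diploid individuals, 39 unlinked autosomal microsatellites (32
dinucleotide and 7 tetranucleotide motifs), plus four concatenable mtDNA
fragments of 498, 588, 231 and 847 bp (control region, ATP6, COIII, ND4;
2164 bp concatenated).  Every generator is a pure function of its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genepop import write_genepop
from .mtdna import write_fasta_alignment
from .scenarios import ParameterDraw, SCENARIOS
from .simulate import simulate_dataset

__all__ = [
    "FixtureSpec",
    "WOLF_SAMPLE_SIZES",
    "WOLF_N_LOCI",
    "WOLF_TRUTH_SCENARIO2",
    "MTDNA_REGION_LENGTHS",
    "MTDNA_REGION_NAMES",
    "default_motif_lengths",
    "make_pseudo_observed",
    "make_mtdna_fixture",
    "write_fixture_bundle",
]

#: diploid sample sizes of the three focal wolf populations
WOLF_SAMPLE_SIZES = (39, 20, 40)
WOLF_N_LOCI = 39

#: canonical truth for pseudo-observed data: the posterior medians inferred
#: for the simultaneous-split + bottleneck history of the three populations
WOLF_TRUTH_SCENARIO2 = ParameterDraw(
    N1=3380.0, N2=3240.0, N3=5480.0, NA=3270.0,
    t1=6830.0, db=5010.0,
    N1b=6400.0, N2b=14400.0, N3b=16500.0,
    mu_mic=1.72e-4, p_mic=0.104, sni_mic=2.67e-6,
)

MTDNA_REGION_NAMES = ("CR", "ATP6", "COIII", "ND4")
MTDNA_REGION_LENGTHS = (498, 588, 231, 847)

_BASES = np.array(list("ACGT"))


def default_motif_lengths(n_loci: int = WOLF_N_LOCI) -> np.ndarray:
    """Motif lengths for the emulated panel: 32 di- then 7 tetranucleotide."""
    m = np.full(n_loci, 2, dtype=np.int64)
    m[32:] = 4
    return m


@dataclass
class FixtureSpec:
    """Recipe for one pseudo-observed microsatellite dataset."""

    scenario_id: int = 2
    params: ParameterDraw = field(default_factory=lambda: WOLF_TRUTH_SCENARIO2)
    sample_sizes: tuple = WOLF_SAMPLE_SIZES
    n_loci: int = WOLF_N_LOCI
    seed: int = 0

    def truth_record(self) -> dict:
        return {
            "scenario": self.scenario_id,
            "params": self.params.as_dict(),
            "sample_sizes": list(self.sample_sizes),
            "n_loci": self.n_loci,
            "seed": self.seed,
        }

    @classmethod
    def from_truth_record(cls, d: Mapping) -> "FixtureSpec":
        return cls(
            scenario_id=int(d["scenario"]),
            params=ParameterDraw.from_dict(d["params"]),
            sample_sizes=tuple(d["sample_sizes"]),
            n_loci=int(d["n_loci"]),
            seed=int(d["seed"]),
        )


def make_pseudo_observed(spec: FixtureSpec, outdir=None, **sim_kwargs):
    """Simulate a pseudo-observed dataset with its truth record.

    Returns ``(dataset, truth_dict)``; with ``outdir`` also writes
    ``pseudo_observed.gen`` (Genepop) and ``truth.json``.
    """
    rng = np.random.default_rng(spec.seed)
    sim_kwargs.setdefault("motif_lengths", default_motif_lengths(spec.n_loci))
    ds = simulate_dataset(
        SCENARIOS[spec.scenario_id], spec.params, spec.n_loci,
        spec.sample_sizes, rng, **sim_kwargs,
    )
    truth = spec.truth_record()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genepop(ds, outdir / "pseudo_observed.gen",
                      title=f"pseudo-observed scenario {spec.scenario_id}")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return ds, truth


def _haplotype_patterns(k: int, v: int) -> np.ndarray:
    """k x v binary matrix: distinct rows, every column segregating."""
    need = max(1, int(np.ceil(np.log2(k)))) if k > 1 else 1
    if v < need:
        raise ValueError(
            f"{v} variant position(s) cannot distinguish {k} haplotypes"
        )
    pat = np.zeros((k, v), dtype=np.int8)
    for h in range(k):
        for j in range(need):
            pat[h, j] = (h >> j) & 1
    # extra columns alternate so each still segregates
    for j in range(need, v):
        pat[:, j] = np.arange(k) % 2
    if k == 2:
        pat[1, :] = 1  # both haplotypes differ at every variant column
    return pat


def make_mtdna_fixture(
    haplotype_counts: Sequence[int],
    region_lengths: Sequence[int] = MTDNA_REGION_LENGTHS,
    n_variants: int = 1,
    seed: int = 0,
    variant_regions: Sequence[int] | None = None,
    region_names: Sequence[str] = MTDNA_REGION_NAMES,
    sample_prefix: str = "S",
):
    """Generate aligned per-region FASTA-ready haplotype data.

    ``haplotype_counts`` gives the multiplicity of each haplotype;
    ``n_variants`` segregating columns are placed at seeded random
    positions (restricted to ``variant_regions`` indices when given).
    Background composition is uniform random, which no implemented
    statistic depends on.

    Returns ``{region: {sample: sequence}}`` with samples interleaved in
    haplotype order.
    """
    counts = [int(c) for c in haplotype_counts]
    if sum(counts) < 2:
        raise ValueError("need at least two sequences in total")
    if n_variants < 1:
        raise ValueError("need at least one variant position")
    total_len = int(sum(region_lengths))
    if n_variants > total_len:
        raise ValueError("more variants than alignment columns")
    rng = np.random.default_rng(seed)
    k = len(counts)
    pat = _haplotype_patterns(k, n_variants)

    backbone = rng.choice(_BASES, size=total_len)
    # variant columns: position + alternative base
    if variant_regions is None:
        positions = rng.choice(total_len, size=n_variants, replace=False)
    else:
        pool = np.concatenate([
            np.arange(sum(region_lengths[:r]), sum(region_lengths[: r + 1]))
            for r in variant_regions
        ])
        if len(pool) < n_variants:
            raise ValueError("variant_regions too short for n_variants")
        positions = rng.choice(pool, size=n_variants, replace=False)
    alts = np.empty(n_variants, dtype=backbone.dtype)
    for i, pos in enumerate(positions):
        choices = [b for b in _BASES if b != backbone[pos]]
        alts[i] = choices[rng.integers(0, 3)]

    hap_seqs = []
    for h in range(k):
        s = backbone.copy()
        for i, pos in enumerate(positions):
            if pat[h, i]:
                s[pos] = alts[i]
        hap_seqs.append("".join(s))

    names = []
    hap_of = []
    i = 1
    for h, c in enumerate(counts):
        for _ in range(c):
            names.append(f"{sample_prefix}{i:03d}")
            hap_of.append(h)
            i += 1

    out = {}
    start = 0
    for rname, rlen in zip(region_names, region_lengths):
        out[rname] = {
            nm: hap_seqs[h][start:start + rlen] for nm, h in zip(names, hap_of)
        }
        start += rlen
    return out


def write_fixture_bundle(outdir, seed: int = 0,
                         spec: FixtureSpec | None = None) -> dict:
    """Write the default fixtures (Genepop + per-region FASTA + truth JSON).

    The microsatellite fixture follows the emulated study design; the
    mtDNA fixture reproduces the Italian-wolf control-region structure
    (two haplotypes, 34 and 5 carriers, one substitution).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = FixtureSpec(seed=seed)
    _, truth = make_pseudo_observed(spec, outdir=outdir)
    regions = make_mtdna_fixture([34, 5], n_variants=1, seed=seed,
                                 variant_regions=[0])
    paths = {"genepop": str(outdir / "pseudo_observed.gen"),
             "truth": str(outdir / "truth.json")}
    for rname, aln in regions.items():
        p = outdir / f"mtdna_{rname}.fasta"
        write_fasta_alignment(aln, p)
        paths[rname] = str(p)
    return paths
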