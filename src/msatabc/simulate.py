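"""Structured-coalescent simulation of multilocus microsatellite data.

Genealogies are drawn under the continuous-time coalescent with
piecewise-constant diploid population sizes and backwards-in-time merge
events (an :class:`~msatabc.scenarios.EpochPlan`): within a population of
diploid size ``N``, each pair of lineages coalesces at rate ``1/(2N)`` per
generation, so ``k`` lineages coalesce at total rate ``k(k-1)/(4N)``.
Exponential waiting times are re-drawn across epoch boundaries, which is
exact by memorylessness.

Mutations follow the generalised stepwise model (GSM): per branch of length
``b`` the mutation count is Poisson(``mu * b``); each mutation shifts the
repeat count by ``±k`` with fair sign and geometric step size
``P(k) = (1-p) p^(k-1)`` (``p = 0`` recovers the strict stepwise model).
Single-nucleotide indels (SNI) in the flanking sequence are overlaid as an
independent Poisson(``sni * b``) process of ±1-nucleotide offsets, taking
alleles off the repeat ladder.

The hot loops are compiled with numba; a fixed integer seed gives bitwise
reproducible output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .dataset import AlleleState, MicrosatDataset
from .scenarios import DemographicScenario, EpochPlan, ParameterDraw, build_epochs

__all__ = [
    "Genealogy",
    "simulate_genealogy",
    "mutate_gsm",
    "apply_sni",
    "simulate_dataset",
    "DEFAULT_ROOT_STATE",
]

#: root allele; every statistic used downstream is translation invariant,
#: so the value is inert.
DEFAULT_ROOT_STATE = AlleleState(repeat_count=20, indel_offset=0)

_MAX_SEED = 2**31 - 1


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _coalesce_locus(sample_pops, sizes0, ev_time, ev_kind, ev_pop, ev_arg,
                    parent, node_time):
    """Fill parent/node_time arrays for one genealogy. Leaves are 0..n-1."""
    n = sample_pops.shape[0]
    n_pops = sizes0.shape[0]
    sizes = sizes0.copy()
    act_id = np.empty(n, np.int64)
    act_pop = np.empty(n, np.int64)
    for i in range(n):
        act_id[i] = i
        act_pop[i] = sample_pops[i]
        node_time[i] = 0.0
    n_act = n
    cnt = np.empty(n_pops, np.int64)
    rate = np.empty(n_pops, np.float64)
    t = 0.0
    ev_i = 0
    n_ev = ev_time.shape[0]
    next_node = n
    while n_act > 1:
        for p in range(n_pops):
            cnt[p] = 0
        for a in range(n_act):
            cnt[act_pop[a]] += 1
        tot = 0.0
        for p in range(n_pops):
            k = cnt[p]
            if k > 1:
                rate[p] = k * (k - 1) / (4.0 * sizes[p])
            else:
                rate[p] = 0.0
            tot += rate[p]
        if tot > 0.0:
            t_c = t + np.random.exponential(1.0 / tot)
        else:
            t_c = np.inf
        if ev_i < n_ev and ev_time[ev_i] <= t_c:
            t = ev_time[ev_i]
            if ev_kind[ev_i] == 0:  # resize
                sizes[ev_pop[ev_i]] = ev_arg[ev_i]
            else:  # merge: lineages of ev_pop move to dest
                dst = np.int64(ev_arg[ev_i])
                src = ev_pop[ev_i]
                for a in range(n_act):
                    if act_pop[a] == src:
                        act_pop[a] = dst
            ev_i += 1
            continue
        if t_c == np.inf:  # invalid plan guard; validated plans never hit this
            break
        t = t_c
        u = np.random.random() * tot
        p = 0
        acc = rate[0]
        while acc < u and p < n_pops - 1:
            p += 1
            acc += rate[p]
        k = cnt[p]
        i1 = np.random.randint(0, k)
        i2 = np.random.randint(0, k - 1)
        if i2 >= i1:
            i2 += 1
        pos1 = -1
        pos2 = -1
        seen = 0
        for a in range(n_act):
            if act_pop[a] == p:
                if seen == i1:
                    pos1 = a
                if seen == i2:
                    pos2 = a
                seen += 1
        node_time[next_node] = t
        parent[act_id[pos1]] = next_node
        parent[act_id[pos2]] = next_node
        act_id[pos1] = next_node
        # pos1 keeps pop p; drop pos2 by swapping in the last active
        act_id[pos2] = act_id[n_act - 1]
        act_pop[pos2] = act_pop[n_act - 1]
        n_act -= 1
        next_node += 1
    parent[2 * n - 2] = -1


@njit(cache=True)
def _mutate_into(parent, node_time, n_leaves, mu, p_geom, sni,
                 root_repeat, root_offset, lo, hi, out_rep, out_off):
    """Drop GSM + SNI mutations on a genealogy; write leaf states.

    ``lo > hi`` disables the allele ladder bounds; otherwise each GSM step
    is reflected back into ``[lo, hi]``.
    """
    n_nodes = parent.shape[0]
    rep = np.empty(n_nodes, np.int64)
    off = np.empty(n_nodes, np.int64)
    rep[n_nodes - 1] = root_repeat
    off[n_nodes - 1] = root_offset
    bounded = lo <= hi
    for i in range(n_nodes - 2, -1, -1):
        b = node_time[parent[i]] - node_time[i]
        r = rep[parent[i]]
        if mu > 0.0:
            nm = np.random.poisson(mu * b)
            for _ in range(nm):
                k = np.random.geometric(1.0 - p_geom)
                if np.random.random() < 0.5:
                    r += k
                else:
                    r -= k
                if bounded:
                    while r > hi or r < lo:
                        if r > hi:
                            r = 2 * hi - r
                        if r < lo:
                            r = 2 * lo - r
        rep[i] = r
        o = off[parent[i]]
        if sni > 0.0:
            ns = np.random.poisson(sni * b)
            for _ in range(ns):
                if np.random.random() < 0.5:
                    o += 1
                else:
                    o -= 1
        off[i] = o
    for i in range(n_leaves):
        out_rep[i] = rep[i]
        out_off[i] = off[i]


@njit(cache=True)
def _sim_tree_kernel(seed, sample_pops, sizes0, ev_time, ev_kind, ev_pop, ev_arg):
    np.random.seed(seed)
    n = sample_pops.shape[0]
    parent = np.empty(2 * n - 1, np.int64)
    node_time = np.zeros(2 * n - 1, np.float64)
    _coalesce_locus(sample_pops, sizes0, ev_time, ev_kind, ev_pop, ev_arg,
                    parent, node_time)
    return parent, node_time


@njit(cache=True)
def _mutate_kernel(seed, parent, node_time, n_leaves, mu, p_geom, sni,
                   root_repeat, root_offset, lo, hi):
    np.random.seed(seed)
    out_rep = np.empty(n_leaves, np.int64)
    out_off = np.empty(n_leaves, np.int64)
    _mutate_into(parent, node_time, n_leaves, mu, p_geom, sni,
                 root_repeat, root_offset, lo, hi, out_rep, out_off)
    return out_rep, out_off


@njit(cache=True)
def _sim_dataset_kernel(seed, sample_pops, sizes0, ev_time, ev_kind, ev_pop,
                        ev_arg, mu_per_locus, p_geom, sni,
                        root_repeat, lo, hi):
    np.random.seed(seed)
    n = sample_pops.shape[0]
    n_loci = mu_per_locus.shape[0]
    reps = np.empty((n_loci, n), np.int64)
    offs = np.empty((n_loci, n), np.int64)
    parent = np.empty(2 * n - 1, np.int64)
    node_time = np.zeros(2 * n - 1, np.float64)
    for l in range(n_loci):
        _coalesce_locus(sample_pops, sizes0, ev_time, ev_kind, ev_pop, ev_arg,
                        parent, node_time)
        _mutate_into(parent, node_time, n, mu_per_locus[l], p_geom, sni,
                     root_repeat, 0, lo, hi, reps[l], offs[l])
    return reps, offs


# ---------------------------------------------------------------------------
# Python API
# ---------------------------------------------------------------------------

def _plan_arrays(plan: EpochPlan):
    plan.validate()
    ev = plan.events
    ev_time = np.array([e.time for e in ev], dtype=np.float64)
    ev_kind = np.array([0 if e.kind == "resize" else 1 for e in ev], dtype=np.int64)
    ev_pop = np.array([e.pop for e in ev], dtype=np.int64)
    ev_arg = np.array(
        [e.size if e.kind == "resize" else float(e.dest) for e in ev],
        dtype=np.float64,
    )
    sizes0 = np.asarray(plan.initial_sizes, dtype=np.float64)
    return sizes0, ev_time, ev_kind, ev_pop, ev_arg


def _sample_pops(sample_sizes: Sequence[int]) -> np.ndarray:
    """Population label per gene copy (2 copies per diploid individual)."""
    return np.repeat(np.arange(len(sample_sizes)), 2 * np.asarray(sample_sizes))


@dataclass
class Genealogy:
    """A coalescent tree for one locus.

    Nodes ``0 .. n_leaves-1`` are leaves at time 0; internal nodes are
    numbered in coalescence-time order, the root last with ``parent = -1``.
    """

    parent: np.ndarray
    node_time: np.ndarray
    leaf_pops: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_pops)

    @property
    def tmrca(self) -> float:
        return float(self.node_time[-1])

    def validate(self) -> None:
        n = self.n_leaves
        assert self.parent.shape[0] == 2 * n - 1
        assert np.all(self.node_time[:n] == 0.0)
        internal = self.node_time[n:]
        assert np.all(np.diff(internal) >= 0)
        assert np.all(self.parent[:-1] > np.arange(2 * n - 2))
        kids = np.bincount(self.parent[:-1], minlength=2 * n - 1)
        assert np.all(kids[n:] == 2)

    def mrca_time(self, i: int, j: int) -> float:
        """Coalescence time of leaves ``i`` and ``j``."""
        anc = set()
        a = i
        while a != -1:
            anc.add(a)
            a = int(self.parent[a])
        a = j
        while a not in anc:
            a = int(self.parent[a])
        return float(self.node_time[a])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        return self.node_time[self.parent[:-1]] - self.node_time[:-1]


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, _MAX_SEED))


def simulate_genealogy(
    plan: EpochPlan, sample_sizes: Sequence[int], rng: np.random.Generator
) -> Genealogy:
    """Draw one genealogy of ``2 * sum(sample_sizes)`` gene copies."""
    sample_sizes = np.asarray(sample_sizes, dtype=np.int64)
    if np.any(sample_sizes < 1):
        raise ValueError("sample sizes must be >= 1")
    if len(sample_sizes) != plan.n_pops:
        raise ValueError("one sample size per population required")
    pops = _sample_pops(sample_sizes)
    parent, node_time = _sim_tree_kernel(_derive_seed(rng), pops, *_plan_arrays(plan))
    return Genealogy(parent=parent, node_time=node_time, leaf_pops=pops)


def mutate_gsm(
    tree: Genealogy,
    mu: float,
    p: float,
    rng: np.random.Generator,
    root_state: AlleleState = DEFAULT_ROOT_STATE,
    ladder_bounds=None,
) -> np.ndarray:
    """GSM repeat counts at the leaves (SNI rate 0)."""
    if not 0.0 <= p < 1.0:
        raise ValueError("geometric parameter p must satisfy 0 <= p < 1")
    lo, hi = ladder_bounds if ladder_bounds is not None else (1, 0)
    rep, _ = _mutate_kernel(
        _derive_seed(rng), tree.parent, tree.node_time, tree.n_leaves,
        float(mu), float(p), 0.0, root_state.repeat_count,
        root_state.indel_offset, lo, hi,
    )
    return rep


def apply_sni(
    tree: Genealogy,
    sni: float,
    rng: np.random.Generator,
    root_offset: int = 0,
) -> np.ndarray:
    """Single-nucleotide indel offsets at the leaves."""
    if sni < 0:
        raise ValueError("sni rate must be >= 0")
    _, off = _mutate_kernel(
        _derive_seed(rng), tree.parent, tree.node_time, tree.n_leaves,
        0.0, 0.0, float(sni), 0, root_offset, 1, 0,
    )
    return off


def simulate_dataset(
    scenario: DemographicScenario,
    draw: ParameterDraw,
    n_loci: int,
    sample_sizes: Sequence[int],
    rng: np.random.Generator,
    motif_lengths=None,
    ladder_bounds=None,
    gamma_rate_shape: float | None = None,
    pop_names=None,
) -> MicrosatDataset:
    """Simulate one multilocus dataset (one reference-table row's data).

    Loci are unlinked: each gets a fresh genealogy.  ``gamma_rate_shape``
    optionally draws per-locus mutation rates from a Gamma distribution
    with the given shape and mean ``draw.mu_mic`` (off by default: one
    shared rate).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    plan = build_epochs(scenario, draw)
    pops = _sample_pops(sample_sizes)
    if gamma_rate_shape is None:
        mu_per_locus = np.full(n_loci, draw.mu_mic, dtype=np.float64)
    else:
        mu_per_locus = draw.mu_mic * rng.gamma(
            gamma_rate_shape, 1.0 / gamma_rate_shape, size=n_loci
        )
    lo, hi = ladder_bounds if ladder_bounds is not None else (1, 0)
    reps, offs = _sim_dataset_kernel(
        _derive_seed(rng), pops, *_plan_arrays(plan), mu_per_locus,
        float(draw.p_mic), float(draw.sni_mic),
        DEFAULT_ROOT_STATE.repeat_count, lo, hi,
    )
    return MicrosatDataset.from_copy_arrays(
        reps, offs, sample_sizes,
        pop_names=pop_names or scenario.pop_labels,
        motif_lengths=motif_lengths,
    )
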