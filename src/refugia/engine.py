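"""Structured-coalescent simulation engine with pulse admixture.

Simulates genealogies backward in time under a three-population
:class:`~refugia.models.DemographicModel`: within a deme of current diploid
size ``Ne(t)`` each lineage pair coalesces at rate ``1/(2 Ne(t))`` per
generation; at a migration pulse (forward fraction ``p`` of ``dest`` deriving
from ``source``) each lineage currently in ``dest`` moves to ``source``
independently with probability ``p``; at a split all lineages of the derived
deme move to the ancestral deme; exponential growth ``g`` gives
``Ne(t) = Ne0 * exp(-g t)`` backward in time.

The continuous-time coalescent is used as the large-``Ne`` limit of the
discrete Moran/Wright-Fisher models (sample sizes here are orders of
magnitude below ``Ne``).  The hot loop is JIT-compiled with numba; all
randomness flows through explicit 31-bit seeds so that identical
``(model, params, seed)`` yield identical genealogies and datasets.

Monte-Carlo expected joint site-frequency spectra are computed by branch-
length accumulation: every branch adds its length to the cell indexed by the
numbers of sampled allele copies it subtends in each population, and cells
are normalised to sum to one over polymorphic configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .models import (
    ANCESTOR_AB,
    ANCESTOR_ABC,
    Bottleneck,
    DemographicModel,
    EvolutionaryConstants,
    Growth,
    ParameterSet,
    Pulse,
    SizeChange,
    Split,
    years_to_generations,
)

__all__ = [
    "SampleConfig",
    "Genealogy",
    "ExpectedSFS",
    "simulate_genealogy",
    "expected_sfs_mc",
    "simulate_snp_dataset",
    "simulate_site_matrix",
    "derive_seeds",
]

_DEME = {"A": 0, "B": 1, "C": 2, ANCESTOR_AB: 3, ANCESTOR_ABC: 4}
_NDEME = 5
# event kinds used by the kernel
_EV_RELABEL = 0
_EV_PULSE = 1
_EV_SETSIZE = 2
_EV_SCALESIZE = 3
_EV_PULSE2 = 4

MAX_TOTAL_SAMPLES = 60  # leaf masks are packed in a single int64


# ---------------------------------------------------------------------------
# Sample configuration and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample sizes (allele copies) per population."""

    n_A: int
    n_B: int
    n_C: int

    def __post_init__(self) -> None:
        ns = (self.n_A, self.n_B, self.n_C)
        if any(n < 0 for n in ns):
            raise ValueError("sample sizes must be non-negative")
        if self.total < 2:
            raise ValueError("need at least two allele copies in total")
        if self.total > MAX_TOTAL_SAMPLES:
            raise ValueError(f"total sample size capped at {MAX_TOTAL_SAMPLES}")

    @property
    def total(self) -> int:
        return self.n_A + self.n_B + self.n_C

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (self.n_A, self.n_B, self.n_C)

    def leaf_pops(self) -> np.ndarray:
        return np.repeat(np.arange(3, dtype=np.int64), np.array(self.sizes))

    def pop_masks(self) -> tuple[int, int, int]:
        """Bitmasks over leaf indices for populations A, B, C."""
        masks = []
        start = 0
        for n in self.sizes:
            m = 0
            for i in range(start, start + n):
                m |= 1 << i
            masks.append(m)
            start += n
        return tuple(masks)


@dataclass
class Genealogy:
    """A realised coalescent tree.

    Nodes ``0..n-1`` are leaves at time 0; internal nodes are appended in
    coalescence order; the root is the last node.  Times are in generations.
    ``node_mask[v]`` packs the leaves subtended by ``v`` as bits.
    """

    node_time: np.ndarray
    parent: np.ndarray
    node_mask: np.ndarray
    sample_config: SampleConfig

    @property
    def n_leaves(self) -> int:
        return (self.node_time.size + 1) // 2

    @property
    def root(self) -> int:
        return self.node_time.size - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above every non-root node."""
        v = np.arange(self.node_time.size - 1)
        return self.node_time[self.parent[v]] - self.node_time[v]

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def branch_configs(self) -> np.ndarray:
        """(n_nodes-1, 3) subtended allele-copy counts per branch."""
        mA, mB, mC = self.sample_config.pop_masks()
        m = self.node_mask[:-1]
        return np.stack([
            np.bitwise_count(m & mA),
            np.bitwise_count(m & mB),
            np.bitwise_count(m & mC),
        ], axis=1).astype(np.int64)


@dataclass
class ExpectedSFS:
    """Monte-Carlo expected joint SFS over polymorphic configurations.

    ``probs[iA, iB, iC]`` is the probability that a segregating site has the
    given joint derived-allele configuration; entries sum to one and the
    monomorphic corners are structurally zero.  ``se`` holds per-cell
    Monte-Carlo standard errors (replicate-level, delta approximation).
    """

    probs: np.ndarray
    se: np.ndarray | None
    n_reps: int
    sample_config: SampleConfig

    def __post_init__(self) -> None:
        if np.any(self.probs < 0):
            raise ValueError("negative SFS mass")


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _popcount(x):
    x = x - ((x >> 1) & 0x5555555555555555)
    x = (x & 0x3333333333333333) + ((x >> 2) & 0x3333333333333333)
    x = (x + (x >> 4)) & 0x0F0F0F0F0F0F0F0F
    return (x * 0x0101010101010101) >> 56


@njit(cache=True)
def _sim_one(pop0, ne0, gr0, ev_time, ev_kind, ev_a, ev_b, ev_c, ev_x,
             node_time, node_parent, node_mask, cur_node, cur_pop):
    """Simulate one genealogy; fills the node arrays, returns the TMRCA."""
    n = pop0.size
    ndem = ne0.size
    ne_ref = ne0.copy()
    g = gr0.copy()
    t_ref = np.zeros(ndem)
    for i in range(n):
        node_time[i] = 0.0
        node_mask[i] = np.int64(1) << i
        node_parent[i] = -1
        cur_node[i] = i
        cur_pop[i] = pop0[i]
    nact = n
    nxt = n
    t = 0.0
    ei = 0
    nev = ev_time.size
    cnt = np.zeros(ndem, np.int64)
    while nact > 1:
        for d in range(ndem):
            cnt[d] = 0
        for i in range(nact):
            cnt[cur_pop[i]] += 1
        tmin = np.inf
        dmin = -1
        for d in range(ndem):
            k = cnt[d]
            if k >= 2:
                pairs = 0.5 * k * (k - 1)
                u = np.random.random()
                e = -np.log(1.0 - u)
                if g[d] == 0.0:
                    w = e * 2.0 * ne_ref[d] / pairs
                else:
                    arg = 1.0 + g[d] * e * (2.0 * ne_ref[d] / pairs) \
                        * np.exp(-g[d] * (t - t_ref[d]))
                    if arg <= 0.0:
                        w = np.inf
                    else:
                        w = np.log(arg) / g[d]
                if t + w < tmin:
                    tmin = t + w
                    dmin = d
        if ei < nev and ev_time[ei] <= tmin:
            te = ev_time[ei]
            kind = ev_kind[ei]
            a = ev_a[ei]
            b = ev_b[ei]
            c = ev_c[ei]
            x = ev_x[ei]
            if kind == 0:  # relabel: deme a joins deme b
                for i in range(nact):
                    if cur_pop[i] == a:
                        cur_pop[i] = b
            elif kind == 1:  # pulse: dest deme b sends lineages to source a
                for i in range(nact):
                    if cur_pop[i] == b and np.random.random() < x:
                        cur_pop[i] = a
            elif kind == 4:  # pulse with split source (a or c, equal odds)
                for i in range(nact):
                    if cur_pop[i] == b and np.random.random() < x:
                        if np.random.random() < 0.5:
                            cur_pop[i] = a
                        else:
                            cur_pop[i] = c
            elif kind == 2:  # set size for older times
                ne_ref[a] = x
                g[a] = 0.0
                t_ref[a] = te
            elif kind == 3:  # scale size (bottleneck) for older times
                cur = ne_ref[a] * np.exp(-g[a] * (te - t_ref[a]))
                ne_ref[a] = cur * x
                g[a] = 0.0
                t_ref[a] = te
            t = te
            ei += 1
            continue
        if dmin < 0:
            return -1.0  # non-coalescing configuration (invalid model)
        k = cnt[dmin]
        r1 = np.random.randint(k)
        r2 = np.random.randint(k - 1)
        if r2 >= r1:
            r2 += 1
        i1 = -1
        i2 = -1
        idx = 0
        for i in range(nact):
            if cur_pop[i] == dmin:
                if idx == r1:
                    i1 = i
                if idx == r2:
                    i2 = i
                idx += 1
        nm = nxt
        nxt += 1
        node_time[nm] = tmin
        node_mask[nm] = node_mask[cur_node[i1]] | node_mask[cur_node[i2]]
        node_parent[nm] = -1
        node_parent[cur_node[i1]] = nm
        node_parent[cur_node[i2]] = nm
        cur_node[i1] = nm
        cur_node[i2] = cur_node[nact - 1]
        cur_pop[i2] = cur_pop[nact - 1]
        nact -= 1
        t = tmin
    return t


@njit(cache=True)
def _sim_one_seeded(seed, pop0, ne0, gr0, ev_time, ev_kind, ev_a, ev_b,
                    ev_c, ev_x, node_time, node_parent, node_mask,
                    cur_node, cur_pop):
    # numba keeps its own RNG state: seeding must happen inside the kernel
    np.random.seed(seed)
    return _sim_one(pop0, ne0, gr0, ev_time, ev_kind, ev_a, ev_b, ev_c,
                    ev_x, node_time, node_parent, node_mask,
                    cur_node, cur_pop)


@njit(cache=True)
def _esfs_batch(pop0, ne0, gr0, ev_time, ev_kind, ev_a, ev_b, ev_c, ev_x,
                seeds, mA, mB, mC, nB1, nC1,
                sfs_sum, sfs_sq, want_var, totals, tmrcas):
    """Accumulate branch lengths per joint configuration over replicates."""
    n = pop0.size
    nn = 2 * n - 1
    node_time = np.empty(nn)
    node_parent = np.empty(nn, np.int64)
    node_mask = np.empty(nn, np.int64)
    cur_node = np.empty(n, np.int64)
    cur_pop = np.empty(n, np.int64)
    tmp = np.zeros(sfs_sum.size)
    n_bad = 0
    for r in range(seeds.size):
        np.random.seed(seeds[r])
        tm = _sim_one(pop0, ne0, gr0, ev_time, ev_kind, ev_a, ev_b, ev_c,
                      ev_x, node_time, node_parent, node_mask,
                      cur_node, cur_pop)
        if tm < 0:
            n_bad += 1
            totals[r] = 0.0
            tmrcas[r] = np.nan
            continue
        if want_var:
            for j in range(tmp.size):
                tmp[j] = 0.0
        tot = 0.0
        for v in range(nn - 1):
            ln = node_time[node_parent[v]] - node_time[v]
            m = node_mask[v]
            iA = _popcount(m & mA)
            iB = _popcount(m & mB)
            iC = _popcount(m & mC)
            idx = (iA * nB1 + iB) * nC1 + iC
            if want_var:
                tmp[idx] += ln
            else:
                sfs_sum[idx] += ln
            tot += ln
        if want_var:
            for j in range(tmp.size):
                sfs_sum[j] += tmp[j]
                sfs_sq[j] += tmp[j] * tmp[j]
        totals[r] = tot
        tmrcas[r] = tm
    return n_bad


@njit(cache=True)
def _snp_batch(pop0, ne0, gr0, ev_time, ev_kind, ev_a, ev_b, ev_c, ev_x,
               seeds, out_masks):
    """One segregating site per locus: a branch drawn with probability
    proportional to its length determines the derived leaf set."""
    n = pop0.size
    nn = 2 * n - 1
    node_time = np.empty(nn)
    node_parent = np.empty(nn, np.int64)
    node_mask = np.empty(nn, np.int64)
    cur_node = np.empty(n, np.int64)
    cur_pop = np.empty(n, np.int64)
    for r in range(seeds.size):
        np.random.seed(seeds[r])
        tm = _sim_one(pop0, ne0, gr0, ev_time, ev_kind, ev_a, ev_b, ev_c,
                      ev_x, node_time, node_parent, node_mask,
                      cur_node, cur_pop)
        if tm < 0:
            out_masks[r] = 0
            continue
        tot = 0.0
        for v in range(nn - 1):
            tot += node_time[node_parent[v]] - node_time[v]
        u = np.random.random() * tot
        acc = 0.0
        chosen = np.int64(0)
        for v in range(nn - 1):
            acc += node_time[node_parent[v]] - node_time[v]
            if u < acc:
                chosen = node_mask[v]
                break
        out_masks[r] = chosen
    return 0


@njit(cache=True)
def _mutation_scatter(pop0, ne0, gr0, ev_time, ev_kind, ev_a, ev_b, ev_c,
                      ev_x, seed, mut_per_gen, out_masks):
    """Poisson mutations along branches (infinite-sites); returns the number
    of segregating sites written into ``out_masks``."""
    n = pop0.size
    nn = 2 * n - 1
    node_time = np.empty(nn)
    node_parent = np.empty(nn, np.int64)
    node_mask = np.empty(nn, np.int64)
    cur_node = np.empty(n, np.int64)
    cur_pop = np.empty(n, np.int64)
    np.random.seed(seed)
    tm = _sim_one(pop0, ne0, gr0, ev_time, ev_kind, ev_a, ev_b, ev_c,
                  ev_x, node_time, node_parent, node_mask, cur_node, cur_pop)
    if tm < 0:
        return -1
    ns = 0
    for v in range(nn - 1):
        ln = node_time[node_parent[v]] - node_time[v]
        k = np.random.poisson(ln * mut_per_gen)
        for _ in range(k):
            if ns < out_masks.size:
                out_masks[ns] = node_mask[v]
                ns += 1
    return ns


# ---------------------------------------------------------------------------
# Model -> kernel argument resolution
# ---------------------------------------------------------------------------

def _resolve_label(label: str, t: float, t_ab: float) -> list[int]:
    """Demes realising a population label at backward time ``t``."""
    if label == "A":
        return [0] if t < t_ab else [3]
    if label == "B":
        return [1] if t < t_ab else [3]
    if label == "C":
        return [2]
    if label == ANCESTOR_AB:
        return [3] if t >= t_ab else [0, 1]
    raise ValueError(f"unknown population label {label!r}")


def kernel_args(model: DemographicModel, params: ParameterSet,
                constants: EvolutionaryConstants,
                sample_config: SampleConfig):
    """Resolve a model + parameter set into the flat event arrays consumed
    by the simulation kernels (times in generations).

    Pulses with fraction exactly zero are dropped *before* the event arrays
    are built, so a zero-fraction pulse leaves the consumed random stream —
    and hence every simulated genealogy — exactly unchanged.
    """
    gt = constants.gen_time
    res = lambda ref: model.resolve(ref, params)  # noqa: E731

    t_ab = res(model.split_time_symbols()[0]) / gt
    t_abc = res(model.split_time_symbols()[1]) / gt
    if t_ab < 0 or t_abc < t_ab:
        raise ValueError("split times must satisfy 0 <= tdiv_AB <= tdiv_ABC")

    ne0 = np.empty(_NDEME)
    for lbl, d in (("A", 0), ("B", 1), ("C", 2)):
        ne0[d] = res(f"Ne_{lbl}") if f"Ne_{lbl}" in params else res(model.tie_ancestral_ne)
    tie = res(model.tie_ancestral_ne)
    ne0[3] = res("Ne_AB") if "Ne_AB" in params else tie
    ne0[4] = res("Ne_ABC") if "Ne_ABC" in params else tie
    if np.any(ne0 <= 0):
        raise ValueError("effective sizes must be positive")

    gr0 = np.zeros(_NDEME)
    # (time, priority, kind, a, b, c, x); pulses fire before size events,
    # size events before splits, at coinciding times
    raw: list[tuple] = [
        (t_ab, 2, _EV_RELABEL, 0, 3, -1, 0.0),
        (t_ab, 2, _EV_RELABEL, 1, 3, -1, 0.0),
        (t_abc, 2, _EV_RELABEL, 3, 4, -1, 0.0),
        (t_abc, 2, _EV_RELABEL, 2, 4, -1, 0.0),
    ]
    for ev in model.events:
        if isinstance(ev, Split):
            continue  # handled via split_time_symbols above
        if isinstance(ev, Growth):
            gr0[_DEME[ev.pop]] = res(ev.rate)
            continue
        t = res(ev.time) / gt
        if isinstance(ev, Pulse):
            p = res(ev.fraction)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"pulse fraction {p:g} outside [0, 1]")
            if p == 0.0:
                continue
            if t > t_abc:
                raise ValueError(
                    f"pulse {ev.source}->{ev.dest} at {t * gt:g} y postdates "
                    "the root divergence")
            src = _resolve_label(ev.source, t, t_ab)
            dst = _resolve_label(ev.dest, t, t_ab)
            if set(src) == set(dst):
                continue  # pulse at the split instant: vacuous
            if set(src) & set(dst):
                raise ValueError("pulse source and dest coincide")
            for d in dst:
                if len(src) == 1:
                    raw.append((t, 0, _EV_PULSE, src[0], d, -1, p))
                else:
                    raw.append((t, 0, _EV_PULSE2, src[0], d, src[1], p))
        elif isinstance(ev, SizeChange):
            raw.append((t, 1, _EV_SETSIZE, _DEME[ev.pop], -1, -1, res(ev.new_ne)))
        elif isinstance(ev, Bottleneck):
            s = res(ev.strength)
            if not (0.0 < s <= 1.0):
                raise ValueError(f"bottleneck strength {s:g} outside (0, 1]")
            raw.append((t, 1, _EV_SCALESIZE, _DEME[ev.pop], -1, -1, s))
        else:
            raise TypeError(f"unknown event {ev!r}")

    raw.sort(key=lambda r: (r[0], r[1]))
    ev_time = np.array([r[0] for r in raw])
    ev_kind = np.array([r[2] for r in raw], dtype=np.int64)
    ev_a = np.array([r[3] for r in raw], dtype=np.int64)
    ev_b = np.array([r[4] for r in raw], dtype=np.int64)
    ev_c = np.array([r[5] for r in raw], dtype=np.int64)
    ev_x = np.array([r[6] for r in raw])
    pop0 = sample_config.leaf_pops()
    return pop0, ne0, gr0, ev_time, ev_kind, ev_a, ev_b, ev_c, ev_x


# ---------------------------------------------------------------------------
# Seeds
# ---------------------------------------------------------------------------

def _as_seed(rng) -> int:
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(2 ** 31))
    if rng is None:
        raise ValueError("an explicit seed or Generator is required")
    return int(rng) % (2 ** 31)


def derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic, well-mixed 31-bit seed stream for replicate kernels."""
    ss = np.random.SeedSequence(int(base_seed) % (2 ** 31))
    return (ss.generate_state(n, dtype=np.uint32) % (2 ** 31)).astype(np.int64)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def simulate_genealogy(model: DemographicModel, params: ParameterSet,
                       sample_config: SampleConfig, rng,
                       constants: EvolutionaryConstants = EvolutionaryConstants(),
                       ) -> Genealogy:
    """Simulate a single genealogy (times in generations)."""
    args = kernel_args(model, params, constants, sample_config)
    n = sample_config.total
    nn = 2 * n - 1
    node_time = np.empty(nn)
    node_parent = np.empty(nn, np.int64)
    node_mask = np.empty(nn, np.int64)
    seed = _as_seed(rng)
    seeds = derive_seeds(seed, 1)
    cur_node = np.empty(n, np.int64)
    cur_pop = np.empty(n, np.int64)
    tm = _sim_one_seeded(int(seeds[0]), *args, node_time, node_parent,
                         node_mask, cur_node, cur_pop)
    if tm < 0:
        raise RuntimeError("non-coalescing configuration (internal error)")
    return Genealogy(node_time=node_time, parent=node_parent,
                     node_mask=node_mask, sample_config=sample_config)


def _mask_args(sc: SampleConfig):
    mA, mB, mC = sc.pop_masks()
    return (np.int64(mA), np.int64(mB), np.int64(mC),
            np.int64(sc.n_B + 1), np.int64(sc.n_C + 1))


def expected_sfs_mc(model: DemographicModel, params: ParameterSet,
                    sample_config: SampleConfig, n_reps: int, rng,
                    constants: EvolutionaryConstants = EvolutionaryConstants(),
                    track_se: bool = True) -> ExpectedSFS:
    """Monte-Carlo expected joint SFS (normalised over polymorphic cells)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    args = kernel_args(model, params, constants, sample_config)
    seeds = derive_seeds(_as_seed(rng), n_reps)
    shape = (sample_config.n_A + 1, sample_config.n_B + 1,
             sample_config.n_C + 1)
    sfs_sum = np.zeros(int(np.prod(shape)))
    sfs_sq = np.zeros_like(sfs_sum)
    totals = np.empty(n_reps)
    tmrcas = np.empty(n_reps)
    n_bad = _esfs_batch(*args, seeds, *_mask_args(sample_config),
                        sfs_sum, sfs_sq, track_se, totals, tmrcas)
    if n_bad:
        raise RuntimeError(f"{n_bad} replicates failed to coalesce")
    grand = sfs_sum.sum()
    if grand <= 0:
        raise RuntimeError("zero total branch length")
    probs = (sfs_sum / grand).reshape(shape)
    se = None
    if track_se:
        mean_c = sfs_sum / n_reps
        var_c = np.maximum(sfs_sq / n_reps - mean_c ** 2, 0.0)
        se = (np.sqrt(var_c / n_reps) / (grand / n_reps)).reshape(shape)
    return ExpectedSFS(probs=probs, se=se, n_reps=n_reps,
                       sample_config=sample_config)


def sfs_kernel_probs(args, seeds, sample_config: SampleConfig) -> np.ndarray:
    """Low-overhead expected-SFS evaluation for resolved kernel args
    (used by the likelihood objective under common random numbers)."""
    shape = (sample_config.n_A + 1, sample_config.n_B + 1,
             sample_config.n_C + 1)
    sfs_sum = np.zeros(int(np.prod(shape)))
    sfs_sq = np.empty(0)
    totals = np.empty(seeds.size)
    tmrcas = np.empty(seeds.size)
    n_bad = _esfs_batch(*args, seeds, *_mask_args(sample_config),
                        sfs_sum, np.zeros(1), False, totals, tmrcas)
    if n_bad:
        raise RuntimeError(f"{n_bad} replicates failed to coalesce")
    return (sfs_sum / sfs_sum.sum()).reshape(shape)


def simulate_snp_masks(model: DemographicModel, params: ParameterSet,
                       n_loci: int, sample_config: SampleConfig, rng,
                       constants: EvolutionaryConstants = EvolutionaryConstants(),
                       ) -> np.ndarray:
    """Derived-allele leaf masks for one conditioned SNP per locus."""
    args = kernel_args(model, params, constants, sample_config)
    seeds = derive_seeds(_as_seed(rng), n_loci)
    masks = np.empty(n_loci, np.int64)
    _snp_batch(*args, seeds, masks)
    return masks


def simulate_snp_dataset(model: DemographicModel, params: ParameterSet,
                         n_loci: int, sample_config: SampleConfig,
                         missing_rate: float, rng,
                         constants: EvolutionaryConstants = EvolutionaryConstants(),
                         locus_prefix: str = "uce"):
    """Simulate diploid genotypes: one biallelic SNP per unlinked locus.

    Allele copies are paired into diploids within each population (haploid
    sample sizes must be even); genotype calls are masked independently at
    ``missing_rate``; the ancestral state is known (REF allele).
    Returns a :class:`refugia.sfs.GenotypeTable`.
    """
    from .sfs import GenotypeTable

    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if any(n % 2 for n in sample_config.sizes):
        raise ValueError("diploid output needs even haploid counts per population")

    seed = _as_seed(rng)
    masks = simulate_snp_masks(model, params, n_loci, sample_config,
                               seed, constants)
    n = sample_config.total
    leaf_idx = np.arange(n)
    # haplotype matrix: (n_loci, n) 0/1
    hap = ((masks[:, None] >> leaf_idx[None, :]) & 1).astype(np.int8)
    geno = hap.reshape(n_loci, n // 2, 2)

    post = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    if missing_rate > 0:
        miss = post.random((n_loci, n // 2)) < missing_rate
        geno = geno.copy()
        geno[miss] = -1

    pops = np.repeat(np.array(["A", "B", "C"]),
                     np.array(sample_config.sizes) // 2)
    counts = {"A": 0, "B": 0, "C": 0}
    samples = []
    for p in pops:
        counts[p] += 1
        samples.append(f"{p}{counts[p]:02d}")

    width = max(4, len(str(n_loci)))
    loci = np.array([f"{locus_prefix}-{i + 1:0{width}d}" for i in range(n_loci)])
    pos = post.integers(100, 900, size=n_loci)
    nucs = np.array(list("ACGT"))
    ref_i = post.integers(0, 4, size=n_loci)
    alt_i = (ref_i + post.integers(1, 4, size=n_loci)) % 4
    return GenotypeTable(
        genotypes=geno,
        site_locus=loci,
        site_pos=pos.astype(np.int64),
        ref=nucs[ref_i],
        alt=nucs[alt_i],
        ancestral_known=np.ones(n_loci, dtype=bool),
        samples=samples,
        sample_pop=pops.copy(),
    )


# ---------------------------------------------------------------------------
# Single-population sequence simulation (for neutrality statistics)
# ---------------------------------------------------------------------------

def _single_pop_args(ne: float, n: int, growth: float = 0.0):
    pop0 = np.zeros(n, np.int64)
    ne0 = np.full(_NDEME, ne)
    gr0 = np.zeros(_NDEME)
    gr0[0] = growth
    empty_t = np.empty(0)
    empty_i = np.empty(0, np.int64)
    return pop0, ne0, gr0, empty_t, empty_i, empty_i, empty_i, empty_i, empty_t


def simulate_site_matrix(ne: float, n: int, mut_per_gen: float, rng,
                         growth: float = 0.0, min_s: int = 0,
                         max_sites: int = 4096) -> np.ndarray:
    """Infinite-sites 0/1 haplotype matrix (n sequences x S sites) for a
    single population of diploid size ``ne``; ``mut_per_gen`` is the total
    per-locus mutation rate per generation.  With ``min_s > 0`` genealogies
    are redrawn until at least that many segregating sites arise."""
    args = _single_pop_args(ne, n, growth)
    seed = _as_seed(rng)
    out = np.empty(max_sites, np.int64)
    for attempt in range(10000):
        s = int(_mutation_scatter(*args, int(derive_seeds(seed + attempt, 1)[0]),
                                  mut_per_gen, out))
        if s < 0:
            raise RuntimeError("simulation failed")
        if s >= min_s:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not reach the requested number of sites")
    masks = out[:s]
    leaf = np.arange(n)
    return ((masks[:, None] >> leaf[None, :]) & 1).astype(np.int8).T
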