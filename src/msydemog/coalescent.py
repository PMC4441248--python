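"""Haploid coalescent simulation with finite-sites mutation.

The simulator generates single-population, single-locus genealogies under a
:class:`~msydemog.demography.PiecewiseDemography` by time rescaling: with k
lineages alive at time t the pair-coalescence intensity is
k(k-1)/2 * 1/N(t), and waiting times are drawn by inverting the cumulative
intensity in closed form within each constant or exponential epoch, carrying
the residual exponential deviate across epoch boundaries.

Mutations follow a finite-sites 4-state model with no transition/transversion
bias: the total count is Poisson(mu * L * total branch length), each mutation
lands on a branch with probability proportional to its length and at a
position uniform on [1, L], and each hit replaces the current base by one of
the other three bases with equal probability.  Repeat hits at one position
are applied in age order along lineages, so a site can revert or become
triallelic; the derived site frequency spectrum keeps biallelic sites only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import Epoch, ModelSpec, PiecewiseDemography, build_demography, sample_prior

__all__ = [
    "Genealogy",
    "SiteTable",
    "SFSVector",
    "coalescent_sim",
    "drop_mutations",
    "compute_derived_sfs",
    "simulate_batch",
    "write_reference_table",
    "read_reference_table",
]

BASES = "ACGT"


@dataclass(frozen=True)
class Genealogy:
    """A realised coalescent tree for ``n_tips`` haploid samples.

    Nodes 0..n_tips-1 are tips at time 0; internal nodes follow in
    coalescence order, so node 2*n_tips-2 is the root.  ``parent[i]`` is -1
    for the root, ``time`` is in generations before present.
    """

    n_tips: int
    parent: np.ndarray  # (2n-1,) int
    time: np.ndarray  # (2n-1,) float

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("a genealogy requires n_tips >= 2")
        if len(self.parent) != 2 * self.n_tips - 1:
            raise ValueError("parent array has wrong length")

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length in generations of the branch above each non-root node."""
        nodes = np.arange(self.n_nodes - 1)
        return self.time[self.parent[nodes]] - self.time[nodes]

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tips_below(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips) matrix: tips descending from each node."""
        below = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        below[np.arange(self.n_tips), np.arange(self.n_tips)] = True
        for node in range(self.n_nodes - 1):  # children precede parents by construction
            below[self.parent[node]] |= below[node]
        return below


def _epoch_intensity(ep: Epoch, s: float, t: float) -> float:
    """Integral of 1/N over [s, t] within epoch ``ep``."""
    if ep.constant:
        return (t - s) / ep.size_recent
    r = ep.rate
    return (math.exp(-r * (s - ep.t_recent)) - math.exp(-r * (t - ep.t_recent))) / (
        ep.size_recent * r
    )


def _epoch_invert(ep: Epoch, s: float, target: float) -> float:
    """Time t > s in epoch ``ep`` with integral of 1/N over [s, t] = target."""
    if ep.constant:
        return s + target * ep.size_recent
    r = ep.rate
    arg = math.exp(-r * (s - ep.t_recent)) - target * ep.size_recent * r
    return ep.t_recent - math.log(arg) / r


def _next_coalescence(
    demo: PiecewiseDemography, t0: float, k: int, rng: np.random.Generator
) -> float:
    """Time of the next coalescence among k lineages, starting from t0."""
    need = rng.exponential() / (k * (k - 1) / 2.0)
    s = t0
    for ep in demo.epochs:
        if ep.t_ancient <= s:
            continue
        lo = max(s, ep.t_recent)
        if math.isinf(ep.t_ancient):
            return _epoch_invert(ep, lo, need)
        cap = _epoch_intensity(ep, lo, ep.t_ancient)
        if need <= cap:
            return _epoch_invert(ep, lo, need)
        need -= cap
    raise RuntimeError("unreachable: last epoch extends to infinity")


def coalescent_sim(
    demo: PiecewiseDemography, n: int, rng: np.random.Generator | int
) -> Genealogy:
    """Simulate one single-population coalescent genealogy of ``n`` tips."""
    if n < 2:
        raise ValueError("coalescent simulation requires n >= 2 tips")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes, dtype=float)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t = _next_coalescence(demo, t, k, rng)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)]
        active.append(nxt)
        nxt += 1
    return Genealogy(n_tips=n, parent=parent, time=time)


@dataclass(frozen=True)
class SiteTable:
    """Polymorphic sites of one simulated replicate.

    ``alleles`` is an (n_sites, n_tips) matrix of base codes (0=A, 1=C,
    2=G, 3=T); ``ancestral`` holds the ancestral base code per site.  Only
    sites where at least one tip differs from the ancestral base are kept,
    and positions are unique (1-based within the locus).
    """

    n_tips: int
    positions: np.ndarray  # (n_sites,) int, 1-based
    ancestral: np.ndarray  # (n_sites,) uint8
    alleles: np.ndarray  # (n_sites, n_tips) uint8

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SFSVector:
    """Derived site frequency spectrum: counts xi_1 .. xi_{n-1}."""

    n: int
    counts: np.ndarray  # (n-1,) int

    def __post_init__(self) -> None:
        if len(self.counts) != self.n - 1:
            raise ValueError("SFS must have n-1 categories")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("SFS counts must be non-negative")

    @property
    def total(self) -> int:
        return int(np.sum(self.counts))


def drop_mutations(
    g: Genealogy, mu: float, L: int, rng: np.random.Generator | int
) -> SiteTable:
    """Drop finite-sites mutations on a genealogy and return its site table."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    lengths = g.branch_lengths()
    total = lengths.sum()
    n_mut = rng.poisson(mu * L * total)
    if n_mut == 0:
        return SiteTable(
            n_tips=g.n_tips,
            positions=np.empty(0, dtype=np.int64),
            ancestral=np.empty(0, dtype=np.uint8),
            alleles=np.empty((0, g.n_tips), dtype=np.uint8),
        )

    cum = np.cumsum(lengths)
    branch = np.searchsorted(cum, rng.random(n_mut) * total, side="right")
    branch = np.minimum(branch, len(lengths) - 1)
    pos = rng.integers(1, L + 1, size=n_mut)
    # age of each mutation, used to order repeat hits along lineages
    age = g.time[branch] + rng.random(n_mut) * lengths[branch]
    step = rng.integers(1, 4, size=n_mut).astype(np.uint8)  # +1..+3 mod 4

    below = g.tips_below()
    uniq_pos, first_idx, counts = np.unique(pos, return_index=True, return_counts=True)
    anc = rng.integers(0, 4, size=len(uniq_pos)).astype(np.uint8)

    single = counts == 1
    alleles = np.repeat(anc[:, None], g.n_tips, axis=1)
    if single.any():
        idx = first_idx[single]
        mask = below[branch[idx]]
        derived = ((anc[single] + step[idx]) % 4).astype(np.uint8)
        rows = np.where(single)[0]
        alleles[rows] = np.where(mask, derived[:, None], anc[single][:, None])

    # repeat hits: resolve by descending the tree applying hits oldest-first
    multi_rows = np.where(~single)[0]
    if len(multi_rows):
        order = np.argsort(g.time)[::-1]  # parents before children
        for row in multi_rows:
            p = uniq_pos[row]
            hits = np.where(pos == p)[0]
            base = np.empty(g.n_nodes, dtype=np.uint8)
            base[g.root] = anc[row]
            hit_nodes = branch[hits]
            for node in order:
                if node == g.root:
                    continue
                b = base[g.parent[node]]
                here = hits[hit_nodes == node]
                for h in here[np.argsort(-age[here])]:
                    b = (b + step[h]) % 4
                base[node] = b
            alleles[row] = base[: g.n_tips]

    keep = (alleles != anc[:, None]).any(axis=1)
    return SiteTable(
        n_tips=g.n_tips,
        positions=uniq_pos[keep].astype(np.int64),
        ancestral=anc[keep],
        alleles=alleles[keep],
    )


def compute_derived_sfs(sites: SiteTable, n: int | None = None) -> SFSVector:
    """Derived SFS over biallelic sites.

    A site contributes to category i when exactly one non-ancestral base is
    present and it is carried by i tips, 0 < i < n.  Fixed-derived and
    triallelic (or worse) sites are excluded.
    """
    n = sites.n_tips if n is None else n
    if n != sites.n_tips:
        raise ValueError("tip count mismatch")
    counts = np.zeros(n - 1, dtype=np.int64)
    if sites.n_sites == 0:
        return SFSVector(n=n, counts=counts)
    diff = sites.alleles != sites.ancestral[:, None]
    n_derived = diff.sum(axis=1)
    lo = np.where(diff, sites.alleles, 4).min(axis=1)
    hi = np.where(diff, sites.alleles.astype(np.int16), -1).max(axis=1)
    biallelic = (n_derived > 0) & (n_derived < n) & (lo == hi)
    counts = np.bincount(n_derived[biallelic], minlength=n)[1:n]
    return SFSVector(n=n, counts=counts.astype(np.int64))


def simulate_batch(
    spec: ModelSpec,
    n_sims: int,
    n: int,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Simulate a reference table: prior draw -> demography -> tree -> SFS.

    Returns a DataFrame with columns ``model``, the model's parameters,
    ``mu``, and ``xi_1`` .. ``xi_{n-1}``; one row per simulation,
    reproducible given the seed (each replicate uses its own spawned
    substream).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_sims)
    pnames = list(spec.parameter_names)
    rows = np.empty((n_sims, len(pnames) + 1 + n - 1), dtype=float)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = sample_prior(spec, rng)
        demo = build_demography(params)
        g = coalescent_sim(demo, n, rng)
        sites = drop_mutations(g, params.mu, spec.locus_length_bp, rng)
        sfs = compute_derived_sfs(sites)
        rows[i, : len(pnames)] = [params.values[p] for p in pnames]
        rows[i, len(pnames)] = params.mu
        rows[i, len(pnames) + 1 :] = sfs.counts
    cols = pnames + ["mu"] + [f"xi_{i}" for i in range(1, n)]
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "model", spec.model_id)
    return df


def write_reference_table(table: pd.DataFrame, path: str) -> None:
    """Write a reference table as (optionally gzipped) TSV with a header."""
    table.to_csv(path, sep="\t", index=False)


def read_reference_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
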