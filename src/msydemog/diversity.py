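"""Intrapopulation diversity statistics and geographic cline tests.

Implements the classical summaries for haploid resequencing samples: number
of segregating sites S, per-individual singleton counts (a singleton being a
variant carried by exactly one individual within the population), mean
pairwise differences pi, Tajima's D, and Fu's FS based on the Ewens sampling
formula; plus coalescent-null significance for D and FS and Pearson
correlation of diversity with latitude/longitude.

Fu's FS uses S' = P(K >= k_obs | theta = pi) under the Ewens sampling
formula, with unsigned Stirling numbers of the first kind computed by a
log-space recurrence (naive products overflow well below n = 20), and
FS = ln(S' / (1 - S')).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

from .coalescent import Genealogy, SiteTable, coalescent_sim
from .demography import Epoch, PiecewiseDemography

__all__ = [
    "PopulationSample",
    "sample_from_sites",
    "segregating_sites",
    "singleton_summary",
    "mean_pairwise_differences",
    "distinct_haplotypes",
    "tajimas_d",
    "log_stirling_first",
    "ewens_log_pmf",
    "fus_fs",
    "diversity_significance",
    "correlation_test",
    "diversity_table",
]

MISSING = -1


@dataclass(frozen=True)
class PopulationSample:
    """Haploid calls for one population: (n_sites, n_individuals) matrix.

    Allele codes are arbitrary non-negative integers; ``MISSING`` (-1)
    marks a missing call.  All individuals share the same site set.
    """

    pop_id: str
    individuals: tuple[str, ...]
    positions: np.ndarray  # (n_sites,)
    calls: np.ndarray  # (n_sites, n_individuals) int

    def __post_init__(self) -> None:
        if self.calls.ndim != 2 or self.calls.shape[1] != len(self.individuals):
            raise ValueError("calls must be (n_sites, n_individuals)")
        if len(self.positions) != self.calls.shape[0]:
            raise ValueError("positions length must match site count")

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]


def sample_from_sites(sites: SiteTable, pop_id: str = "sim") -> PopulationSample:
    """View a simulated SiteTable as a PopulationSample."""
    return PopulationSample(
        pop_id=pop_id,
        individuals=tuple(f"t{i}" for i in range(sites.n_tips)),
        positions=sites.positions.copy(),
        calls=sites.alleles.astype(np.int64).copy(),
    )


def _check_nonempty(sample: PopulationSample) -> None:
    if sample.n_sites and not (sample.calls != MISSING).any():
        raise ValueError("all calls are missing")


def segregating_sites(sample: PopulationSample) -> int:
    """Number of sites with >= 2 distinct non-missing alleles."""
    _check_nonempty(sample)
    if sample.n_sites == 0:
        return 0
    valid = sample.calls != MISSING
    lo = np.where(valid, sample.calls, np.iinfo(np.int64).max).min(axis=1)
    hi = np.where(valid, sample.calls, MISSING).max(axis=1)
    return int(np.sum((hi != MISSING) & (lo != hi)))


def singleton_summary(sample: PopulationSample) -> dict:
    """Per-individual singleton counts with their median and sample s.d.

    A site is a singleton site when exactly one individual carries a
    non-modal (minor) allele among the non-missing calls; that individual
    is the carrier.  Median and s.d. are taken across individuals.
    """
    if sample.n < 1:
        raise ValueError("need at least one individual")
    counts = np.zeros(sample.n, dtype=np.int64)
    for row in sample.calls:
        obs = row[row != MISSING]
        if len(obs) < 2:
            continue
        alleles, ac = np.unique(obs, return_counts=True)
        modal = alleles[np.argmax(ac)]
        minor_carriers = np.where((row != MISSING) & (row != modal))[0]
        if len(minor_carriers) == 1:
            counts[minor_carriers[0]] += 1
    sd = float(np.std(counts, ddof=1)) if sample.n > 1 else 0.0
    return {
        "per_individual_counts": counts,
        "median": float(np.median(counts)),
        "sd": sd,
    }


def mean_pairwise_differences(sample: PopulationSample) -> float:
    """Mean number of differing sites over all haplotype pairs (pi).

    Missing calls are handled pairwise-complete: a site counts for a pair
    only when both calls are present; no rescaling is applied.
    """
    n = sample.n
    if n < 2:
        raise ValueError("pi requires n >= 2")
    total = 0.0
    for i in range(n - 1):
        a = sample.calls[:, i]
        rest = sample.calls[:, i + 1 :]
        ok = (a[:, None] != MISSING) & (rest != MISSING)
        total += np.sum((a[:, None] != rest) & ok)
    return total / (n * (n - 1) / 2)


def distinct_haplotypes(sample: PopulationSample) -> int:
    """Number of distinct haplotypes (missing treated as its own state)."""
    if sample.n_sites == 0:
        return 1
    return len({tuple(col) for col in sample.calls.T})


_TAJIMA_CACHE: dict[int, tuple[float, float]] = {}


def _tajima_norm(n: int) -> tuple[float, float]:
    """Tajima (1989) normalising constants e1, e2 for sample size n."""
    if n in _TAJIMA_CACHE:
        return _TAJIMA_CACHE[n]
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    _TAJIMA_CACHE[n] = (e1, e2)
    return e1, e2


def tajimas_d(S: int, pi: float, n: int) -> float:
    """Tajima's D from segregating sites, mean pairwise differences and n.

    Returns NaN (not computable) when S = 0.
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return math.nan
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    e1, e2 = _tajima_norm(n)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n.

    Uses the recurrence |s(n+1, k)| = n |s(n, k)| + |s(n, k-1)| in log
    space (log-sum-exp), stable far beyond the overflow point of integer
    or float products.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    row = np.full(n + 1, -np.inf)
    row[1] = 0.0  # |s(1,1)| = 1
    for m in range(1, n):
        new = np.full(n + 1, -np.inf)
        new[1:] = np.logaddexp(math.log(m) + row[1:], row[:-1])
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 1..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = log_stirling_first(n)[1:]
    k = np.arange(1, n + 1)
    log_denom = float(np.sum(np.log(theta + np.arange(n))))
    return ls + k * math.log(theta) - log_denom


def fus_fs(pi: float, n: int, k_obs: int) -> float:
    """Fu's FS statistic.

    ``pi`` plays the role of theta; ``k_obs`` is the observed number of
    distinct haplotypes.  Returns NaN when not computable (pi <= 0, or the
    tail probability S' equals 1, i.e. k_obs = 1).
    """
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must be in [1, n]")
    if n < 2:
        raise ValueError("n must be >= 2")
    if pi <= 0:
        return math.nan
    logp = ewens_log_pmf(n, pi)
    log_sp = float(logsumexp(logp[k_obs - 1 :]))
    log_sp = min(log_sp, 0.0)
    if log_sp == 0.0:
        return math.nan
    # FS = ln(S'/(1-S')) = log_sp - log(1 - exp(log_sp))
    return log_sp - math.log(-math.expm1(log_sp))


def _fixed_s_null(
    n: int, S: int, n_sims: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated (D, FS) under a constant-size coalescent conditioned on S.

    Conditioning on the observed number of segregating sites makes the null
    free of theta: S infinite-sites mutations are placed multinomially on
    the genealogy's branches in proportion to branch length.
    """
    demo = PiecewiseDemography((Epoch(0.0, math.inf, 1.0, 1.0),))
    d_vals = np.empty(n_sims)
    fs_vals = np.empty(n_sims)
    npairs = n * (n - 1) / 2
    for s in range(n_sims):
        g = coalescent_sim(demo, n, rng)
        lengths = g.branch_lengths()
        below = g.tips_below()[: g.n_nodes - 1]
        n_below = below.sum(axis=1)
        hits = rng.multinomial(S, lengths / lengths.sum())
        pi = float(np.sum(hits * n_below * (n - n_below)) / npairs)
        d_vals[s] = tajimas_d(S, pi, n)
        # haplotype of a tip = set of mutated branches above it
        profile = below[hits > 0]
        cols = {tuple(profile[:, t]) for t in range(n)}
        fs_vals[s] = fus_fs(pi, n, len(cols))
    return d_vals, fs_vals


def diversity_significance(
    sample: PopulationSample, n_sims: int, rng: np.random.Generator | int
) -> dict:
    """Observed D and FS with coalescent-null p-values.

    p(D) is the fraction of null simulations with D <= observed, and
    likewise for FS; the null is a constant-size neutral coalescent
    conditioned on the observed S.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    S = segregating_sites(sample)
    pi = mean_pairwise_differences(sample)
    k = distinct_haplotypes(sample)
    d_obs = tajimas_d(S, pi, sample.n)
    fs_obs = fus_fs(pi, sample.n, k)
    if math.isnan(d_obs):
        raise ValueError("D not computable (S = 0)")
    d_null, fs_null = _fixed_s_null(sample.n, S, n_sims, rng)
    p_d = float(np.mean(d_null <= d_obs))
    with np.errstate(invalid="ignore"):
        ok = ~np.isnan(fs_null)
    p_fs = float(np.mean(fs_null[ok] <= fs_obs)) if (ok.any() and not math.isnan(fs_obs)) else math.nan
    return {
        "S": S,
        "pi": pi,
        "k": k,
        "D": d_obs,
        "p_D": p_d,
        "FS": fs_obs,
        "p_FS": p_fs,
    }


def correlation_test(values, coordinate) -> dict:
    """Pearson correlation of a per-population statistic with a coordinate.

    Returns r, the t statistic t = r * sqrt((m-2)/(1-r^2)), and the
    two-sided p-value from the t distribution with m-2 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(coordinate, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, _ = sps.pearsonr(x, y)
    m = len(x)
    if abs(r) >= 1.0:
        return {"r": float(r), "t": math.inf * np.sign(r), "p": 0.0}
    t = r * math.sqrt((m - 2) / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), df=m - 2)
    return {"r": float(r), "t": float(t), "p": float(p)}


def diversity_table(
    samples: list[PopulationSample], n_sims: int, seed: int
) -> pd.DataFrame:
    """Per-population diversity summary (one row per population).

    Columns: pop, N, S, median_singletons, sd_singletons, D, p_D, FS, p_FS.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for sample, child in zip(samples, ss.spawn(len(samples))):
        sing = singleton_summary(sample)
        sig = diversity_significance(sample, n_sims, np.random.default_rng(child))
        rows.append(
            {
                "pop": sample.pop_id,
                "N": sample.n,
                "S": sig["S"],
                "median_singletons": sing["median"],
                "sd_singletons": sing["sd"],
                "D": sig["D"],
                "p_D": sig["p_D"],
                "FS": sig["FS"],
                "p_FS": sig["p_FS"],
            }
        )
    return pd.DataFrame(rows)
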