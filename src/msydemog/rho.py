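"""Rho-statistic TMRCA dating on mutation-count trees.

The rho statistic of a clade is the mean number of mutations on the path
from the clade's root node to each of its tips; multiplied by a scaled rate
in years per mutation it dates the clade.  The standard deviation follows
the branch-weight estimator sd^2 = sum_b (n_b / n)^2 * l_b, where n_b is
the number of tips below branch b and l_b its mutation count.

Input trees are Newick with branch lengths interpreted as mutation counts
(e.g. branch lengths of a maximum-parsimony tree).  Non-integer counts are
accepted with a warning, since consensus trees may carry averaged counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from io import StringIO

import dendropy
import pandas as pd

__all__ = [
    "MutationTree",
    "parse_mutation_tree",
    "ScaledRate",
    "scaled_rate",
    "rho",
    "tmrca_from_rho",
    "RhoEstimate",
    "round_to_ten",
    "haplogroup_frequencies",
    "clade_table",
]


@dataclass(frozen=True)
class MutationTree:
    """Rooted tree whose branch lengths are mutation counts."""

    tree: dendropy.Tree

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def find_clade(self, label: str) -> dendropy.Node:
        """Locate an internal node by label or a tip by taxon name."""
        for node in self.tree:
            if node.label == label or (
                node.taxon is not None and node.taxon.label == label
            ):
                return node
        raise KeyError(f"no node labelled {label!r}")

    def mrca(self, tip_labels: list[str]) -> dendropy.Node:
        return self.tree.mrca(taxon_labels=tip_labels)


def parse_mutation_tree(newick: str) -> MutationTree:
    """Parse a Newick string whose branch lengths are mutation counts.

    A missing branch length anywhere below the root is an error (it would
    silently zero a mutation count); negative counts are rejected.
    """
    tree = dendropy.Tree.get(
        file=StringIO(newick),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = True  # counts are directional: root-to-tip
    non_integer = False
    for node in tree:
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            name = node.taxon.label if node.taxon else (node.label or "<internal>")
            raise ValueError(f"missing branch length above node {name!r}")
        if node.edge.length < 0:
            raise ValueError("negative mutation count")
        if float(node.edge.length) != int(node.edge.length):
            non_integer = True
    if non_integer:
        warnings.warn(
            "non-integer mutation counts found (consensus-tree averages?)",
            stacklevel=2,
        )
    return MutationTree(tree=tree)


@dataclass(frozen=True)
class ScaledRate:
    """Years per mutation with its (low, high) range from the rate CI.

    ``years_per_mutation`` is the reported value (0.1-year precision);
    ``exact`` keeps the unrounded 1/(mu*L).
    """

    years_per_mutation: float
    low: float = math.nan  # NaN when no rate CI was supplied
    high: float = math.nan
    exact: float = math.nan

    def __post_init__(self) -> None:
        if math.isnan(self.low) or math.isnan(self.high):
            return
        # the point may sit on a range endpoint (rate evaluated at a CI bound)
        if not self.low <= self.years_per_mutation <= self.high:
            raise ValueError("range must bracket the point rate")
        if not self.low < self.high:
            raise ValueError("range must have positive width")


def scaled_rate(
    mu_per_site_per_year: float,
    L: int,
    mu_ci: tuple[float, float] | None = None,
) -> ScaledRate:
    """Scale a per-site per-year rate to years per mutation over L sites.

    years_per_mutation = 1 / (mu * L), reported to 0.1.  A higher mutation
    rate gives fewer years per mutation, so the CI bounds swap:
    the rate CI's upper end maps to the range's low end.

    >>> scaled_rate(1.0e-9, 3_724_156, (0.92e-9, 1.09e-9)).years_per_mutation
    268.5
    """
    if mu_per_site_per_year <= 0 or L < 1:
        raise ValueError("rate and locus length must be positive")
    point = round(1.0 / (mu_per_site_per_year * L), 1)
    if mu_ci is None:  # point-only rate: no range
        return ScaledRate(
            years_per_mutation=point, exact=1.0 / (mu_per_site_per_year * L)
        )
    lo_mu, hi_mu = max(mu_ci), min(mu_ci)
    if lo_mu <= 0 or hi_mu <= 0:
        raise ValueError("CI bounds must be positive")
    low = round(1.0 / (lo_mu * L), 1)
    high = round(1.0 / (hi_mu * L), 1)
    return ScaledRate(
        years_per_mutation=point,
        low=low,
        high=high,
        exact=1.0 / (mu_per_site_per_year * L),
    )


def _clade_tips(node: dendropy.Node) -> list[dendropy.Node]:
    return [leaf for leaf in node.leaf_iter()]


def rho(clade: dendropy.Node | MutationTree) -> dict:
    """Rho and its s.d. for a clade.

    rho is the mean over tips of the summed mutation counts from the clade
    root to each tip; sd^2 = sum over branches of (n_b / n)^2 * l_b.
    """
    node = clade.root if isinstance(clade, MutationTree) else clade
    tips = _clade_tips(node)
    if not tips:
        raise ValueError("empty clade")
    n = len(tips)
    total = 0.0
    var = 0.0
    # iterate branches strictly below the clade root
    stack = list(node.child_nodes())
    while stack:
        child = stack.pop()
        n_b = len(_clade_tips(child))
        l_b = float(child.edge.length)
        total += n_b * l_b
        var += (n_b / n) ** 2 * l_b
        stack.extend(child.child_nodes())
    return {"rho": total / n, "sd_rho": math.sqrt(var), "n_tips": n}


def round_to_ten(x: float) -> float:
    """Round to the nearest 10 years, halves up (2,685 -> 2,690)."""
    if math.isnan(x):
        return math.nan
    return math.floor(x / 10.0 + 0.5) * 10.0


@dataclass(frozen=True)
class RhoEstimate:
    rho: float
    sd_rho: float
    n_tips: int
    tmrca_years: float  # unrounded
    tmrca_low: float
    tmrca_high: float

    @property
    def reported(self) -> tuple[float, float, float]:
        """(TMRCA, low, high) rounded to the nearest 10 years."""
        return (
            round_to_ten(self.tmrca_years),
            round_to_ten(self.tmrca_low),
            round_to_ten(self.tmrca_high),
        )


def tmrca_from_rho(est: dict, rate: ScaledRate) -> RhoEstimate:
    """Convert a rho estimate into calendar years via the scaled rate."""
    r = float(est["rho"])
    if r < 0:
        raise ValueError("rho must be non-negative")
    return RhoEstimate(
        rho=r,
        sd_rho=float(est.get("sd_rho", math.nan)),
        n_tips=int(est.get("n_tips", 0)),
        tmrca_years=r * rate.years_per_mutation,
        tmrca_low=r * rate.low,
        tmrca_high=r * rate.high,
    )


def haplogroup_frequencies(assignments: dict[str, str]) -> pd.DataFrame:
    """Tabulate haplogroup counts and percentages from sample assignments.

    Percentages are 100 * count / total reported to 0.1.
    """
    if not assignments:
        raise ValueError("no assignments")
    counts = pd.Series(list(assignments.values())).value_counts()
    total = int(counts.sum())
    df = pd.DataFrame(
        {
            "haplogroup": counts.index,
            "count": counts.values,
            "percent": (100.0 * counts.values / total).round(1),
        }
    )
    return df.reset_index(drop=True)


def clade_table(
    tree: MutationTree, clade_labels: list[str], rate: ScaledRate
) -> pd.DataFrame:
    """Rho TMRCA summary for a list of labelled clades (Table-1 style)."""
    rows = []
    for label in clade_labels:
        est = tmrca_from_rho(rho(tree.find_clade(label)), rate)
        t, lo, hi = est.reported
        rows.append(
            {
                "hg": label,
                "N": est.n_tips,
                "rho": est.rho,
                "sd_rho": est.sd_rho,
                "tmrca": t,
                "tmrca_low": lo,
                "tmrca_high": hi,
            }
        )
    return pd.DataFrame(rows)
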