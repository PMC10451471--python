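"""The gene-tree Delta statistic.

For a rooted quartet (((P1,P2),P3),O) each gene tree is classified as
concordant, discordant-1 (((P2,P3),P1),O), discordant-2
(((P1,P3),P2),O), or uninformative. Under incomplete lineage sorting
alone the two discordant topologies are equally likely, so

    Delta = (n_disc1 - n_disc2) / (n_disc1 + n_disc2)

has expectation zero; a positive value signals excess P2-P3 allele
sharing, matching the orientation of Patterson's D. Because Delta is
computed from whole gene-tree topologies rather than site patterns, it
is insensitive to multiple substitutions per site.

Significance is assessed by resampling the classified gene trees with
replacement (multinomial over the four categories), recomputing Delta
for each pseudoreplicate, and taking the bootstrap standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .treeops import QuartetSpec, QuartetTopology, classify_quartet_topology

__all__ = [
    "QuartetCounts",
    "DeltaResult",
    "count_quartet_topologies",
    "compute_delta",
    "delta_method_se",
    "bootstrap_delta",
]


@dataclass(frozen=True)
class QuartetCounts:
    """Topology tallies for one quartet across a set of gene trees."""

    n_concordant: int
    n_disc1: int
    n_disc2: int
    n_uninformative: int = 0

    def __post_init__(self) -> None:
        if min(self.n_concordant, self.n_disc1,
               self.n_disc2, self.n_uninformative) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return (self.n_concordant + self.n_disc1
                + self.n_disc2 + self.n_uninformative)

    def swap_disc(self) -> "QuartetCounts":
        return QuartetCounts(self.n_concordant, self.n_disc2,
                             self.n_disc1, self.n_uninformative)


@dataclass
class DeltaResult:
    delta: float
    se: float
    z: float
    p: float
    n_reps: int
    seed: int
    n_dropped_reps: int = 0


def count_quartet_topologies(
    trees: Iterable, q: QuartetSpec
) -> QuartetCounts:
    """Classify every gene tree against the quartet and tally."""
    tally = {t: 0 for t in QuartetTopology}
    for tree in trees:
        tally[classify_quartet_topology(tree, q)] += 1
    return QuartetCounts(
        n_concordant=tally[QuartetTopology.CONCORDANT],
        n_disc1=tally[QuartetTopology.DISC1],
        n_disc2=tally[QuartetTopology.DISC2],
        n_uninformative=tally[QuartetTopology.UNINFORMATIVE],
    )


def compute_delta(counts: QuartetCounts) -> float:
    """Delta = (disc1 - disc2)/(disc1 + disc2); NaN when undefined."""
    denom = counts.n_disc1 + counts.n_disc2
    if denom == 0:
        return math.nan
    return (counts.n_disc1 - counts.n_disc2) / denom


def delta_method_se(counts: QuartetCounts) -> float:
    """Closed-form large-sample SE: sqrt((1 - Delta^2)/(d1 + d2))."""
    nd = counts.n_disc1 + counts.n_disc2
    if nd == 0:
        return math.nan
    delta = compute_delta(counts)
    return math.sqrt(max(1.0 - delta * delta, 0.0) / nd)


def bootstrap_delta(
    counts: QuartetCounts,
    n_reps: int = 10_000,
    seed: int = 0,
) -> DeltaResult:
    """Bootstrap Delta by multinomial resampling of classified trees.

    Each pseudoreplicate draws ``n_total`` trees with replacement from
    the empirical category distribution (concordant/disc1/disc2/
    uninformative) and recomputes Delta. Replicates where both
    discordant counts are zero leave Delta undefined; they are dropped
    from the SE and counted in ``n_dropped_reps``. Z uses the bootstrap
    standard deviation; p is the two-tailed normal tail probability.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    n = counts.n_total
    if n == 0:
        raise ValueError("no gene trees to resample")
    delta_obs = compute_delta(counts)
    rng = np.random.default_rng(seed)
    probs = np.array([counts.n_concordant, counts.n_disc1,
                      counts.n_disc2, counts.n_uninformative], dtype=float) / n
    draws = rng.multinomial(n, probs, size=n_reps)
    d1 = draws[:, 1].astype(float)
    d2 = draws[:, 2].astype(float)
    denom = d1 + d2
    ok = denom > 0
    reps = (d1[ok] - d2[ok]) / denom[ok]
    n_dropped = int(n_reps - ok.sum())
    if len(reps) < 2:
        se = math.nan
    else:
        se = float(np.std(reps, ddof=1))
    if math.isnan(se) or math.isnan(delta_obs):
        z = p = math.nan
    elif se == 0:
        z = math.inf if delta_obs != 0 else math.nan
        p = 0.0 if delta_obs != 0 else math.nan
    else:
        z = delta_obs / se
        p = float(2 * stats.norm.sf(abs(z)))
    return DeltaResult(delta_obs, se, z, p, n_reps, seed, n_dropped)
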