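"""Site-resampling bootstrap with majority-rule consensus.

Each replicate draws ``round(ratio * total_sites)`` site indices uniformly
with replacement (duplicates kept with multiplicity, as in the ordinary
bootstrap), rebuilds the p-distance matrix over exactly those draws using
the same per-pair missing-data denominators, builds one tree per replicate,
and summarises the replicate set as a majority-rule consensus with support
values.

Per-site pair scores are materialised once in a :class:`SiteScoreCache`
(one float and one flag per pair per site) so that with-replacement draws
become fancy-indexed sums; for very large inputs this cache is the memory
bottleneck and inputs should be thinned beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .distance import DistanceMatrix, _ChunkArrays, _score_pair_slice
from .errors import PdistreeError
from .io_variants import SiteGenotypes
from .phylogeny import PhyloTree, majority_consensus, neighbor_joining, upgma

__all__ = [
    "ResamplePlan",
    "SiteScoreCache",
    "resample_accumulate",
    "bootstrap_trees",
    "bootstrap_tree",
]


@dataclass(frozen=True)
class ResamplePlan:
    """Parameters of the site-resampling scheme.

    ``ratio`` is the fraction of all sites drawn per replicate (default
    0.25); the draw count is round-half-even of ``ratio * total_sites``,
    minimum 1.  The same (seed, ratio, total_sites, n_replicates) always
    yields the same draws.  ``diagnostic_identity`` replaces the random
    draw by a permutation of all sites (each site exactly once), which at
    ratio 1 must reproduce the full-data matrix exactly.
    """

    total_sites: int
    n_replicates: int = 100
    ratio: float = 0.25
    seed: int = 0
    diagnostic_identity: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio <= 1.0:
            raise PdistreeError(f"resample ratio must be in (0, 1], got {self.ratio}")
        if self.n_replicates < 1:
            raise PdistreeError("n_replicates must be >= 1")
        if self.total_sites < 1:
            raise PdistreeError("total_sites must be >= 1")

    @property
    def draw_count(self) -> int:
        return max(1, round(self.ratio * self.total_sites))


class SiteScoreCache:
    """Per-site condensed pair scores: d (m, n_pairs) and usable flags."""

    def __init__(self, names: Sequence[str], d: np.ndarray, usable: np.ndarray):
        self.names = tuple(names)
        self.d = d
        self.usable = usable

    @property
    def n_sites(self) -> int:
        return self.d.shape[0]

    @classmethod
    def from_stream(
        cls, stream: Iterable[SiteGenotypes], names: Sequence[str]
    ) -> "SiteScoreCache":
        names = tuple(names)
        n = len(names)
        iu = np.triu_indices(n, 1)
        d_blocks: list[np.ndarray] = []
        u_blocks: list[np.ndarray] = []
        chunk: list[SiteGenotypes] = []

        def flush() -> None:
            ch = _ChunkArrays(chunk, n)
            if ch.general_sites:
                raise PdistreeError(
                    "bootstrap cache supports ploidy <= 2 calls only"
                )
            d, usable, _ = _score_pair_slice(ch, iu[0], iu[1])
            d_blocks.append(d)
            u_blocks.append(usable)
            chunk.clear()

        for site in stream:
            chunk.append(site)
            if len(chunk) >= 10_000:
                flush()
        if chunk:
            flush()
        if not d_blocks:
            raise PdistreeError("cannot bootstrap an empty site stream")
        return cls(names, np.vstack(d_blocks), np.vstack(u_blocks))

    def matrix_for(self, idx: np.ndarray) -> DistanceMatrix:
        """Finalized p-distance matrix over the drawn site multiset."""
        sum_d = self.d[idx].sum(axis=0)
        used = self.usable[idx].sum(axis=0)
        n = len(self.names)
        D = np.zeros((n, n))
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = sum_d / used
        vals = np.where(used == 0, np.nan, vals)
        iu = np.triu_indices(n, 1)
        D[iu] = vals
        D[(iu[1], iu[0])] = vals
        return DistanceMatrix(self.names, D)

    def full_matrix(self) -> DistanceMatrix:
        return self.matrix_for(np.arange(self.n_sites))


def _draws(plan: ResamplePlan, rng: np.random.Generator) -> np.ndarray:
    if plan.diagnostic_identity:
        return rng.permutation(plan.total_sites)
    return rng.integers(0, plan.total_sites, size=plan.draw_count)


def resample_accumulate(
    cache: SiteScoreCache, plan: ResamplePlan
) -> list[DistanceMatrix]:
    """One finalized DistanceMatrix per bootstrap replicate."""
    if plan.total_sites != cache.n_sites:
        raise PdistreeError(
            f"plan covers {plan.total_sites} sites, cache holds {cache.n_sites}"
        )
    rng = np.random.default_rng(plan.seed)
    return [cache.matrix_for(_draws(plan, rng)) for _ in range(plan.n_replicates)]


def bootstrap_trees(
    cache: SiteScoreCache,
    plan: ResamplePlan,
    method: str = "nj",
    clamp_negative: bool = False,
) -> list[PhyloTree]:
    """Build one tree per replicate matrix."""
    if method not in ("nj", "upgma"):
        raise PdistreeError(f"unknown tree method {method!r}")
    trees = []
    for dm in resample_accumulate(cache, plan):
        if method == "nj":
            trees.append(neighbor_joining(dm, clamp_negative=clamp_negative))
        else:
            trees.append(upgma(dm))
    return trees


def bootstrap_tree(
    cache: SiteScoreCache,
    plan: ResamplePlan,
    method: str = "nj",
    threshold: float = 0.5,
    clamp_negative: bool = False,
) -> tuple[PhyloTree, list[PhyloTree]]:
    """Consensus tree with supports, plus the replicate trees themselves.

    A single replicate degenerates to that replicate's own topology with
    all supports 100.
    """
    trees = bootstrap_trees(cache, plan, method=method, clamp_negative=clamp_negative)
    if len(trees) == 1:
        consensus = majority_consensus([trees[0], trees[0]], threshold)
    else:
        consensus = majority_consensus(trees, threshold)
    return consensus, trees
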