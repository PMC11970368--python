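"""Synthetic data generators with analytically known expectations.

The VCF generator plants group structure through a two-layer site model
chosen so that the *expected* pairwise p-distance is exactly the requested
``within_diff_prob`` (w) for same-group pairs and ``between_diff_prob`` (b)
for cross-group pairs, with no resimulation needed to know the truth:

* every site is biallelic in sample space (0/1, shifted to 1/2 on
  "multiallelic" sites so a third allele exists in the ALT column);
* with probability delta a site is *divergent*: a uniformly random
  nonempty proper subset of groups carries base allele 1, the rest base 0
  (so any two groups differ with probability gamma(k) = 2^(k-1)/(2^k - 2));
* each of a sample's two allele copies equals its group base flipped
  independently with probability eps.

With u = eps(1 - eps), a same-group pair's expected per-site distance under
the genotype multiset rule is 2u(1 - u), and eps, delta are solved from
(w, b) in closed form; the generator refuses parameter combinations outside
the solvable region (w <= 0.375, b not above the divergent-site ceiling).
Phased calls are written with alleles in sorted order, which leaves the
per-site score identical under the positional rule, so ``phased_fraction``
does not perturb the expectation; missing calls are excluded pairwise and
do not bias it either.

The alignment generator evolves sequences down a given tree under the
Jukes-Cantor process, and the random additive / ultrametric tree factories
provide matrices on which NJ and UPGMA are provably consistent.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix, write_matrix
from .errors import PdistreeError
from .io_sequences import Alignment
from .phylogeny import Node, PhyloTree

__all__ = [
    "PopulationModel",
    "simulate_vcf",
    "simulate_alignment",
    "solve_site_model",
    "random_binary_tree",
    "random_ultrametric_tree",
]


@dataclass(frozen=True)
class PopulationModel:
    """Planted-structure population for synthetic VCFs.

    ``groups`` is an ordered list of (name, size); sample names are
    ``<group>_<k>``.  Probabilities are per-site (within/between expected
    pairwise distance) or per-call (phased/missing/multiallelic rates).
    """

    groups: tuple = (("g1", 5), ("g2", 5))
    m_sites: int = 1000
    within_diff_prob: float = 0.05
    between_diff_prob: float = 0.2
    phased_fraction: float = 0.0
    missing_rate: float = 0.0
    multiallelic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p_name in (
            "within_diff_prob",
            "between_diff_prob",
            "phased_fraction",
            "missing_rate",
            "multiallelic_fraction",
        ):
            v = getattr(self, p_name)
            if not 0.0 <= v <= 1.0:
                raise PdistreeError(f"{p_name} must be in [0, 1], got {v}")
        if self.between_diff_prob < self.within_diff_prob:
            raise PdistreeError("between_diff_prob must be >= within_diff_prob")
        if self.m_sites < 1 or any(size < 1 for _, size in self.groups):
            raise PdistreeError("m_sites and group sizes must be >= 1")

    @property
    def sample_names(self) -> tuple[str, ...]:
        return tuple(
            f"{gname}_{k + 1}" for gname, size in self.groups for k in range(size)
        )

    @property
    def group_of_sample(self) -> np.ndarray:
        return np.concatenate(
            [np.full(size, gi) for gi, (_, size) in enumerate(self.groups)]
        )


def _binom2(p: float) -> np.ndarray:
    """Pmf of Bin(2, p)."""
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


def _expected_divergent_d(eps: float) -> float:
    """E[|z_i - z_j| / 2] when the two samples sit on opposite base alleles.

    With base 0 the alt-allele count is a ~ Bin(2, eps); with base 1 it is
    2 - b with b ~ Bin(2, eps); the multiset genotype distance is half the
    absolute count difference.
    """
    pa = _binom2(eps)
    total = 0.0
    for a in range(3):
        for b in range(3):
            total += pa[a] * pa[b] * abs(a - (2 - b)) / 2.0
    return total


def group_divergence_prob(n_groups: int) -> float:
    """P(two given groups get different bases on a divergent site).

    Bases on a divergent site follow a uniformly random nonempty proper
    subset of the n_groups groups: gamma = 2^(k-1) / (2^k - 2).
    """
    if n_groups < 2:
        return 0.0
    return 2.0 ** (n_groups - 1) / (2.0**n_groups - 2.0)


def solve_site_model(
    within: float, between: float, n_groups: int
) -> tuple[float, float, float]:
    """Solve (eps, delta, e_div) so expectations hit (within, between) exactly."""
    if within > 0.375:
        raise PdistreeError(
            f"within_diff_prob {within} exceeds 0.375, the maximum achievable "
            "expected genotype distance under the allele-flip model"
        )
    u = (1.0 - math.sqrt(1.0 - 8.0 * within / 4.0)) / 2.0  # solve 2u(1-u) = w
    eps = (1.0 - math.sqrt(1.0 - 4.0 * u)) / 2.0
    e_div = _expected_divergent_d(eps)
    if between == within:
        return eps, 0.0, e_div
    if n_groups < 2:
        raise PdistreeError("between_diff_prob > within requires >= 2 groups")
    gamma = group_divergence_prob(n_groups)
    ceiling = within + gamma * (e_div - within)
    if between > ceiling + 1e-12:
        raise PdistreeError(
            f"between_diff_prob {between} not achievable: maximum is "
            f"{ceiling:.4f} given within_diff_prob {within} and {n_groups} groups"
        )
    delta = (between - within) / (gamma * (e_div - within))
    return eps, min(delta, 1.0), e_div


def expected_distance_matrix(model: PopulationModel) -> DistanceMatrix:
    """The exact E[D] implied by the model (validates solvability)."""
    solve_site_model(
        model.within_diff_prob, model.between_diff_prob, len(model.groups)
    )
    g = model.group_of_sample
    same = g[:, None] == g[None, :]
    D = np.where(same, model.within_diff_prob, model.between_diff_prob)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(model.sample_names, D)


def simulate_vcf(
    model: PopulationModel, path: str | os.PathLike
) -> tuple[tuple[str, ...], DistanceMatrix]:
    """Write a synthetic VCF; return (sample names, exact expected D).

    The expected-distance matrix is also written alongside the VCF as
    ``<path>.expected.mat`` in the same Phylip format the tool emits.
    Output is byte-identical for identical models (seed included).
    """
    eps, delta, _ = solve_site_model(
        model.within_diff_prob, model.between_diff_prob, len(model.groups)
    )
    names = model.sample_names
    group_idx = model.group_of_sample
    n = len(names)
    m = model.m_sites
    k = len(model.groups)
    rng = np.random.default_rng(model.seed)

    divergent = rng.random(m) < delta
    if k >= 2:
        subset_codes = rng.integers(1, 2**k - 1, size=m)
    else:
        subset_codes = np.zeros(m, dtype=np.int64)
    group_bases = ((subset_codes[:, None] >> np.arange(k)[None, :]) & 1).astype(np.int8)
    group_bases[~divergent] = 0
    base = group_bases[:, group_idx]  # (m, n)

    flips = rng.random((m, n, 2)) < eps
    alleles = base[:, :, None] ^ flips  # (m, n, 2) in {0, 1}
    lo = alleles.min(axis=2).astype(np.int8)
    hi = alleles.max(axis=2).astype(np.int8)
    missing = rng.random((m, n)) < model.missing_rate
    phased = rng.random((m, n)) < model.phased_fraction
    multi = rng.random(m) < model.multiallelic_fraction
    lo = lo + multi[:, None].astype(np.int8)
    hi = hi + multi[:, None].astype(np.int8)

    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=pdistree synthetic fixture (seed={model.seed})\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for s in range(m):
            alt = "C,T" if multi[s] else "C"
            cols = [
                "1",
                str(s + 1),
                ".",
                "A",
                alt,
                ".",
                ".",
                ".",
                "GT",
            ]
            row_lo, row_hi = lo[s], hi[s]
            row_missing, row_phased = missing[s], phased[s]
            for t in range(n):
                if row_missing[t]:
                    cols.append("./.")
                else:
                    sep = "|" if row_phased[t] else "/"
                    cols.append(f"{row_lo[t]}{sep}{row_hi[t]}")
            fh.write("\t".join(cols) + "\n")

    expected = expected_distance_matrix(model)
    write_matrix(expected, f"{os.fspath(path)}.expected.mat")
    return names, expected


# ---------------------------------------------------------------------------
# alignment and tree generators

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_alignment(
    tree: PhyloTree,
    n_sites: int,
    rate: float = 1.0,
    seed: int = 0,
    path: str | os.PathLike | None = None,
) -> Alignment:
    """Evolve sequences down ``tree`` under Jukes-Cantor; optionally write FASTA.

    Branch lengths are interpreted in expected substitutions per site scaled
    by ``rate``; expected p-distance between two leaves is a monotone
    function of their path length.  ``rate=0`` yields identical sequences.
    """
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=n_sites)
    rows: dict[str, str] = {}

    def walk(node: Node, seq: np.ndarray) -> None:
        t = (node.length or 0.0) * rate
        if t > 0:
            # JC: with prob 1 - exp(-4t/3) redraw uniformly over all 4 bases.
            q = 1.0 - math.exp(-4.0 * t / 3.0)
            mask = rng.random(n_sites) < q
            redraw = rng.integers(0, 4, size=n_sites)
            seq = np.where(mask, redraw, seq)
        if node.is_leaf:
            rows[node.name] = _BASES[seq].tobytes().decode("ascii")
        for child in node.children:
            walk(child, seq)

    walk(tree.root, root_seq)
    names = tree.leaf_names()
    aln = Alignment(names, tuple(rows[n] for n in names))
    if path is not None:
        with open(path, "wt", encoding="utf-8") as fh:
            for name, row in zip(aln.names, aln.rows):
                fh.write(f">{name}\n{row}\n")
    return aln


def _leaf_labels(n_taxa: int) -> list[str]:
    width = len(str(n_taxa))
    return [f"T{i + 1:0{width}d}" for i in range(n_taxa)]


def random_binary_tree(
    n_taxa: int,
    seed: int = 0,
    min_len: float = 0.1,
    max_len: float = 1.0,
) -> PhyloTree:
    """Random binary topology with i.i.d. uniform positive branch lengths.

    Its leaf-to-leaf path-length matrix is additive by construction, so NJ
    must recover the (unrooted) topology and all pairwise distances.
    """
    if n_taxa < 3:
        raise PdistreeError("need >= 3 taxa")
    rng = np.random.default_rng(seed)
    nodes = [Node(name=lbl) for lbl in _leaf_labels(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(min_len, max_len))
        b.length = float(rng.uniform(min_len, max_len))
        parent = Node(children=[a, b])
        nodes = [x for x_i, x in enumerate(nodes) if x_i not in (i, j)] + [parent]
    a, b = nodes
    a.length = float(rng.uniform(min_len, max_len))
    b.length = float(rng.uniform(min_len, max_len))
    return PhyloTree(Node(children=[a, b]))


def random_ultrametric_tree(
    n_taxa: int,
    seed: int = 0,
    min_step: float = 0.1,
    max_step: float = 1.0,
) -> PhyloTree:
    """Random rooted tree with strictly increasing merge heights.

    Leaf-to-leaf distances are twice the height of the MRCA, hence
    ultrametric with distinct merge levels, on which UPGMA is exact.
    """
    if n_taxa < 2:
        raise PdistreeError("need >= 2 taxa")
    rng = np.random.default_rng(seed)
    nodes = [Node(name=lbl) for lbl in _leaf_labels(n_taxa)]
    heights = [0.0] * n_taxa
    h = 0.0
    while len(nodes) > 1:
        h += float(rng.uniform(min_step, max_step))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = h - heights[i]
        b.length = h - heights[j]
        parent = Node(children=[a, b])
        nodes = [x for x_i, x in enumerate(nodes) if x_i not in (i, j)] + [parent]
        heights = [hh for h_i, hh in enumerate(heights) if h_i not in (i, j)] + [h]
    return PhyloTree(nodes[0])
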