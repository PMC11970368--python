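"""Streaming p-distance accumulation and the Phylip matrix format.

The distance between individuals i and j is

    D_ij = (sum over usable sites l of d_l) / L_ij

where d_l compares the two genotype calls at site l and L_ij counts the
sites at which *both* members of the pair are called (pairwise deletion).
For an unphased pair, d_l is the multiset mismatch fraction of the two
allele tuples (for diploids exactly {0, 0.5, 1}); when both calls are
phased, alleles are compared positionally so that e.g. ordered genotypes
CA vs AC score 1 even though their allele content is identical.

Sites stream through in bounded-size chunks; within a chunk only the upper
triangle of sample pairs is scored, and the pair range can be partitioned
across worker threads.  Per-site scores are exact binary fractions
(k/ploidy), each pair's sum is accumulated in site order regardless of the
partitioning, and workers write disjoint slices, so single- and
multi-worker runs produce bit-identical accumulators.
"""

from __future__ import annotations

import os
from collections import Counter
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import MatrixFormatError, MixedPloidyError, PdistreeError
from .io_variants import Call, SiteGenotypes

__all__ = [
    "PairAccumulator",
    "DistanceMatrix",
    "score_pair",
    "accumulate",
    "finalize",
    "distance_matrix_from_stream",
    "write_matrix",
    "read_matrix",
    "UNDEFINED_SENTINEL",
]

#: Value written to the matrix file for a pair with no usable site.
UNDEFINED_SENTINEL = -1.0

#: Default number of sites buffered per processing chunk.
DEFAULT_CHUNK_SITES = 10_000


def score_pair(call_a: Call, call_b: Call) -> float:
    """Per-site distance contribution d_l for two non-missing calls.

    Both phased and equal ploidy -> positional Hamming fraction; otherwise
    the multiset rule d = 1 - |multiset intersection| / ploidy.  Calls of
    different ploidy are incomparable and raise :class:`MixedPloidyError`
    (the accumulator skips such pairs at that site and counts them).
    """
    pa, pb = len(call_a.alleles), len(call_b.alleles)
    if pa != pb:
        raise MixedPloidyError(
            f"cannot compare calls of ploidy {pa} and {pb} at one site"
        )
    if call_a.phased and call_b.phased:
        diff = sum(x != y for x, y in zip(call_a.alleles, call_b.alleles))
        return diff / pa
    shared = sum((Counter(call_a.alleles) & Counter(call_b.alleles)).values())
    return 1.0 - shared / pa


@dataclass
class PairAccumulator:
    """Upper-triangle running sums of per-site distances and usable-site counts.

    Pair (i, j) with i < j lives at condensed slot
    ``i * (2n - i - 1) // 2 + (j - i - 1)`` (row-major upper triangle).
    ``comparisons`` counts every pair slot visited per streamed site (the
    Theta(n^2 m) work term); ``mixed_ploidy_skips`` counts pair-site
    combinations dropped because the two calls had unequal ploidy.
    """

    n: int
    sum_d: np.ndarray = field(init=False)
    used_sites: np.ndarray = field(init=False)
    sites_streamed: int = 0
    mixed_ploidy_skips: int = 0
    comparisons: int = 0
    max_buffered_sites: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise PdistreeError("accumulator needs n >= 1 samples")
        npairs = self.n * (self.n - 1) // 2
        self.sum_d = np.zeros(npairs, dtype=np.float64)
        self.used_sites = np.zeros(npairs, dtype=np.int64)

    @property
    def n_pairs(self) -> int:
        return self.sum_d.shape[0]

    def pair_index(self, i: int, j: int) -> int:
        if not 0 <= i < j < self.n:
            raise IndexError(f"pair ({i}, {j}) out of range for n={self.n}")
        return i * (2 * self.n - i - 1) // 2 + (j - i - 1)

    def merge(self, other: "PairAccumulator") -> "PairAccumulator":
        """Merge an accumulator built from a disjoint block of sites."""
        if other.n != self.n:
            raise PdistreeError("cannot merge accumulators of different n")
        self.sum_d += other.sum_d
        self.used_sites += other.used_sites
        self.sites_streamed += other.sites_streamed
        self.mixed_ploidy_skips += other.mixed_ploidy_skips
        self.comparisons += other.comparisons
        self.max_buffered_sites = max(self.max_buffered_sites, other.max_buffered_sites)
        return self


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric p-distance matrix; undefined pairs hold NaN."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        n = len(self.names)
        if v.shape != (n, n):
            raise PdistreeError(f"matrix shape {v.shape} does not match {n} names")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def require_defined(self) -> None:
        """Raise if any off-diagonal pair shared no usable site."""
        bad = np.argwhere(~self.defined)
        if bad.size:
            i, j = bad[0]
            raise PdistreeError(
                f"distance between {self.names[i]!r} and {self.names[j]!r} is "
                "undefined (no site where both are called)"
            )

    def reorder(self, names: Sequence[str]) -> "DistanceMatrix":
        idx = [self.names.index(n) for n in names]
        return DistanceMatrix(tuple(names), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# chunked scoring


class _ChunkArrays:
    """Dense per-chunk genotype representation for ploidy <= 2 calls.

    a0/a1: allele indices (-1 where absent), pl: ploidy (0 = missing),
    ph: phased flags, lo/hi: per-site sorted allele pair for the multiset
    rule.  Sites containing any ploidy > 2 call are diverted to the scalar
    path and recorded in ``general_sites``.
    """

    def __init__(self, sites: Sequence[SiteGenotypes], n: int) -> None:
        s = len(sites)
        self.a0 = np.full((s, n), -1, dtype=np.int32)
        self.a1 = np.full((s, n), -1, dtype=np.int32)
        self.pl = np.zeros((s, n), dtype=np.int8)
        self.ph = np.zeros((s, n), dtype=bool)
        self.general_sites: list[SiteGenotypes] = []
        keep = np.ones(s, dtype=bool)
        for si, site in enumerate(sites):
            if len(site.genotypes) != n:
                raise PdistreeError(
                    f"site {site.chrom}:{site.pos} carries {len(site.genotypes)} "
                    f"genotypes, accumulator expects {n}"
                )
            row_a0, row_a1 = self.a0[si], self.a1[si]
            row_pl, row_ph = self.pl[si], self.ph[si]
            for sj, call in enumerate(site.genotypes):
                if call is None:
                    continue
                alleles = call.alleles
                p = len(alleles)
                if p > 2:
                    self.general_sites.append(site)
                    keep[si] = False
                    break
                row_pl[sj] = p
                row_ph[sj] = call.phased
                row_a0[sj] = alleles[0]
                if p == 2:
                    row_a1[sj] = alleles[1]
        if not keep.all():
            self.a0 = self.a0[keep]
            self.a1 = self.a1[keep]
            self.pl = self.pl[keep]
            self.ph = self.ph[keep]
        self.lo = np.minimum(self.a0, self.a1)
        self.hi = np.maximum(self.a0, self.a1)
        self.n_vector_sites = int(keep.sum())


def _score_pair_slice(
    ch: _ChunkArrays, i_idx: np.ndarray, j_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Score a slice of pairs over all vectorised sites of a chunk.

    Returns (d, usable) of shape (sites, pairs) and the mixed-ploidy count.
    """
    pli = ch.pl[:, i_idx]
    plj = ch.pl[:, j_idx]
    both = (pli > 0) & (plj > 0)
    same = pli == plj
    usable = both & same
    mixed = int(np.count_nonzero(both & ~same))

    d = np.zeros(usable.shape, dtype=np.float64)

    hap = usable & (pli == 1)
    if hap.any():
        dh = (ch.a0[:, i_idx] != ch.a0[:, j_idx]).astype(np.float64)
        np.copyto(d, dh, where=hap)

    dip = usable & (pli == 2)
    if dip.any():
        ai0, ai1 = ch.a0[:, i_idx], ch.a1[:, i_idx]
        aj0, aj1 = ch.a0[:, j_idx], ch.a1[:, j_idx]
        # Unphased multiset rule on sorted pairs: two 2-multisets intersect in
        # 2 elements iff equal, else in 1 iff they share any element.
        li, hi_ = ch.lo[:, i_idx], ch.hi[:, i_idx]
        lj, hj = ch.lo[:, j_idx], ch.hi[:, j_idx]
        eq2 = (li == lj) & (hi_ == hj)
        any_common = (li == lj) | (li == hj) | (hi_ == lj) | (hi_ == hj)
        shared = np.where(eq2, 2, np.where(any_common, 1, 0))
        dms = 1.0 - shared / 2.0
        bothphased = ch.ph[:, i_idx] & ch.ph[:, j_idx]
        dpos = ((ai0 != aj0).astype(np.float64) + (ai1 != aj1)) / 2.0
        np.copyto(d, np.where(bothphased, dpos, dms), where=dip)

    return d, usable, mixed


def _apply_general_sites(
    acc: PairAccumulator, sites: list[SiteGenotypes], iu: tuple[np.ndarray, np.ndarray]
) -> None:
    """Scalar fallback for sites containing ploidy > 2 calls."""
    for site in sites:
        g = site.genotypes
        for k, (i, j) in enumerate(zip(iu[0], iu[1])):
            a, b = g[i], g[j]
            if a is None or b is None:
                continue
            try:
                acc.sum_d[k] += score_pair(a, b)
                acc.used_sites[k] += 1
            except MixedPloidyError:
                acc.mixed_ploidy_skips += 1


def accumulate(
    stream: Iterable[SiteGenotypes],
    acc: PairAccumulator,
    workers: int = 1,
    chunk_sites: int = DEFAULT_CHUNK_SITES,
) -> PairAccumulator:
    """Stream sites into the accumulator, chunked and optionally threaded.

    Pairs are partitioned into ``workers`` contiguous condensed-index blocks
    per chunk; each worker writes only its own slice, so the result is
    bit-identical for any worker count.
    """
    if workers < 1:
        raise PdistreeError("workers must be >= 1")
    if chunk_sites < 1:
        raise PdistreeError("chunk_sites must be >= 1")
    iu = np.triu_indices(acc.n, 1)
    buf: list[SiteGenotypes] = []
    for site in stream:
        buf.append(site)
        if len(buf) >= chunk_sites:
            _process_chunk(buf, acc, iu, workers)
            buf.clear()
    if buf:
        _process_chunk(buf, acc, iu, workers)
    return acc


def _process_chunk(
    buf: list[SiteGenotypes],
    acc: PairAccumulator,
    iu: tuple[np.ndarray, np.ndarray],
    workers: int,
) -> None:
    acc.max_buffered_sites = max(acc.max_buffered_sites, len(buf))
    acc.sites_streamed += len(buf)
    acc.comparisons += len(buf) * acc.n_pairs
    if acc.n_pairs == 0:
        return
    ch = _ChunkArrays(buf, acc.n)
    npairs = acc.n_pairs

    def work(lo: int, hi: int) -> int:
        d, usable, mixed = _score_pair_slice(ch, iu[0][lo:hi], iu[1][lo:hi])
        acc.sum_d[lo:hi] += d.sum(axis=0)
        acc.used_sites[lo:hi] += usable.sum(axis=0)
        return mixed

    bounds = np.linspace(0, npairs, min(workers, npairs) + 1).astype(int)
    if workers == 1 or len(bounds) <= 2:
        mixed_counts = [work(bounds[0], bounds[-1])]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            mixed_counts = list(
                pool.map(lambda t: work(*t), zip(bounds[:-1], bounds[1:]))
            )
    for m in mixed_counts:
        acc.mixed_ploidy_skips += m
    if ch.general_sites:
        _apply_general_sites(acc, ch.general_sites, iu)


def finalize(acc: PairAccumulator, names: Sequence[str]) -> DistanceMatrix:
    """Turn accumulated sums into the symmetric p-distance matrix.

    Pairs with no usable site become NaN (serialised as the -1 sentinel by
    :func:`write_matrix`).
    """
    names = tuple(names)
    if len(names) != acc.n:
        raise PdistreeError(f"{len(names)} names for accumulator of n={acc.n}")
    n = acc.n
    D = np.zeros((n, n), dtype=np.float64)
    iu = np.triu_indices(n, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = acc.sum_d / acc.used_sites
    vals[acc.used_sites == 0] = np.nan
    D[iu] = vals
    D[(iu[1], iu[0])] = vals
    return DistanceMatrix(names, D)


def distance_matrix_from_stream(
    stream: Iterable[SiteGenotypes],
    names: Sequence[str],
    workers: int = 1,
    chunk_sites: int = DEFAULT_CHUNK_SITES,
) -> tuple[DistanceMatrix, PairAccumulator]:
    """Convenience wrapper: accumulate a whole stream and finalize."""
    acc = PairAccumulator(len(names))
    accumulate(stream, acc, workers=workers, chunk_sites=chunk_sites)
    return finalize(acc, names), acc


# ---------------------------------------------------------------------------
# Phylip square distance matrix


def format_matrix(dm: DistanceMatrix, decimals: int = 6) -> str:
    """Render the square relaxed-Phylip matrix as text."""
    if decimals < 1:
        raise PdistreeError("decimals must be >= 1")
    width = max(10, max(len(n) for n in dm.names) + 1)
    lines = [str(dm.n)]
    for i, name in enumerate(dm.names):
        row = dm.values[i].copy()
        row[np.isnan(row)] = UNDEFINED_SENTINEL
        cells = " ".join(f"{v:.{decimals}f}" for v in row)
        lines.append(f"{name.ljust(width)}{cells}")
    return "\n".join(lines) + "\n"


def write_matrix(dm: DistanceMatrix, path: str | os.PathLike, decimals: int = 6) -> None:
    """Write a square Phylip-style distance matrix file."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(format_matrix(dm, decimals))


def read_matrix(path: str | os.PathLike) -> DistanceMatrix:
    """Read a Phylip distance matrix, square or lower-triangle.

    Square input must be symmetric to within the printed precision; the two
    triangles are averaged.  Negative entries mark undefined pairs.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        raw = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not raw:
        raise MatrixFormatError(f"{path}: empty matrix file")
    try:
        n = int(raw[0].split()[0])
    except ValueError:
        raise MatrixFormatError(f"{path}: first line must hold the sample count") from None
    if len(raw) - 1 != n:
        raise MatrixFormatError(
            f"{path}: header declares {n} samples but file has {len(raw) - 1} rows"
        )
    names: list[str] = []
    rows: list[list[float]] = []
    max_dec = 1
    for line in raw[1:]:
        tokens = line.split()
        names.append(tokens[0])
        vals = []
        for tok in tokens[1:]:
            try:
                vals.append(float(tok))
            except ValueError:
                raise MatrixFormatError(f"{path}: bad matrix entry {tok!r}") from None
            if "." in tok:
                max_dec = max(max_dec, len(tok.split(".")[1]))
        rows.append(vals)
    lengths = [len(r) for r in rows]
    D = np.zeros((n, n), dtype=np.float64)
    if all(k == n for k in lengths):
        M = np.array(rows)
        tol = 0.5 * 10.0 ** (-max_dec) + 1e-12
        if np.nanmax(np.abs(M - M.T)) > tol:
            raise MatrixFormatError(f"{path}: matrix asymmetric beyond printed precision")
        D = (M + M.T) / 2.0
    elif all(k in (i, i + 1) for i, k in enumerate(lengths)):
        for i, vals in enumerate(rows):
            vals = vals[:i]  # drop diagonal if present
            for j, v in enumerate(vals):
                D[i, j] = D[j, i] = v
    else:
        raise MatrixFormatError(
            f"{path}: rows are neither square (n entries) nor lower-triangle"
        )
    np.fill_diagonal(D, 0.0)
    D[D < 0] = np.nan
    return DistanceMatrix(tuple(names), D)
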