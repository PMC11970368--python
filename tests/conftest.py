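"""Shared fixtures and independent reference implementations.

The reference scorers here are written directly from the distance
definition (multiset mismatch fraction, positional comparison for phased
pairs, pairwise deletion) as plain scalar loops, independent of the
package's vectorised path, so they can serve as oracles.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pdistree.io_variants import Call, SiteGenotypes

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independent reference implementation (oracle)


def oracle_site_score(a: Call | None, b: Call | None) -> float | None:
    """Scalar d_l from the definition; None if the pair is unusable here."""
    if a is None or b is None:
        return None
    if len(a.alleles) != len(b.alleles):
        return None  # mixed ploidy: skipped
    p = len(a.alleles)
    if a.phased and b.phased:
        return sum(1 for x, y in zip(a.alleles, b.alleles) if x != y) / p
    # multiset intersection by explicit removal
    remaining = list(b.alleles)
    shared = 0
    for x in a.alleles:
        if x in remaining:
            remaining.remove(x)
            shared += 1
    return 1.0 - shared / p


def oracle_distance_matrix(sites: list[SiteGenotypes], n: int) -> np.ndarray:
    """Naive all-pairs, all-sites double loop with pairwise deletion.

    Returns an n x n matrix with NaN where no site was usable.
    """
    sums = np.zeros((n, n))
    counts = np.zeros((n, n))
    for site in sites:
        g = site.genotypes
        for i in range(n):
            for j in range(i + 1, n):
                d = oracle_site_score(g[i], g[j])
                if d is None:
                    continue
                sums[i, j] += d
                counts[i, j] += 1
    with np.errstate(invalid="ignore"):
        D = sums / counts
    D = np.where(counts == 0, np.nan, D)
    full = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    full[iu] = D[iu]
    full[(iu[1], iu[0])] = D[iu]
    return full


# ---------------------------------------------------------------------------
# random genotype streams


def random_sites(
    rng: np.random.Generator,
    n_samples: int,
    m_sites: int,
    missing_rate: float = 0.1,
    phased_fraction: float = 0.3,
    multiallelic_fraction: float = 0.2,
    haploid_fraction: float = 0.0,
) -> list[SiteGenotypes]:
    """Arbitrary random sites: missing data, multiallelics, mixed phasing."""
    sites = []
    for s in range(m_sites):
        n_alleles = 3 if rng.random() < multiallelic_fraction else 2
        calls = []
        for _ in range(n_samples):
            if rng.random() < missing_rate:
                calls.append(None)
                continue
            if rng.random() < haploid_fraction:
                calls.append(Call((int(rng.integers(n_alleles)),), False))
                continue
            alleles = (
                int(rng.integers(n_alleles)),
                int(rng.integers(n_alleles)),
            )
            phased = bool(rng.random() < phased_fraction)
            calls.append(Call(alleles, phased))
        sites.append(
            SiteGenotypes(chrom="1", pos=s + 1, n_alleles=n_alleles, genotypes=tuple(calls))
        )
    return sites


def write_vcf(sites: list[SiteGenotypes], names: list[str], path) -> None:
    """Serialise SiteGenotypes to a minimal VCF (test-side writer)."""
    alts = {1: ".", 2: "C", 3: "C,T", 4: "C,T,G"}
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for site in sites:
            cols = [
                site.chrom,
                str(site.pos),
                ".",
                "A",
                alts[site.n_alleles],
                ".",
                ".",
                ".",
                "GT",
            ]
            for call in site.genotypes:
                if call is None:
                    cols.append("./.")
                else:
                    sep = "|" if call.phased else "/"
                    cols.append(sep.join(str(a) for a in call.alleles))
            fh.write("\t".join(cols) + "\n")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
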