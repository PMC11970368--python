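# Methods

## The p-distance for genotype data

For individuals *i* and *j*, the distance is the mean per-site
contribution over the sites where both are called:

    D_ij = ( Σ_l d_l ) / L_ij

`d_l` compares the two genotype calls at site *l*. For an **unphased** pair
of ploidy *p*, `d_l` is the multiset mismatch fraction,
`1 − |G_i ∩ G_j| / p`, where the intersection is taken with multiplicity
over the allele tuples. For equal-ploidy diploids this yields exactly
{0, 0.5, 1}: identical genotypes score 0, a homozygote against a
heterozygote sharing one allele scores 0.5, and opposite homozygotes score
1. When **both** calls are phased (`|` in the VCF), alleles are compared
positionally (Hamming fraction), so ordered genotypes CA and AC score 1
despite identical allele content; if either member of the pair is
unphased, the unordered rule applies, because haplotype order is only
meaningful when both calls carry it. Haploid calls score in {0, 1}; the
same formulas generalise to higher ploidy, though ploidy > 2 input is rare
and is handled on a scalar fallback path.

Sites are taken exactly as they appear: no biallelic filtering, no
QUAL/FILTER gating, and no SNP/indel distinction — multiallelic sites and
indels contribute through their genotype indices like any other site.

### Missing data

A call containing any `.` component (including half-calls such as `./1`)
is treated as entirely missing: a partial call cannot be compared under
the exact-match rule without an asymmetric convention, and whole-call
exclusion is conservative. The denominator `L_ij` is per-pair (pairwise
deletion): only sites where *both* members are called count. This keeps
every defined distance in [0, 1]. A pair sharing no usable site has an
undefined distance; it is serialised as `-1.000000` in the matrix and is a
fatal error if a tree is requested, so an unusable matrix can never flow
silently into a phylogeny. Calls of unequal ploidy at one site are
incomparable; the pair-site is skipped, excluded from `L_ij`, and counted
in a diagnostic that the run log reports.

### Streaming and parallelism

Input is read record by record; at most one chunk of sites (default
10,000) is buffered, so resident memory scales with the number of selected
samples, not with the number of variants. Only the upper triangle of
pairs is scored (n(n−1)/2 comparisons per site; total work Θ(n²·m), plus
O(n³) for tree building). Within a chunk, the condensed pair range can be
partitioned across worker threads. Every per-site score is an exact binary
fraction (k/ploidy for ploidy ≤ 2), each pair's chunk subtotal is a
`numpy` sum over the same site ordering regardless of the partitioning,
and workers write disjoint slices of the accumulator, so single- and
multi-worker runs are bit-identical — a property the test suite asserts on
a 50-sample × 100,000-site stream.

## Sequence input

Aligned FASTA (via Biopython) and Phylip files (sequential or interleaved,
relaxed names — strict 10-character truncation rejects most modern files)
are converted to haploid site streams: at each column, the distinct
unambiguous residues define the allele set and each sample carries a
haploid 1-tuple. Gaps (`-`, `.`), unknowns (`N`, `?`, `X`, `*`) and IUPAC
partial-ambiguity codes (R, Y, …) are scored as missing, because a
partially known base cannot be compared exactly without bias. The
resulting distance is then exactly the classical proportion of differing
sites under pairwise deletion, which the tests verify against a direct
column-scan.

## Tree construction

**Neighbor joining** (unrooted; O(n³)) uses the Studier–Keppler form of
the Saitou–Nei criterion, Q(i,j) = (r−2)·D(i,j) − R_i − R_j, with the
standard branch-length and distance-update formulas, ending in a
trifurcating root. When several pairs tie on Q, the lexicographically
smallest condensed index pair is chosen, making output platform- and
order-deterministic. Negative branch lengths are reported as computed
(consistent with common NJ implementations such as `ape::nj`); an
optional clamp sets them to zero. On additive matrices NJ provably
recovers the generating topology and all path lengths; the suite checks
this to 1e-9 on matrices derived from random binary trees, and
cross-checks an arbitrary matrix against scikit-bio's NJ.

**UPGMA** (rooted, ultrametric) merges the closest clusters with
cluster-size-weighted average linkage; node height is half the merge
distance. Heights are cross-checked against SciPy's average-linkage
dendrogram and exact recovery is asserted on random ultrametric matrices.

**Consensus.** The bootstrap summary is a strict-majority consensus:
non-trivial bipartitions occurring in more than the threshold fraction
(default 0.5) of replicate trees are retained — such splits are pairwise
compatible by a counting argument, so they always assemble into a tree —
with support round(100 × frequency) and no branch lengths. Extended
majority-rule (greedy addition of minority splits) is deliberately not
implemented: strict majority is simpler and deterministic. External
consensus programs remain usable via the replicate-tree file (one Newick
per line).

## Site-resampling bootstrap

Each replicate draws `round(ratio × m)` site indices (round-half-even,
minimum 1; default ratio 0.25) uniformly **with replacement** — duplicate
draws keep their multiplicity, as in the ordinary bootstrap — and the
p-distance matrix is re-finalised over exactly the drawn multiset, with
the same per-pair denominators. Draws come from a seeded
`numpy.random.default_rng`, so a (seed, ratio, m, replicates) tuple fully
determines the output; the CLI writes the seed to the run log. A
diagnostic mode replaces the draw with a permutation of all sites, which
at ratio 1 must reproduce the full-data matrix exactly (asserted).
Per-site pair scores are materialised once in a cache of one float and
one flag per pair per site; this trades memory (O(m·n²)) for resampling
speed and is the practical bound on bootstrap problem sizes — for very
large inputs, thin the site set first.

## Synthetic data

The VCF generator plants group structure through a two-parameter site
model chosen for closed-form expectations rather than realism. Each site
is *divergent* with probability δ (a uniformly random nonempty proper
subset of groups takes base allele 1), and each of a sample's two allele
copies equals its group base flipped independently with probability ε.
Writing u = ε(1−ε), a same-group pair's expected per-site distance is
2u(1−u), and the divergent-site expectation follows from enumerating two
Bin(2, ε) allele counts; ε and δ are solved so that E[D] equals the
requested within- and between-group values *exactly*, and the generator
emits that expected matrix alongside the VCF. Phased calls are written
with sorted alleles, which leaves the positional score equal to the
multiset score, and missing calls are excluded pairwise, so neither knob
perturbs E[D]. Defaults (two groups of five, 1,000 sites, within 0.05,
between 0.2, no missingness) describe a modestly differentiated pair of
populations.

What this model does **not** emulate: linkage disequilibrium, allele
frequency spectra, coalescent genealogies, genotyping-error structure, or
indel length variation. Passing tests therefore demonstrate correctness
of the arithmetic and the pipeline, not robustness to the correlation
structure of real resequencing data — on real data, bootstrap supports
will be optimistic to the extent sites are linked.

The alignment generator evolves sequences down a given tree under
Jukes–Cantor (with probability 1 − e^(−4t/3) the base is redrawn
uniformly), so the expected p-distance is the monotone saturation curve
0.75(1 − e^(−4t/3)) of the path length — used for topology-recovery and
convergence tests. Random binary trees with uniform positive branch
lengths supply additive matrices; random increasing-height merges supply
ultrametric ones.

## Numerical and format choices

- Accumulators: float64 sums, int64 counts; chunk merges are exact because
  all site scores are binary fractions.
- Matrix file: square relaxed-Phylip, names left-justified to
  max(10, longest+1) columns, default 6 decimals; the reader also accepts
  lower-triangle input and rejects square input asymmetric beyond the
  printed precision.
- Newick: names containing whitespace or grammar characters are
  single-quoted with quote doubling; internal support values are written
  as internal node labels; the parser tolerates absent branch lengths.
- Test problem sizes (200 random oracle fixtures ≤ 12 × 200; 100
  generated matrices ≤ 20 taxa; one 50 × 100,000 determinism stream;
  10,000-site convergence checks) were chosen to exercise every code path
  at desk scale while keeping the suite around a minute.

## Known limitations

- The bootstrap cache holds all per-site pair scores in memory; no
  two-pass re-streaming mode is implemented.
- Ploidy > 2 comparisons take the scalar path and are slow at scale.
- No model-corrected distances (Jukes–Cantor, Kimura) for genotype input;
  the p-distance is the only metric.
- Tabix/random access and region queries are out of scope; input files
  are always consumed in full.
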