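"""Streaming VCF genotype input.

Reads one or many VCF files (plain, gzip or bgzip -- detected by magic
bytes, not extension) line by line and yields one :class:`SiteGenotypes`
per data record.  Only the GT sub-field is ever inspected; QUAL, FILTER and
INFO are deliberately ignored so that no implicit preprocessing (biallelic
filtering, PASS filtering, SNP/indel distinction) takes place.  Memory held
while streaming is proportional to the number of selected samples, never to
the number of variant records.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import Iterator, NamedTuple, Sequence

from .errors import VcfError

__all__ = [
    "Call",
    "MISSING",
    "SiteGenotypes",
    "SampleSelection",
    "parse_genotype_field",
    "read_sample_list",
    "open_vcf_stream",
    "open_text_auto",
]

#: Sentinel for a missing call (any GT containing a "." component).
MISSING = None


class Call(NamedTuple):
    """One sample's resolved genotype call at one site.

    ``alleles`` is an ordered tuple of allele indices (0 = REF); its length
    is the ploidy of the call.  ``phased`` records whether the VCF used the
    ``|`` separator, which makes the allele order meaningful.
    """

    alleles: tuple[int, ...]
    phased: bool

    @property
    def ploidy(self) -> int:
        return len(self.alleles)


@dataclass(frozen=True)
class SiteGenotypes:
    """One variant record resolved to per-sample calls.

    ``genotypes`` holds one entry per selected sample, in selection order;
    each entry is a :class:`Call` or :data:`MISSING`.  ``n_alleles`` counts
    REF plus ALT alleles, so every non-missing allele index is in
    ``[0, n_alleles)``.
    """

    chrom: str
    pos: int
    n_alleles: int
    genotypes: tuple

    def __post_init__(self) -> None:
        if self.n_alleles < 1:
            raise VcfError(f"site {self.chrom}:{self.pos} has n_alleles < 1")


@dataclass
class SampleSelection:
    """Ordered subset of sample names applied uniformly across input files.

    The selection order defines the row/column order of every downstream
    matrix and the leaf order of every tree.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise VcfError(f"duplicate sample name(s) in selection: {', '.join(dupes)}")
        if not self.names:
            raise VcfError("empty sample selection")

    def resolve(self, header_samples: Sequence[str], source: str) -> list[int]:
        """Map each selected name to its column index in one file's header."""
        lookup = {name: i for i, name in enumerate(header_samples)}
        indices = []
        for name in self.names:
            if name not in lookup:
                raise VcfError(f"sample {name!r} not found in header of {source}")
            indices.append(lookup[name])
        return indices


def read_sample_list(path: str | os.PathLike) -> SampleSelection:
    """Read a sample-subset file: first token of each non-empty, non-# line.

    Extra columns (e.g. a group label) are ignored here; order is preserved
    and duplicates are rejected.
    """
    names: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name = line.split()[0]
            if name in names:
                raise VcfError(f"duplicate sample name {name!r} in {path}")
            names.append(name)
    if not names:
        raise VcfError(f"sample list {path} selects no samples")
    return SampleSelection(tuple(names))


def open_text_auto(path: str | os.PathLike) -> io.TextIOBase:
    """Open a text file, transparently decompressing gzip/bgzip.

    Compression is detected from the two magic bytes, never from the file
    extension (bgzip is a gzip variant, so the same path handles both).
    """
    if not os.path.exists(path):
        raise VcfError(f"input file does not exist: {path}")
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def parse_genotype_field(token: str) -> Call | None:
    """Parse one GT sub-field into a :class:`Call`, or MISSING.

    ``/`` separates unphased alleles, ``|`` phased ones; a bare integer is a
    haploid call.  Any ``.`` component makes the whole call MISSING -- a
    half-called genotype such as ``./1`` carries no usable pair information
    under whole-call comparison, so it is excluded symmetrically.
    """
    if token == "." or token == "./." or token == ".|.":
        return MISSING
    if "|" in token:
        parts = token.split("|")
        phased = True
    else:
        parts = token.split("/")
        phased = False
    alleles = []
    for part in parts:
        if part == ".":
            return MISSING
        try:
            alleles.append(int(part))
        except ValueError:
            raise VcfError(f"unparseable GT allele token {part!r} in {token!r}") from None
    return Call(tuple(alleles), phased)


def _header_samples(fh: io.TextIOBase, path: str) -> tuple[list[str], int]:
    """Consume header lines up to and including #CHROM; return sample names."""
    lineno = 0
    for line in fh:
        lineno += 1
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise VcfError(f"{path}: #CHROM header has no sample columns")
            return fields[9:], lineno
        raise VcfError(f"{path}: line {lineno}: expected ## or #CHROM header, got data")
    raise VcfError(f"{path}: no #CHROM header line found")


def _stream_one_file(
    path: str | os.PathLike, selection: SampleSelection | None
) -> Iterator[SiteGenotypes]:
    path_str = str(path)
    fh = open_text_auto(path)
    # Frequently recurring GT tokens (0/0, 0|1, ...) are memoised per file so
    # the per-call parse cost is a dict lookup on the hot path.
    memo: dict[str, Call | None] = {}
    try:
        samples, lineno = _header_samples(fh, path_str)
        if selection is None:
            selection = SampleSelection(tuple(samples))
        indices = selection.resolve(samples, path_str)
        n_fields_min = 9 + len(samples)
        for line in fh:
            lineno += 1
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise VcfError(
                    f"{path_str}: line {lineno}: malformed record "
                    f"({len(fields)} tab-separated fields, need >= 10)"
                )
            if len(fields) < n_fields_min:
                raise VcfError(
                    f"{path_str}: line {lineno}: {len(fields) - 9} sample columns, "
                    f"header declares {len(samples)}"
                )
            alt = fields[4]
            n_alleles = 1 if alt in (".", "") else 1 + len(alt.split(","))
            fmt = fields[8]
            if fmt == "GT" or fmt.startswith("GT:"):
                gt_slot = 0
            else:
                keys = fmt.split(":")
                try:
                    gt_slot = keys.index("GT")
                except ValueError:
                    raise VcfError(
                        f"{path_str}: line {lineno}: FORMAT {fmt!r} has no GT key"
                    ) from None
            calls = []
            for col in indices:
                token = fields[9 + col]
                if gt_slot:
                    token = token.split(":")[gt_slot]
                elif ":" in token:
                    token = token.split(":", 1)[0]
                try:
                    call = memo[token]
                except KeyError:
                    call = parse_genotype_field(token)
                    memo[token] = call
                if call is not None:
                    for a in call.alleles:
                        if not 0 <= a < n_alleles:
                            raise VcfError(
                                f"{path_str}: line {lineno}: allele index {a} out of "
                                f"range for {n_alleles} alleles"
                            )
                calls.append(call)
            yield SiteGenotypes(
                chrom=fields[0],
                pos=int(fields[1]),
                n_alleles=n_alleles,
                genotypes=tuple(calls),
            )
    finally:
        fh.close()


def vcf_header_samples(path: str | os.PathLike) -> list[str]:
    """Return the sample names declared by a VCF file's #CHROM header."""
    fh = open_text_auto(path)
    try:
        samples, _ = _header_samples(fh, str(path))
        return samples
    finally:
        fh.close()


def open_vcf_stream(
    paths: Sequence[str | os.PathLike] | str | os.PathLike,
    selection: SampleSelection | None = None,
) -> Iterator[SiteGenotypes]:
    """Stream SiteGenotypes from one or more VCF files, concatenated in order.

    With ``selection=None`` all samples of the *first* file are used and
    every subsequent file must contain them.  Sites are yielded in file
    order then line order; no sorting or deduplication is applied, and only
    one record is materialised at a time.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    if not paths:
        raise VcfError("no input VCF paths given")
    if selection is None:
        selection = SampleSelection(tuple(vcf_header_samples(paths[0])))
    for path in paths:
        yield from _stream_one_file(path, selection)
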