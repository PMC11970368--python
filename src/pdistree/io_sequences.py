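"""Aligned FASTA and Phylip ("phy") input.

Alignments are exposed as haploid site streams (:func:`alignment_to_sites`)
so the same genotype-based distance engine serves sequence input: at each
column the distinct unambiguous residues define the allele set and every
sample carries a haploid one-tuple call.  Gaps and ambiguity codes are
treated as missing, since a p-distance is defined only over characters that
can actually be compared.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator

from Bio import SeqIO

from .errors import AlignmentError
from .io_variants import Call, MISSING, SiteGenotypes, open_text_auto

__all__ = [
    "Alignment",
    "read_fasta",
    "read_phy",
    "phy_to_fasta",
    "alignment_to_sites",
    "MISSING_CHARS",
]

#: Characters scored as missing in alignment columns: gaps, unknowns, and
#: IUPAC partial-ambiguity codes (a partially known base cannot be compared
#: under an exact-match rule without biasing the distance).
MISSING_CHARS = frozenset("-.?NX*RYSWKMBDHV")


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: unique names, equal-length upper-case rows."""

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise AlignmentError(f"duplicate sequence name(s): {', '.join(dupes)}")
        if any(not n for n in self.names):
            raise AlignmentError("empty sequence name")
        if not self.rows:
            raise AlignmentError("empty alignment")
        L = len(self.rows[0])
        if L < 1:
            raise AlignmentError("zero-length alignment")
        for name, row in zip(self.names, self.rows):
            if len(row) != L:
                raise AlignmentError(
                    f"sequence {name!r} has length {len(row)}, expected {L}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def subset(self, names: tuple[str, ...]) -> "Alignment":
        """Reorder/subset rows by name; unknown names raise."""
        index = {n: i for i, n in enumerate(self.names)}
        for n in names:
            if n not in index:
                raise AlignmentError(f"sample {n!r} not present in alignment")
        return Alignment(tuple(names), tuple(self.rows[index[n]] for n in names))


def read_fasta(path: str | os.PathLike) -> Alignment:
    """Read an aligned FASTA file (>= 2 records, equal lengths, upper-cased)."""
    names: list[str] = []
    rows: list[str] = []
    with open_text_auto(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            names.append(record.id)
            rows.append(str(record.seq).upper())
    if len(names) < 2:
        raise AlignmentError(f"{path}: FASTA alignment needs >= 2 records, found {len(names)}")
    return Alignment(tuple(names), tuple(rows))


def _clean_seq_chunk(text: str) -> str:
    return "".join(text.split()).upper()


def read_phy(path: str | os.PathLike) -> Alignment:
    """Read a Phylip alignment, sequential or interleaved, with relaxed names.

    Names are the first whitespace-delimited token of each record line (no
    10-character truncation).  A sequential parse is attempted first; if the
    body does not satisfy it, the interleaved layout is tried.
    """
    with open_text_auto(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = [ln for ln in lines if ln.strip()]
    if not body:
        raise AlignmentError(f"{path}: empty file")
    header = body[0].split()
    if len(header) < 2:
        raise AlignmentError(f"{path}: first line must hold two integers (n, L)")
    try:
        n, L = int(header[0]), int(header[1])
    except ValueError:
        raise AlignmentError(f"{path}: non-integer Phylip header {body[0]!r}") from None
    data = body[1:]

    for parser in (_parse_phy_sequential, _parse_phy_interleaved):
        result = parser(data, n, L)
        if result is not None:
            names, rows = result
            return Alignment(tuple(names), tuple(rows))
    raise AlignmentError(
        f"{path}: body does not match header (expected {n} sequences of length {L})"
    )


def _parse_phy_sequential(data: list[str], n: int, L: int):
    names, rows = [], []
    pos = 0
    for _ in range(n):
        if pos >= len(data):
            return None
        tokens = data[pos].split(None, 1)
        name = tokens[0]
        seq = _clean_seq_chunk(tokens[1]) if len(tokens) > 1 else ""
        pos += 1
        while len(seq) < L:
            if pos >= len(data):
                return None
            seq += _clean_seq_chunk(data[pos])
            pos += 1
        if len(seq) != L:
            return None
        names.append(name)
        rows.append(seq)
    if pos != len(data):
        return None
    return names, rows


def _parse_phy_interleaved(data: list[str], n: int, L: int):
    if len(data) < n or len(data) % n != 0:
        return None
    names, rows = [], []
    for line in data[:n]:
        tokens = line.split(None, 1)
        names.append(tokens[0])
        rows.append(_clean_seq_chunk(tokens[1]) if len(tokens) > 1 else "")
    for block_start in range(n, len(data), n):
        for k in range(n):
            rows[k] += _clean_seq_chunk(data[block_start + k])
    if any(len(r) != L for r in rows):
        return None
    return names, rows


def phy_to_fasta(phy_path: str | os.PathLike, fasta_path: str | os.PathLike) -> None:
    """Convert a Phylip alignment to FASTA (the internal phy input route)."""
    aln = read_phy(phy_path)
    with open(fasta_path, "wt", encoding="utf-8") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name}\n{row}\n")


def alignment_to_sites(aln: Alignment) -> Iterator[SiteGenotypes]:
    """Yield one haploid SiteGenotypes per alignment column.

    Allele indices are assigned from the sorted distinct unambiguous
    characters observed in the column; characters in :data:`MISSING_CHARS`
    become MISSING calls.  Columns are labelled chrom="aln", pos=column+1.
    """
    for col in range(aln.length):
        chars = [row[col] for row in aln.rows]
        observed = sorted({c for c in chars if c not in MISSING_CHARS})
        allele_of = {c: i for i, c in enumerate(observed)}
        n_alleles = max(1, len(observed))
        calls = tuple(
            MISSING if c in MISSING_CHARS else Call((allele_of[c],), False)
            for c in chars
        )
        yield SiteGenotypes(chrom="aln", pos=col + 1, n_alleles=n_alleles, genotypes=calls)
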