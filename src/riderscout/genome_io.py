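"""Genome I/O, coordinate-safe sequence access, random-locus sampling and assembly statistics.

All internal coordinates are 0-based half-open; GFF3 emission converts to
1-based inclusive, BED stays 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised on malformed, empty or duplicate-id FASTA input."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over {A, C, G, T, N}, uppercased on load."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _sanitize(raw: str, record_id: str) -> str:
    seq = raw.upper()
    bad = set(seq) - VALID_ALPHABET
    if bad:
        logger.warning(
            "record %s: %d character(s) outside {A,C,G,T,N} (%s) mapped to N",
            record_id,
            sum(seq.count(c) for c in bad),
            ",".join(sorted(bad)),
        )
        seq = "".join(c if c in VALID_ALPHABET else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into a list of :class:`GenomeSequence`.

    Sequences are uppercased; characters outside the alphabet are mapped to N
    with a logged warning. Record order is preserved.

    Raises
    ------
    FastaFormatError
        On an empty file or duplicate record ids.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(GenomeSequence(rec.id, _sanitize(str(rec.seq), rec.id)))
    return out


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 80) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def fetch(genome: Sequence[GenomeSequence], iv: Interval) -> str:
    """Extract the sequence of an interval, reverse-complemented on strand −."""
    by_id = {g.id: g for g in genome}
    try:
        g = by_id[iv.chrom]
    except KeyError:
        raise KeyError(f"chromosome {iv.chrom!r} not in genome") from None
    if iv.end > g.length:
        raise ValueError(f"interval end {iv.end} beyond chromosome length {g.length}")
    s = g.seq[iv.start:iv.end]
    return revcomp(s) if iv.strand == "-" else s


def sample_random_loci(
    genome: Sequence[GenomeSequence],
    n: int,
    length: int,
    strands: Sequence[str],
    seed: int,
    max_n_fraction: float = 0.10,
    max_attempts: int = 1000,
) -> list[str]:
    """Sample ``n`` random loci of ``length`` bp uniformly over all valid starts.

    The chromosome for each draw is chosen with probability proportional to its
    number of valid start positions; ``strands[i]`` is "-" reverse-complements
    draw *i*. Loci with an N fraction above ``max_n_fraction`` are resampled
    (up to ``max_attempts`` times) so assembly gaps are avoided. Fully
    reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(strands) != n:
        raise ValueError("strands must have exactly n entries")
    valid = [(g, g.length - length + 1) for g in genome if g.length >= length]
    if not valid:
        raise ValueError(f"no chromosome of length >= {length}")
    starts = np.array([v for _, v in valid], dtype=np.int64)
    total = int(starts.sum())
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for i in range(n):
        for _ in range(max_attempts):
            flat = int(rng.integers(0, total))
            ci = int(np.searchsorted(np.cumsum(starts), flat, side="right"))
            g, _nv = valid[ci]
            offset = flat - (int(np.cumsum(starts)[ci - 1]) if ci else 0)
            s = g.seq[offset:offset + length]
            if s.count("N") / length <= max_n_fraction:
                break
        out.append(revcomp(s) if strands[i] == "-" else s)
    return out


def n50(lengths: Sequence[int]) -> float:
    """Assembly N50 in megabases.

    Sort lengths in descending order and return the first length whose
    cumulative sum reaches at least half the total, divided by 1e6.
    """
    if len(lengths) == 0:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    csum = np.cumsum(arr)
    idx = int(np.argmax(csum >= csum[-1] * 0.5))
    return float(arr[idx]) / 1_000_000.0


# ---------------------------------------------------------------------------
# GFF3 / BED emission helpers


def gff3_header() -> str:
    return "##gff-version 3\n"


def interval_to_gff3_coords(iv: Interval) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (GFF3 convention)."""
    return iv.start + 1, iv.end


def write_bed6(intervals: Iterable[tuple[Interval, str, float]], path: str | Path) -> None:
    """Write (interval, name, score) triples as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[Interval, str]]:
    """Read BED (>=4 columns used: chrom start end name); extra columns ignored."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FastaFormatError(f"{path}:{ln}: BED line has <3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            out.append((Interval(chrom, start, end, strand), name))
    return out
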