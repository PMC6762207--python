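"""Cross-genome homology screening on BLAST-tabular hit files.

Consumes outfmt-6 style tables produced externally; applies the 50%
identity / 50% query-length filter that defines "family-like" hits, profiles
hit density over the query, classifies LTR-length regimes and confirms hits
by reciprocal top-hit overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .genome_io import Interval

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]


@dataclass(frozen=True)
class HomologHit:
    query_id: str
    subject_id: str
    pident: float
    align_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    species: str = ""

    @property
    def strand(self) -> str:
        return "-" if self.send < self.sstart else "+"


@dataclass(frozen=True)
class RiderLikeFilter:
    """Keep hits with >= ``min_pident`` identity covering at least
    ``min_len_frac`` of the query length."""

    query_len: int
    min_pident: float = 50.0
    min_len_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.query_len <= 0:
            raise ValueError("query_len must be positive")
        if not (0 <= self.min_pident <= 100) or not (0 <= self.min_len_frac <= 1):
            raise ValueError("filter thresholds out of range")


class HitTableFormatError(ValueError):
    pass


def read_hit_table(path: str | Path,
                   species_map: Optional[dict[str, str]] = None) -> list[HomologHit]:
    """Parse a 12-column tab-separated BLAST hit table with validation."""
    hits: list[HomologHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise HitTableFormatError(
                    f"{path}:{ln}: expected 12 columns, got {len(parts)}")
            try:
                pident = float(parts[2])
                align_len = int(parts[3])
                qstart, qend = int(parts[6]), int(parts[7])
                hit = HomologHit(
                    query_id=parts[0], subject_id=parts[1], pident=pident,
                    align_len=align_len, mismatches=int(parts[4]),
                    gap_opens=int(parts[5]), qstart=qstart, qend=qend,
                    sstart=int(parts[8]), send=int(parts[9]),
                    evalue=float(parts[10]), bitscore=float(parts[11]),
                    species=(species_map or {}).get(parts[1], ""),
                )
            except ValueError as exc:
                raise HitTableFormatError(f"{path}:{ln}: {exc}") from exc
            if not (0 <= pident <= 100):
                raise HitTableFormatError(
                    f"{path}:{ln}: pident {pident} outside [0, 100]")
            if not (1 <= qstart <= qend):
                raise HitTableFormatError(
                    f"{path}:{ln}: invalid query range {qstart}-{qend}")
            hits.append(hit)
    return hits


def filter_rider_like(hits: Sequence[HomologHit],
                      f: RiderLikeFilter) -> list[HomologHit]:
    """Apply the identity and length-fraction thresholds."""
    min_len = f.min_len_frac * f.query_len
    return [h for h in hits
            if h.pident >= f.min_pident and h.align_len >= min_len]


def species_counts(hits: Sequence[HomologHit]) -> pd.DataFrame:
    df = pd.DataFrame([{"species": h.species or "unknown"} for h in hits])
    if df.empty:
        return pd.DataFrame(columns=["species", "n_hits"])
    out = df.value_counts("species").reset_index(name="n_hits")
    return out.sort_values(["n_hits", "species"],
                           ascending=[False, True]).reset_index(drop=True)


def coverage_profile(hits: Sequence[HomologHit],
                     query_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-position hit counts over the query, plus the alignment-length
    distribution. Query spans are clipped to [1, query_len]."""
    profile = np.zeros(query_len, dtype=np.int64)
    lengths = []
    for h in hits:
        lo = max(1, min(h.qstart, h.qend))
        hi = min(query_len, max(h.qstart, h.qend))
        if lo <= hi:
            profile[lo - 1:hi] += 1
        lengths.append(h.align_len)
    return profile, np.asarray(lengths, dtype=np.int64)


LONG_LTR_BAND = (350, 450)
SHORT_LTR_BAND = (150, 300)


def classify_ltr_hits(hits: Sequence[HomologHit],
                      f: Optional[RiderLikeFilter] = None) -> dict[str, str]:
    """Label LTR-query hits by alignment-length regime.

    The homology filter (when supplied) is applied first; surviving hits are
    "long_LTR" at 350–450 bp alignment length, "short_LTR" at 150–300 bp,
    otherwise "other".
    """
    pool = filter_rider_like(hits, f) if f is not None else list(hits)
    labels: dict[str, str] = {}
    for idx, h in enumerate(pool):
        if LONG_LTR_BAND[0] <= h.align_len <= LONG_LTR_BAND[1]:
            lab = "long_LTR"
        elif SHORT_LTR_BAND[0] <= h.align_len <= SHORT_LTR_BAND[1]:
            lab = "short_LTR"
        else:
            lab = "other"
        labels[f"{h.subject_id}:{h.sstart}-{h.send}#{idx}"] = lab
    return labels


def reciprocal_confirm(forward_hits: Sequence[HomologHit],
                       reverse_tables: dict[str, Sequence[HomologHit]],
                       rider_loci: Sequence[Interval],
                       top_n: int = 5) -> dict[str, bool]:
    """Confirm each kept forward hit by reciprocal search.

    A hit is confirmed when any of the top ``top_n`` (by bitscore) reverse
    hits of its subject region overlaps a known family locus by >= 1 bp.
    Missing reverse records yield False.
    """
    import logging
    logger = logging.getLogger(__name__)
    out: dict[str, bool] = {}
    for h in forward_hits:
        key = f"{h.subject_id}:{min(h.sstart, h.send)}-{max(h.sstart, h.send)}"
        rev = reverse_tables.get(key)
        if rev is None:
            logger.warning("no reverse hit table for %s", key)
            out[key] = False
            continue
        top = sorted(rev, key=lambda r: -r.bitscore)[:top_n]
        ok = False
        for r in top:
            lo = min(r.sstart, r.send) - 1
            hi = max(r.sstart, r.send)
            for locus in rider_loci:
                if r.subject_id == locus.chrom and lo < locus.end and locus.start < hi:
                    ok = True
                    break
            if ok:
                break
        out[key] = ok
    return out


# ---------------------------------------------------------------------------
# Naive local-alignment scanner for self-contained fixtures (no E-value model)

_LOCAL = Align.PairwiseAligner(mode="local", match_score=1, mismatch_score=-1,
                               open_gap_score=-2, extend_gap_score=-2)


def naive_local_hits(query: str, subject_id: str, subject: str,
                     min_score: int = 30) -> list[HomologHit]:
    """Best local alignment of a query against one subject, reported as a hit
    record. Intended for small synthetic fixtures only; no E-value model."""
    aln = _LOCAL.align(query, subject)
    if len(aln) == 0 or aln.score < min_score:
        return []
    a = aln[0]
    (qblocks, sblocks) = a.aligned
    qs, qe = qblocks[0][0], qblocks[-1][1]
    ss, se = sblocks[0][0], sblocks[-1][1]
    matches = sum(
        sum(1 for x, y in zip(query[t0:t1], subject[s0:s1]) if x == y)
        for (t0, t1), (s0, s1) in zip(qblocks, sblocks))
    cols = max(qe - qs, se - ss)
    return [HomologHit(
        query_id="query", subject_id=subject_id,
        pident=100.0 * matches / cols, align_len=cols,
        mismatches=cols - matches, gap_opens=0,
        qstart=qs + 1, qend=qe, sstart=ss + 1, send=se,
        evalue=0.0, bitscore=float(a.score))]
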