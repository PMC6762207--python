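"""Per-locus epigenomic and genomic-context summaries.

Weighted DNA methylation per cytosine context (CG/CHG/CHH), small-RNA
RPKM by size class (21–22 nt vs 24 nt), chromatin-compartment and
gene-proximity tables, and in-silico PCR copy coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import Interval, revcomp

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def read_cytosine_table(path: str | Path) -> pd.DataFrame:
    """Per-cytosine TSV: chrom, pos (1-based), strand, context, meth_reads,
    total_reads."""
    df = pd.read_csv(path, sep="\t",
                     names=["chrom", "pos", "strand", "context",
                            "meth_reads", "total_reads"],
                     header=0 if _has_header(path) else None)
    if ((df["meth_reads"] > df["total_reads"]) | (df["meth_reads"] < 0)).any():
        raise ValueError("meth_reads must satisfy 0 <= meth <= total")
    return df


def _has_header(path: str | Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.lower().startswith("chrom")


def methylation_summary(records: pd.DataFrame, loci: Sequence[Interval],
                        locus_ids: Optional[Sequence[str]] = None,
                        min_coverage: int = 1) -> pd.DataFrame:
    """Weighted methylation percentage per locus and context.

    Weighted level = 100 × Σ meth / Σ total over cytosines inside the locus
    with coverage >= ``min_coverage``; a context with no qualifying cytosine
    gives NaN (missing), never 0.
    """
    ids = list(locus_ids) if locus_ids is not None else [
        f"{iv.chrom}:{iv.start}-{iv.end}" for iv in loci]
    rows = []
    for lid, iv in zip(ids, loci):
        sub = records[(records["chrom"] == iv.chrom)
                      & (records["pos"] >= iv.start + 1)
                      & (records["pos"] <= iv.end)
                      & (records["total_reads"] >= min_coverage)]
        row: dict[str, object] = {"locus": lid}
        for ctx in CONTEXTS:
            c = sub[sub["context"] == ctx]
            total = c["total_reads"].sum()
            row[f"{ctx}%"] = (100.0 * c["meth_reads"].sum() / total
                              if total > 0 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("locus")


def read_srna_bed(path: str | Path) -> pd.DataFrame:
    """Small-RNA alignments as BED: chrom, start, end[, name, count].

    Read length is end − start; multiplicity defaults to 1 (column 5 used as
    count when numeric)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            p = line.rstrip("\n").split("\t")
            count = 1
            if len(p) > 4:
                try:
                    count = int(float(p[4]))
                except ValueError:
                    count = 1
            rows.append({"chrom": p[0], "start": int(p[1]), "end": int(p[2]),
                         "count": count})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    df["length_nt"] = df["end"] - df["start"]
    return df


DEFAULT_SIZE_CLASSES = {"21-22": (21, 22), "24": (24, 24)}


def sirna_rpkm(reads: pd.DataFrame, loci: Sequence[Interval],
               library_total: int,
               size_classes: dict[str, tuple[int, int]] = DEFAULT_SIZE_CLASSES,
               locus_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """siRNA reads per kb of locus per million mapped reads, per size class.

    A read counts for a locus when it overlaps it by >= 1 bp.
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    ids = list(locus_ids) if locus_ids is not None else [
        f"{iv.chrom}:{iv.start}-{iv.end}" for iv in loci]
    rows = []
    for lid, iv in zip(ids, loci):
        if iv.length <= 0:
            raise ValueError(f"zero-length locus {lid}")
        ov = reads[(reads["chrom"] == iv.chrom)
                   & (reads["start"] < iv.end) & (reads["end"] > iv.start)]
        row: dict[str, object] = {"locus": lid}
        for name, (lo, hi) in size_classes.items():
            c = ov[(ov["length_nt"] >= lo) & (ov["length_nt"] <= hi)]["count"].sum()
            row[name] = float(c) / (iv.length / 1000.0) / (library_total / 1e6)
        rows.append(row)
    return pd.DataFrame(rows).set_index("locus")


# ---------------------------------------------------------------------------
# Genomic context (compartments and gene proximity)


@dataclass
class ContextRow:
    element_id: str
    compartment: str
    gene_within_2kb: bool
    age_class: Optional[str]


def genomic_context(elements: Sequence[tuple[str, Interval, Optional[str]]],
                    compartments: Sequence[tuple[Interval, str]],
                    genes: pd.DataFrame,
                    window: int = 2000) -> pd.DataFrame:
    """Assign each element a chromatin compartment (by midpoint) and a
    gene-within-``window`` flag (boundary-to-boundary distance; overlap = 0).

    ``elements`` are (id, interval, age_class) triples; ``compartments`` are
    labelled intervals tiling each chromosome; ``genes`` has 0-based
    half-open chrom/start/end columns.
    """
    rows = []
    for eid, iv, age_class in elements:
        mid = (iv.start + iv.end) // 2
        comp = "unassigned"
        for civ, label in compartments:
            if civ.chrom == iv.chrom and civ.start <= mid < civ.end:
                comp = label
                break
        if comp == "unassigned":
            logger.warning("element %s midpoint outside all compartments", eid)
        near = False
        gsub = genes[genes["chrom"] == iv.chrom] if not genes.empty else genes
        for _, g in gsub.iterrows():
            dist = max(g["start"] - iv.end, iv.start - g["end"], 0)
            if dist <= window:
                near = True
                break
        rows.append({"element_id": eid, "compartment": comp,
                     "gene_within_2kb": near, "age_class": age_class})
    return pd.DataFrame(rows)


def compartment_summary(context: pd.DataFrame,
                        age_classes: Sequence[str] = ("98-100", "95-98", "85-95"),
                        ) -> pd.DataFrame:
    """Counts per compartment and age class with total percentages
    (one decimal, round-half-up)."""
    total = len(context)
    rows = []
    for comp in context["compartment"].unique():
        sub = context[context["compartment"] == comp]
        row: dict[str, object] = {"compartment": comp}
        for ac in age_classes:
            row[ac] = int((sub["age_class"] == ac).sum())
        row["total_pct"] = round_half_up(100.0 * len(sub) / total, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def gene_proximity_summary(context: pd.DataFrame,
                           arm_label: str = "arm") -> pd.DataFrame:
    """Per-age-class percentage of elements near a gene and on chromosome
    arms (one decimal, round-half-up)."""
    rows = []
    for ac, sub in context.groupby("age_class", sort=True):
        n = len(sub)
        rows.append({
            "age_class": ac,
            "gene_within_2kb_pct": round_half_up(
                100.0 * sub["gene_within_2kb"].sum() / n, 1),
            "arm_pct": round_half_up(
                100.0 * (sub["compartment"] == arm_label).sum() / n, 1),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# In-silico PCR


def _match_positions(target: str, primer: str, max_mismatch: int) -> list[int]:
    """Start positions where the primer matches with <= max_mismatch
    substitutions (no indels)."""
    out = []
    m = len(primer)
    for i in range(len(target) - m + 1):
        mm = 0
        for a, b in zip(target[i:i + m], primer):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            out.append(i)
    return out


def insilico_pcr(target_seqs: dict[str, str], fwd_primer: str, rev_primer: str,
                 max_mismatch: int = 3, max_product: int = 5000,
                 ) -> tuple[dict[str, bool], int]:
    """Which targets would amplify with the given primer pair.

    A target is amplifiable when a forward-primer site on the plus strand is
    followed by a reverse-primer site on the minus strand within
    ``max_product`` bp. The mismatch budget applies per primer; indels are
    not allowed.
    """
    if len(fwd_primer) < 15 or len(rev_primer) < 15:
        raise ValueError("primers must be >= 15 nt")
    rev_site = revcomp(rev_primer)  # plus-strand footprint of the reverse primer
    flags: dict[str, bool] = {}
    for tid, seq in target_seqs.items():
        fpos = _match_positions(seq, fwd_primer, max_mismatch)
        rpos = _match_positions(seq, rev_site, max_mismatch)
        ok = False
        for f in fpos:
            for r in rpos:
                product = r + len(rev_site) - f
                if 0 < product <= max_product and r >= f:
                    ok = True
                    break
            if ok:
                break
        flags[tid] = ok
    return flags, sum(flags.values())
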