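"""Cis-regulatory element scanning and enrichment testing.

LTR promoter regions (U3) carry short stress-responsive motifs — CGCG box,
MYB cores, ABRE-like, CE3, CBF — whose over-representation relative to gene
promoters or to strand-matched random loci is assessed with Fisher's exact
test on per-sequence presence/absence counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from scipy import stats

from .genome_io import GenomeSequence, revcomp, sample_random_loci

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbol(s) {sorted(bad)} in {self.name}")


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    seq_id: str
    start: int  # 1-based
    end: int    # 1-based inclusive
    strand: str


@dataclass(frozen=True)
class ContingencyResult:
    motif_name: str
    fg_with: int
    fg_without: int
    bg_with: int
    bg_without: int
    odds_ratio: float
    p_value: float


def load_motif_catalogue(path: str | Path | None = None) -> list[MotifDef]:
    """Load motif definitions from YAML (the shipped catalogue by default)."""
    if path is None:
        text = resources.files("riderscout.data").joinpath("motifs.yaml").read_text()
    else:
        text = Path(path).read_text()
    entries = yaml.safe_load(text)
    return [MotifDef(e["name"], e["pattern"], e.get("source", "")) for e in entries]


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in pattern.upper()))


def scan_motifs(seqs: Sequence[GenomeSequence], motifs: Sequence[MotifDef],
                strands: str = "forward_only") -> list[MotifHit]:
    """All exact IUPAC matches (overlaps allowed), 1-based inclusive coordinates.

    With ``strands='both'`` minus-strand hits are reported on forward
    coordinates with strand '-'.
    """
    if strands not in ("forward_only", "both"):
        raise ValueError("strands must be 'forward_only' or 'both'")
    hits: list[MotifHit] = []
    for motif in motifs:
        rx = re.compile(f"(?=({_iupac_regex(motif.pattern).pattern}))")
        m_len = len(motif.pattern)
        for g in seqs:
            for m in rx.finditer(g.seq):
                hits.append(MotifHit(motif.name, g.id, m.start() + 1,
                                     m.start() + m_len, "+"))
            if strands == "both":
                n = len(g.seq)
                for m in rx.finditer(revcomp(g.seq)):
                    s_fwd = n - (m.start() + m_len)  # 0-based forward start
                    hits.append(MotifHit(motif.name, g.id, s_fwd + 1,
                                         s_fwd + m_len, "-"))
    return hits


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene features from a GFF3 file (columns chrom, start, end, strand;
    coordinates converted to 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            rows.append({"chrom": parts[0], "start": int(parts[3]) - 1,
                         "end": int(parts[4]), "strand": parts[6]})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def promoter_background(genes: pd.DataFrame, genome: Sequence[GenomeSequence],
                        upstream_len: int = 400, min_len: int = 50) -> list[str]:
    """Promoter sequences: ``upstream_len`` bp upstream of each gene's TSS.

    Plus-strand genes take the window ending just before the gene start;
    minus-strand genes take the reverse complement of the window just after
    the gene end. Windows truncated below ``min_len`` at a chromosome edge
    are skipped.
    """
    if genes.empty:
        raise ValueError("no gene features")
    by_id = {g.id: g for g in genome}
    out: list[str] = []
    for _, gene in genes.iterrows():
        chrom = by_id[gene["chrom"]]
        if gene["strand"] == "+":
            s = max(0, gene["start"] - upstream_len)
            seq = chrom.seq[s:gene["start"]]
        else:
            e = min(chrom.length, gene["end"] + upstream_len)
            seq = revcomp(chrom.seq[gene["end"]:e])
        if len(seq) < min_len:
            continue
        out.append(seq)
    if not out:
        raise ValueError("all promoter windows shorter than the minimum length")
    return out


def _contains(seq: str, motif: MotifDef, strands: str) -> bool:
    rx = _iupac_regex(motif.pattern)
    if rx.search(seq):
        return True
    return strands == "both" and rx.search(revcomp(seq)) is not None


def fisher_test(fg_with: int, fg_without: int, bg_with: int,
                bg_without: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on one 2×2 table.

    Returns ``(odds_ratio, p)``; the p-value sums hypergeometric
    probabilities no larger than the observed table's, and the odds ratio
    gets a 0.5 Haldane correction when any cell is zero.
    """
    _, p = stats.fisher_exact([[fg_with, fg_without], [bg_with, bg_without]],
                              alternative="two-sided")
    if 0 in (fg_with, fg_without, bg_with, bg_without):
        odds = ((fg_with + 0.5) * (bg_without + 0.5)) / (
            (fg_without + 0.5) * (bg_with + 0.5))
    else:
        odds = (fg_with * bg_without) / (fg_without * bg_with)
    return odds, float(min(p, 1.0))


def fisher_enrichment(fg_seqs: Sequence[str], bg_seqs: Sequence[str],
                      motifs: Sequence[MotifDef], count_mode: str = "presence",
                      strands: str = "forward_only") -> list[ContingencyResult]:
    """Per-motif 2×2 enrichment of foreground vs background sequences.

    ``presence`` mode counts sequences containing at least one hit. The
    two-sided exact p sums hypergeometric probabilities no larger than that of
    the observed table; the odds ratio gets a 0.5 Haldane correction when any
    cell is zero.
    """
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background must be non-empty")
    if count_mode not in ("presence", "occurrence"):
        raise ValueError("count_mode must be 'presence' or 'occurrence'")
    results = []
    for motif in motifs:
        if count_mode == "presence":
            fw = sum(_contains(s, motif, strands) for s in fg_seqs)
            bw = sum(_contains(s, motif, strands) for s in bg_seqs)
            fo, bo = len(fg_seqs) - fw, len(bg_seqs) - bw
        else:
            rx = re.compile(f"(?=({_iupac_regex(motif.pattern).pattern}))")
            fw = sum(len(rx.findall(s)) for s in fg_seqs)
            bw = sum(len(rx.findall(s)) for s in bg_seqs)
            fo = sum(len(s) - len(motif.pattern) + 1 for s in fg_seqs) - fw
            bo = sum(len(s) - len(motif.pattern) + 1 for s in bg_seqs) - bw
        odds, p = fisher_test(fw, fo, bw, bo)
        results.append(ContingencyResult(motif.name, fw, fo, bw, bo, odds, p))
    return results


def presence_matrix(seqs: Sequence[GenomeSequence], motifs: Sequence[MotifDef],
                    strands: str = "forward_only") -> pd.DataFrame:
    """Per-sequence motif presence/absence matrix."""
    data = {m.name: [int(_contains(g.seq, m, strands)) for g in seqs]
            for m in motifs}
    return pd.DataFrame(data, index=[g.id for g in seqs])


def enrichment_report(ltr_seqs: Sequence[str],
                      genome: Sequence[GenomeSequence],
                      genes: Optional[pd.DataFrame],
                      motifs: Sequence[MotifDef],
                      element_strands: Optional[Sequence[str]] = None,
                      n_random: int = 1000,
                      seed: int = 0,
                      count_mode: str = "presence") -> dict[str, list[ContingencyResult]]:
    """Run both enrichment approaches.

    Approach 1 tests LTRs against gene-promoter backgrounds (when a gene
    table is supplied); approach 2 against strand-matched random loci sampled
    genome-wide, one per foreground element, ``n_random`` in total.
    """
    report: dict[str, list[ContingencyResult]] = {}
    if genes is not None and not genes.empty:
        promoters = promoter_background(genes, genome)
        report["promoters"] = fisher_enrichment(ltr_seqs, promoters, motifs,
                                                count_mode)
    if element_strands is None:
        element_strands = ["+"] * len(ltr_seqs)
    length = max(len(s) for s in ltr_seqs)
    strands = [element_strands[i % len(element_strands)] for i in range(n_random)]
    random_bg = sample_random_loci(genome, n_random, length, strands, seed)
    report["random"] = fisher_enrichment(ltr_seqs, random_bg, motifs, count_mode)
    return report


def results_to_frame(results: Sequence[ContingencyResult],
                     background_type: str) -> pd.DataFrame:
    return pd.DataFrame([{
        "motif": r.motif_name,
        "fg_with": r.fg_with, "fg_n": r.fg_with + r.fg_without,
        "bg_with": r.bg_with, "bg_n": r.bg_with + r.bg_without,
        "odds_ratio": r.odds_ratio, "p_value": r.p_value,
        "background_type": background_type,
    } for r in results])
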