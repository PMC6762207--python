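"""De novo structural detection of full-length LTR retrotransposons.

An element is called when two near-identical repeats (the LTRs) are found at a
plausible spacing, flanked by a target-site duplication (TSD), beginning/ending
with the canonical TG...CA termini, and carrying a primer-binding site (PBS)
complementary to the 3' end of a host tRNA just inside the 5' LTR.

Detection is seed-and-extend: exact k-mer seeds shared by two genome positions
at LTR-like spacing are chained per diagonal and extended with x-drop scoring;
boundaries are then refined jointly with the TSD/terminal-motif search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from Bio import Align

from .genome_io import GenomeSequence, Interval, gff3_header, revcomp

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class DetectorParams:
    """Structural-search parameter set.

    Defaults are the consistent annotation configuration used for the family
    survey: LTR length 100–5000 bp, start-to-start spacing 4000–30000 bp,
    TSD length 3–20 bp searched in an 80-bp vicinity, x-drop 7, at most one
    terminal-motif mismatch, PBS searched in a 60-bp radius with alignment
    length 8–40 and offset 0–10, quality filtering on and no ORF requirement.
    """

    min_ltr_len: int = 100
    max_ltr_len: int = 5000
    min_ltr_dist: int = 4000
    max_ltr_dist: int = 30000
    min_tsd: int = 3
    max_tsd: int = 20
    vicinity: int = 80
    xdrop: int = 7
    motif_mismatch_max: int = 1
    pbs_radius: int = 60
    pbs_align_len: tuple[int, int] = (8, 40)
    pbs_offset: tuple[int, int] = (0, 10)
    require_quality_filter: bool = True
    min_orfs: int = 0
    seed_kmer: int = 20
    match_score: int = 2
    mismatch_score: int = -2
    gap_score: int = -3
    min_pair_identity: float = 0.80
    overlaps_mode: str = "no"

    def __post_init__(self) -> None:
        if self.min_ltr_len > self.max_ltr_len:
            raise ValueError("min_ltr_len > max_ltr_len")
        if self.min_ltr_dist > self.max_ltr_dist:
            raise ValueError("min_ltr_dist > max_ltr_dist")
        if self.min_tsd > self.max_tsd:
            raise ValueError("min_tsd > max_tsd")
        if not (0 < self.min_pair_identity <= 1):
            raise ValueError("min_pair_identity must be in (0, 1]")
        if self.overlaps_mode not in ("no", "all"):
            raise ValueError("overlaps_mode must be 'no' or 'all'")


@dataclass(frozen=True)
class PbsHit:
    trna_id: str
    offset_from_ltr_end: int
    align_len: int
    align_identity: float
    aligned_trna_segment: str


@dataclass
class RepeatPair:
    """Candidate LTR pair: two same-length ungapped repeat copies."""

    ltr5: Interval
    ltr3: Interval
    identity: float
    score: int = 0


@dataclass
class LtrElement:
    id: str
    location: Interval
    ltr5: Interval
    ltr3: Interval
    ltr_identity: float
    tsd_seq: str = ""
    motif_ok: bool = False
    pbs: Optional[PbsHit] = None
    orf_count: int = 0
    domain_hits: list[str] = field(default_factory=list)
    quality_pass: bool = False
    strand: str = "+"

    @property
    def tsd_len(self) -> int:
        return len(self.tsd_seq)


# ---------------------------------------------------------------------------
# Seed-and-extend repeat-pair search


def _xdrop_extend(seq: str, i: int, j: int, direction: int, p: DetectorParams,
                  limit: int) -> int:
    """Extend the ungapped alignment (seq[i] vs seq[j]) along a diagonal.

    Returns the number of columns extended (the best-scoring prefix before the
    running score fell more than ``xdrop`` below its maximum). ``limit`` caps
    the extension length.
    """
    score = 0
    best = 0
    best_k = 0
    n = len(seq)
    for k in range(1, limit + 1):
        a = i + direction * k
        b = j + direction * k
        if a < 0 or b < 0 or a >= n or b >= n:
            break
        score += p.match_score if seq[a] == seq[b] else p.mismatch_score
        if score > best:
            best, best_k = score, k
        elif best - score > p.xdrop:
            break
    return best_k


def _trim_max_subalignment(seq: str, a: int, d: int, length: int,
                           p: DetectorParams) -> tuple[int, int]:
    """Kadane trim of an ungapped pair alignment to its max-scoring segment."""
    best_sum = cur = 0
    best_lo = best_hi = lo = 0
    for k in range(length):
        s = p.match_score if seq[a + k] == seq[a + d + k] else p.mismatch_score
        if cur <= 0:
            cur, lo = s, k
        else:
            cur += s
        if cur > best_sum:
            best_sum, best_lo, best_hi = cur, lo, k + 1
    return a + best_lo, a + best_hi


def find_repeat_pairs(seq: GenomeSequence, params: DetectorParams) -> list[RepeatPair]:
    """Find candidate LTR pairs on the forward strand of one sequence.

    Exact ``seed_kmer`` seeds shared by two positions at LTR-like spacing are
    grouped per diagonal, chained, extended outward with x-drop scoring and
    trimmed to the maximal-scoring sub-alignment. Pairs are kept when both
    copies have an allowed length, pair identity reaches ``min_pair_identity``
    and the start-to-start distance is within the allowed spacing.
    """
    s = seq.seq
    n = len(s)
    p = params
    k = p.seed_kmer
    if n < p.min_ltr_dist + p.min_ltr_len:
        return []

    lo_sep = max(1, p.min_ltr_dist - p.max_ltr_len)
    hi_sep = p.max_ltr_dist

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        w = s[i:i + k]
        if "N" in w:
            continue
        index.setdefault(w, []).append(i)

    # seeds grouped by diagonal d = p2 - p1
    diagonals: dict[int, list[int]] = {}
    for positions in index.values():
        if len(positions) < 2 or len(positions) > 100:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                if lo_sep <= d <= hi_sep:
                    diagonals.setdefault(d, []).append(positions[ai])

    candidates: list[RepeatPair] = []
    for d, starts in diagonals.items():
        starts.sort()
        # chain seeds on one diagonal that lie within one LTR length of each other
        chains: list[list[int]] = [[starts[0]]]
        for pos in starts[1:]:
            if pos - chains[-1][-1] <= p.max_ltr_len:
                chains[-1].append(pos)
            else:
                chains.append([pos])
        for chain in chains:
            a0, a1 = chain[0], chain[-1] + k
            left = _xdrop_extend(s, a0, a0 + d, -1, p, limit=p.max_ltr_len)
            right = _xdrop_extend(s, a1 - 1, a1 - 1 + d, +1, p, limit=p.max_ltr_len)
            a, b = a0 - left, a1 + right
            if b + d > n:
                b = n - d
            a, b = _trim_max_subalignment(s, a, d, b - a, p)
            length = b - a
            if not (p.min_ltr_len <= length <= p.max_ltr_len):
                continue
            if not (p.min_ltr_dist <= d <= p.max_ltr_dist):
                continue
            matches = sum(1 for i in range(a, b) if s[i] == s[i + d])
            identity = matches / length
            if identity < p.min_pair_identity:
                continue
            score = matches * p.match_score + (length - matches) * p.mismatch_score
            candidates.append(RepeatPair(
                ltr5=Interval(seq.id, a, b),
                ltr3=Interval(seq.id, a + d, b + d),
                identity=identity,
                score=score,
            ))

    # merge overlapping extensions: keep the best-scoring candidate per locus
    candidates.sort(key=lambda c: (-c.score, c.ltr5.start))
    kept: list[RepeatPair] = []
    for c in candidates:
        dup = False
        for kc in kept:
            if (c.ltr5.start < kc.ltr3.end and kc.ltr5.start < c.ltr3.end):
                dup = True
                break
        if not dup:
            kept.append(c)
    kept.sort(key=lambda c: c.ltr5.start)
    return kept


# ---------------------------------------------------------------------------
# Boundary refinement: TSD and terminal motif


def _motif_mismatches(element_seq: str) -> int:
    mm = sum(1 for a, b in zip(element_seq[:2], "TG") if a != b)
    mm += sum(1 for a, b in zip(element_seq[-2:], "CA") if a != b)
    return mm


def detect_tsd(seq: GenomeSequence, pair: RepeatPair, params: DetectorParams,
               ) -> tuple[str, int, int]:
    """Search the boundary vicinities for a target-site duplication.

    All exact duplications of length ``min_tsd``..``max_tsd`` between the
    vicinity window spanning the 5' boundary and the one spanning the 3'
    boundary are enumerated; each defines an adjusted element whose TSD copies
    immediately flank it. Candidates are scored ``length − 0.5 × total
    boundary adjustment`` (a duplication that contradicts the repeat
    alignment's boundary evidence pays for every base it moves), and those
    whose adjusted termini preserve the TG...CA motif (within
    ``motif_mismatch_max``) are preferred. Among equals: longest duplication,
    then smallest adjustment, then leftmost. Returns ``(tsd_seq, start,
    end)`` with the refined element boundaries (unchanged boundaries and ""
    when nothing is found).
    """
    s = seq.seq
    p = params
    half = p.vicinity // 2
    s0, e0 = pair.ltr5.start, pair.ltr3.end

    win5 = range(max(p.max_tsd, s0 - half), min(len(s), s0 + half + 1))
    win3 = range(max(0, e0 - half), min(len(s) - p.min_tsd, e0 + half + 1))

    best = None       # (score, L, -adjust, -start) maximized
    best_no_motif = None
    for L in range(p.max_tsd, p.min_tsd - 1, -1):
        upstream: dict[str, list[int]] = {}
        for cs in win5:
            if cs - L < 0:
                continue
            upstream.setdefault(s[cs - L:cs], []).append(cs)
        for ce in win3:
            if ce + L > len(s):
                continue
            w = s[ce:ce + L]
            if "N" in w or w not in upstream:
                continue
            for cs in upstream[w]:
                if ce - cs < p.min_ltr_dist // 2:
                    continue
                adjust = abs(cs - s0) + abs(ce - e0)
                key = (L - 0.5 * adjust, L, -adjust, -cs)
                if best_no_motif is None or key > best_no_motif[0]:
                    best_no_motif = (key, w, cs, ce)
                if _motif_mismatches(s[cs:ce]) <= p.motif_mismatch_max:
                    if best is None or key > best[0]:
                        best = (key, w, cs, ce)
    chosen = best if best is not None else best_no_motif
    if chosen is None:
        return "", s0, e0
    _, tsd, cs, ce = chosen
    return tsd, cs, ce


def check_terminal_motif(seq: GenomeSequence, element: LtrElement,
                         params: DetectorParams) -> bool:
    """True iff the element's TG...CA termini hold within the mismatch budget."""
    body = seq.seq[element.location.start:element.location.end]
    return _motif_mismatches(body) <= params.motif_mismatch_max


# ---------------------------------------------------------------------------
# PBS detection

_PBS_ALIGNER = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def detect_pbs(seq: GenomeSequence, element: LtrElement,
               trnas: Sequence[GenomeSequence], params: DetectorParams,
               ) -> Optional[PbsHit]:
    """Screen the window just downstream of the 5' LTR for a primer-binding site.

    For each tRNA the reverse complement of its 3'-terminal 40 nt is locally
    aligned (match +1, mismatch −1, gap −2) against the ``pbs_radius`` bp
    inside the element following the 5' LTR. The best hit with alignment
    length and offset in range and identity >= 0.8 is reported; ties broken by
    higher identity, then lower offset, then tRNA id.
    """
    if not trnas:
        return None
    p = params
    w_start = element.ltr5.end
    window = seq.seq[w_start:w_start + p.pbs_radius]
    if not window:
        return None
    lo_len, hi_len = p.pbs_align_len
    lo_off, hi_off = p.pbs_offset
    best: Optional[tuple[tuple, PbsHit]] = None
    for trna in sorted(trnas, key=lambda t: t.id):
        probe = revcomp(trna.seq[-40:])
        try:
            alns = _PBS_ALIGNER.align(window, probe)
            aln = alns[0]
        except (ValueError, IndexError):
            continue
        tgt, qry = aln.aligned
        if len(tgt) == 0:
            continue
        cols = 0
        matches = 0
        for (ts, te), (qs, qe) in zip(tgt, qry):
            cols += te - ts
            matches += sum(1 for a, b in zip(window[ts:te], probe[qs:qe]) if a == b)
        # gap columns inside the local alignment
        span_t = tgt[-1][1] - tgt[0][0]
        span_q = qry[-1][1] - qry[0][0]
        cols += (span_t - cols) + (span_q - cols)
        offset = int(tgt[0][0])
        align_len = int(span_t)
        identity = matches / cols if cols else 0.0
        if not (lo_len <= align_len <= hi_len):
            continue
        if not (lo_off <= offset <= hi_off):
            continue
        if identity < 0.8:
            continue
        key = (-identity, offset, trna.id)
        hit = PbsHit(trna.id, offset, align_len, identity,
                     probe[qry[0][0]:qry[-1][1]])
        if best is None or key < best[0]:
            best = (key, hit)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# ORF counting (6-frame, ATG to stop, no splicing)


def count_orfs(element_seq: str, min_len: int = 300) -> int:
    total = 0
    for strand_seq in (element_seq, revcomp(element_seq)):
        for frame in range(3):
            i = frame
            start = None
            while i + 3 <= len(strand_seq):
                codon = strand_seq[i:i + 3]
                if start is None and codon == "ATG":
                    start = i
                elif start is not None and codon in STOP_CODONS:
                    if i + 3 - start >= min_len:
                        total += 1
                    start = None
                i += 3
    return total


# ---------------------------------------------------------------------------
# Overlap resolution and full pipeline


def resolve_overlaps(elements: list[LtrElement], mode: str = "no") -> list[LtrElement]:
    """Resolve mutually overlapping calls.

    ``all`` keeps everything; ``no`` greedily keeps, within any overlapping
    set, the element with the highest LTR identity (ties: longer, then
    leftmost). Output sorted by start.
    """
    if mode == "all":
        return sorted(elements, key=lambda e: e.location.start)
    order = sorted(elements, key=lambda e: (-e.ltr_identity,
                                            -(e.location.length),
                                            e.location.start))
    kept: list[LtrElement] = []
    for el in order:
        if any(el.location.chrom == k.location.chrom
               and el.location.start < k.location.end
               and k.location.start < el.location.end for k in kept):
            continue
        kept.append(el)
    kept.sort(key=lambda e: (e.location.chrom, e.location.start))
    return kept


def _annotate_strand(seq: GenomeSequence, trnas: Sequence[GenomeSequence],
                     params: DetectorParams) -> list[LtrElement]:
    elements = []
    for pair in find_repeat_pairs(seq, params):
        tsd, s, e = detect_tsd(seq, pair, params)
        # refinement moves the outer LTR edges; inner edges come from the alignment
        ltr5 = Interval(seq.id, s, max(s + 1, pair.ltr5.end))
        ltr3 = Interval(seq.id, min(pair.ltr3.start, e - 1), e)
        el = LtrElement(
            id="", location=Interval(seq.id, s, e),
            ltr5=ltr5, ltr3=ltr3,
            ltr_identity=pair.identity, tsd_seq=tsd,
        )
        el.motif_ok = check_terminal_motif(seq, el, params)
        el.pbs = detect_pbs(seq, el, trnas, params)
        el.orf_count = count_orfs(seq.seq[s:e])
        el.quality_pass = bool(tsd) and el.motif_ok and el.pbs is not None
        elements.append(el)
    return elements


def _mirror_element(el: LtrElement, chrom_len: int) -> LtrElement:
    def flip(iv: Interval) -> Interval:
        return Interval(iv.chrom, chrom_len - iv.end, chrom_len - iv.start, "-")

    return replace(
        el,
        location=flip(el.location),
        ltr5=flip(el.ltr3),
        ltr3=flip(el.ltr5),
        strand="-",
    )


def annotate_genome(genome: Sequence[GenomeSequence],
                    trnas: Sequence[GenomeSequence] = (),
                    params: DetectorParams | None = None,
                    domain_table: Optional[dict[str, list[str]]] = None,
                    ) -> list[LtrElement]:
    """Run the full structural-annotation pipeline over a genome.

    Both strands are scanned (minus via reverse complement with coordinates
    mapped back); plus/minus calls at one locus are merged preferring the
    orientation that passes the quality filter. When the quality filter is on,
    only passing elements are reported. Ids are ``<chrom>_<rank>`` by position.
    """
    params = params or DetectorParams()
    out: list[LtrElement] = []
    for chrom in genome:
        plus = _annotate_strand(chrom, trnas, params)
        rc = GenomeSequence(chrom.id, revcomp(chrom.seq))
        minus = [_mirror_element(el, chrom.length)
                 for el in _annotate_strand(rc, trnas, params)]
        merged: list[LtrElement] = []
        for el in sorted(plus + minus,
                         key=lambda e: (-int(e.quality_pass), -e.ltr_identity,
                                        0 if e.strand == "+" else 1)):
            if any(el.location.start < m.location.end
                   and m.location.start < el.location.end
                   and _reciprocal_overlap(el.location, m.location) >= 0.8
                   for m in merged):
                continue
            merged.append(el)
        if params.require_quality_filter:
            merged = [el for el in merged
                      if el.quality_pass and el.orf_count >= params.min_orfs]
        merged = resolve_overlaps(merged, params.overlaps_mode)
        for rank, el in enumerate(merged, 1):
            el.id = f"{chrom.id}_{rank}"
            if domain_table and el.id in domain_table:
                el.domain_hits = list(domain_table[el.id])
        out.extend(merged)
    return out


def _reciprocal_overlap(a: Interval, b: Interval) -> float:
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return min(ov / a.length, ov / b.length)


# ---------------------------------------------------------------------------
# GFF3 emission


def elements_to_gff3(elements: Sequence[LtrElement]) -> str:
    """Render elements as GFF3 (1-based inclusive coordinates)."""
    lines = [gff3_header().rstrip("\n")]
    for el in elements:
        attrs = [f"ID={el.id}", f"ltr_identity={el.ltr_identity:.4f}",
                 f"quality={'PASS' if el.quality_pass else 'FAIL'}"]
        if el.tsd_seq:
            attrs.append(f"tsd={el.tsd_seq}")
        if el.pbs:
            attrs.append(f"pbs_trna={el.pbs.trna_id}")
        if el.domain_hits:
            attrs.append("domains=" + ",".join(el.domain_hits))
        loc = el.location
        lines.append("\t".join([
            loc.chrom, "riderscout", "LTR_retrotransposon",
            str(loc.start + 1), str(loc.end), f"{el.ltr_identity:.4f}",
            el.strand, ".", ";".join(attrs)]))
        for name, iv in (("five_prime", el.ltr5), ("three_prime", el.ltr3)):
            lines.append("\t".join([
                iv.chrom, "riderscout", "long_terminal_repeat",
                str(iv.start + 1), str(iv.end), ".", el.strand, ".",
                f"ID={el.id}_ltr_{name};Parent={el.id}"]))
        if el.tsd_seq:
            t = el.tsd_len
            lines.append("\t".join([
                loc.chrom, "riderscout", "target_site_duplication",
                str(loc.start - t + 1), str(loc.start), ".", el.strand, ".",
                f"ID={el.id}_tsd5;Parent={el.id}"]))
            lines.append("\t".join([
                loc.chrom, "riderscout", "target_site_duplication",
                str(loc.end + 1), str(loc.end + t), ".", el.strand, ".",
                f"ID={el.id}_tsd3;Parent={el.id}"]))
    return "\n".join(lines) + "\n"


def write_gff3(elements: Sequence[LtrElement], path: str | Path) -> None:
    Path(path).write_text(elements_to_gff3(elements))
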