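"""Synthetic genomes with planted LTR retrotransposons and ground-truth tables.

The generator emulates, at desk scale, the substrate the annotation pipeline
runs on: an i.i.d. nucleotide background at a tomato-like GC content with
planted full-length elements (LTR pair + PBS + internal region with a long
ORF + polypurine tract), solo LTRs and 5'-truncated copies. Each planted
element's realized LTR-pair identity is recomputed by direct alignment after
mutation, never taken from the nominal divergence.

Mutations are substitutions only by default, so realized identity follows a
clean binomial model; an indel mode exists for robustness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cre_enrichment import MotifDef
from .family_evolution import global_identity
from .genome_io import GenomeSequence, gff3_header, revcomp, write_fasta

STOP_CODONS = ("TAA", "TAG", "TGA")

#: synthetic initiator-methionine-like tRNA used for PBS construction; the
#: 3'-terminal bases are what the PBS complements.
DEFAULT_TRNA = GenomeSequence(
    "tRNA-Met",
    "GCCGCGGTAGCTCAGTTGGTTAGAGCGTCGTGCTCATAACGCGAAGGTCGCGGGTTCGAGCCCCGTCCGCGGCACCA",
)


@dataclass
class SynthSpec:
    """Parameters of one synthetic genome build."""

    genome_len: int = 200_000
    gc: float = 0.35
    n_intact: int = 12
    n_solo_ltr: int = 3
    n_truncated: int = 2
    ltr_len: int = 400
    internal_len: int = 5000
    divergence_per_element: Optional[Sequence[float]] = None
    tsd_len_range: tuple[int, int] = (4, 6)
    pbs_trna: GenomeSequence = DEFAULT_TRNA
    pbs_offset: int = 2
    pbs_len: int = 18
    planted_motifs: list[tuple[MotifDef, int]] = field(default_factory=list)
    primer_sites: Optional[tuple[str, str, Sequence[int]]] = None
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.divergence_per_element is not None:
            if any(not (0 <= d <= 0.2) for d in self.divergence_per_element):
                raise ValueError("divergences must lie in [0, 0.2]")
        footprint = (self.n_intact * (2 * self.ltr_len + self.internal_len + 100)
                     + self.n_solo_ltr * self.ltr_len
                     + self.n_truncated * (self.ltr_len + self.internal_len // 2))
        if footprint >= self.genome_len / 2:
            raise ValueError("total planted footprint must stay below half "
                             "the genome length")


@dataclass
class TruthRecord:
    kind: str  # intact | solo_ltr | truncated
    element_id: str
    chrom: str = ""
    start: int = -1
    end: int = -1
    strand: str = "+"
    pair_identity: float = float("nan")
    tsd_seq: str = ""
    pbs_offset: int = -1
    motif_positions: dict[str, int] = field(default_factory=dict)
    motifs_intact: dict[str, bool] = field(default_factory=dict)
    primer_mismatches: tuple[int, int] = (-1, -1)
    seq: str = ""


def random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            indel_rate: float = 0.0) -> str:
    if rate <= 0 and indel_rate <= 0:
        return seq
    bases = "ACGT"
    out = []
    for c in seq:
        if indel_rate > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(bases[rng.integers(4)])  # insertion before c
        if rng.random() < rate:
            choices = [b for b in bases if b != c]
            out.append(choices[rng.integers(3)])
        else:
            out.append(c)
    return "".join(out)


def _random_orf(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    codons = []
    while len(codons) < n_codons:
        c = random_seq(rng, 3, gc)
        if c not in STOP_CODONS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def _plant(seq: str, insert: str, pos: int) -> str:
    if pos + len(insert) > len(seq):
        raise ValueError("planted feature exceeds sequence length")
    return seq[:pos] + insert + seq[pos + len(insert):]


def build_element(spec: SynthSpec, divergence: float,
                  rng: np.random.Generator,
                  element_id: str = "element",
                  primer_mismatches: tuple[int, int] = (0, 0),
                  total_len: Optional[int] = None) -> TruthRecord:
    """Construct one full-length element and its truth record.

    Layout: LTR — offset — PBS — stuffer with a long ORF — polypurine tract —
    LTR. Both LTR copies are independently point-mutated at rate
    ``divergence/2`` (expected pair identity ≈ 1 − divergence); TG/CA termini
    are re-enforced after mutation; planted motifs are written before
    mutation and their post-mutation status recorded. The realized pair
    identity is recomputed by direct alignment.
    """
    if not (0 <= divergence <= 0.2):
        raise ValueError("divergence must lie in [0, 0.2]")
    ltr = random_seq(rng, spec.ltr_len, spec.gc)
    for mdef, off in spec.planted_motifs:
        if off + len(mdef.pattern) > spec.ltr_len:
            raise ValueError(f"motif {mdef.name} offset exceeds LTR length")
        concrete = "".join(  # pick one concrete base per IUPAC symbol
            {"V": "A", "B": "G", "N": "A", "R": "A", "Y": "C", "S": "C",
             "W": "A", "K": "G", "M": "A", "D": "A", "H": "A"}.get(c, c)
            for c in mdef.pattern)
        ltr = _plant(ltr, concrete, off)
    ltr = "TG" + ltr[2:-2] + "CA"

    pbs = revcomp(spec.pbs_trna.seq[-spec.pbs_len:])
    orf = _random_orf(rng, 120, spec.gc)
    ppt = "AG" * 8
    fixed = (spec.ltr_len * 2 + spec.pbs_offset + spec.pbs_len
             + len(orf) + len(ppt))
    stuffer_len = ((total_len - fixed) if total_len is not None
                   else spec.internal_len - len(orf))
    if stuffer_len < 0:
        raise ValueError("requested total length too short for the layout")
    half = stuffer_len // 2
    internal = (random_seq(rng, spec.pbs_offset, spec.gc) + pbs
                + random_seq(rng, half, spec.gc) + orf
                + random_seq(rng, stuffer_len - half, spec.gc) + ppt)

    rate = divergence / 2.0
    ltr5 = _mutate(rng, ltr, rate, spec.indel_rate)
    ltr3 = _mutate(rng, ltr, rate, spec.indel_rate)
    ltr5 = "TG" + ltr5[2:-2] + "CA"
    ltr3 = "TG" + ltr3[2:-2] + "CA"

    seq = ltr5 + internal + ltr3
    mism = (-1, -1)
    if spec.primer_sites is not None:
        fwd, rev, _ = spec.primer_sites
        fwd_m, rev_m = primer_mismatches
        fwd_site = _with_mismatches(rng, fwd, fwd_m)
        rev_site = _with_mismatches(rng, revcomp(rev), rev_m)
        fpos = spec.ltr_len + spec.pbs_offset + spec.pbs_len + 10
        rpos = fpos + len(fwd) + 120
        seq = _plant(seq, fwd_site, fpos)
        seq = _plant(seq, rev_site, rpos)
        mism = (fwd_m, rev_m)

    ident = global_identity(ltr5, ltr3, "plus").identity
    motif_pos = {}
    motifs_ok = {}
    for mdef, off in spec.planted_motifs:
        motif_pos[mdef.name] = off
        from .cre_enrichment import _iupac_regex
        motifs_ok[mdef.name] = bool(
            _iupac_regex(mdef.pattern).fullmatch(seq[off:off + len(mdef.pattern)]))
    return TruthRecord(kind="intact", element_id=element_id,
                       pair_identity=ident, pbs_offset=spec.pbs_offset,
                       motif_positions=motif_pos, motifs_intact=motifs_ok,
                       primer_mismatches=mism, seq=seq)


def _with_mismatches(rng: np.random.Generator, site: str, n_mm: int) -> str:
    if n_mm <= 0:
        return site
    pos = rng.choice(len(site), size=n_mm, replace=False)
    out = list(site)
    for p in pos:
        out[p] = [b for b in "ACGT" if b != out[p]][rng.integers(3)]
    return "".join(out)


def build_element_in_class(spec: SynthSpec, lo: float, hi: float,
                           rng: np.random.Generator, element_id: str,
                           max_tries: int = 200) -> TruthRecord:
    """Build an element whose *realized* pair identity lies in [lo, hi)."""
    for _ in range(max_tries):
        d = float(rng.uniform(max(0.0, 1 - hi), min(0.2, 1 - lo)))
        rec = build_element(spec, d, rng, element_id)
        if lo <= rec.pair_identity < hi:
            return rec
    raise RuntimeError("could not realize an element in the identity class")


def build_genome(spec: SynthSpec) -> tuple[list[GenomeSequence], pd.DataFrame]:
    """Build a genome with planted intact elements, solo LTRs and truncated
    copies at non-overlapping positions; fully reproducible from the seed.

    Returns the genome (one chromosome, id "chr1") and the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    divergences = (list(spec.divergence_per_element)
                   if spec.divergence_per_element is not None
                   else [float(x) for x in rng.uniform(0.0, 0.10, spec.n_intact)])
    primer_mm = (list(spec.primer_sites[2]) if spec.primer_sites is not None
                 else [0] * spec.n_intact)

    inserts: list[TruthRecord] = []
    for i in range(spec.n_intact):
        d = divergences[i % len(divergences)] if divergences else 0.0
        mm = (primer_mm[i % len(primer_mm)], 0)
        inserts.append(build_element(spec, d, rng, f"intact_{i + 1}",
                                     primer_mismatches=mm))
    for i in range(spec.n_solo_ltr):
        ltr = "TG" + random_seq(rng, spec.ltr_len - 4, spec.gc) + "CA"
        inserts.append(TruthRecord(kind="solo_ltr",
                                   element_id=f"solo_{i + 1}", seq=ltr))
    for i in range(spec.n_truncated):
        rec = build_element(spec, 0.02, rng, f"trunc_{i + 1}")
        cut = len(rec.seq) // 2
        inserts.append(TruthRecord(kind="truncated",
                                   element_id=f"trunc_{i + 1}",
                                   seq=rec.seq[cut:]))

    background = random_seq(rng, spec.genome_len, spec.gc)
    # non-overlapping insertion points in background coordinates, kept at
    # least 300 bp apart so flank windows never touch a neighbouring feature
    margin = 300
    positions: list[int] = []
    for _ in range(len(inserts)):
        for _attempt in range(10_000):
            p = int(rng.integers(margin, spec.genome_len - margin))
            if all(abs(p - q) >= margin for q in positions):
                positions.append(p)
                break
        else:
            raise RuntimeError("could not place features without overlap")

    order = np.argsort(positions)
    parts: list[str] = []
    cursor = 0
    out_pos = 0
    for idx in order:
        rec = inserts[idx]
        p = positions[idx]
        parts.append(background[cursor:p])
        out_pos += p - cursor
        cursor = p
        strand = "+" if rng.random() < 0.5 else "-"
        body = rec.seq if strand == "+" else revcomp(rec.seq)
        tsd = ""
        if rec.kind in ("intact", "solo_ltr"):
            tsd_len = int(rng.integers(spec.tsd_len_range[0],
                                       spec.tsd_len_range[1] + 1))
            tsd = random_seq(rng, tsd_len, spec.gc)
        parts.append(tsd)
        out_pos += len(tsd)
        rec.chrom = "chr1"
        rec.start = out_pos
        rec.end = out_pos + len(body)
        rec.strand = strand
        rec.tsd_seq = tsd
        parts.append(body)
        out_pos += len(body)
        parts.append(tsd)
        out_pos += len(tsd)
    parts.append(background[cursor:])
    genome = [GenomeSequence("chr1", "".join(parts))]

    truth = pd.DataFrame([{
        "kind": r.kind, "element_id": r.element_id, "chrom": r.chrom,
        "start": r.start, "end": r.end, "strand": r.strand,
        "pair_identity": r.pair_identity, "tsd_seq": r.tsd_seq,
        "pbs_offset": r.pbs_offset if r.kind == "intact" else -1,
        "motif_positions": ";".join(f"{k}:{v}" for k, v in r.motif_positions.items()),
        "primer_mm_fwd": r.primer_mismatches[0],
        "primer_mm_rev": r.primer_mismatches[1],
    } for r in inserts])
    return genome, truth


def reference_like_element(seed: int = 0, total_len: int = 4867,
                           ltr_len: int = 400) -> TruthRecord:
    """A synthetic stand-in for a reference element: ``total_len`` bp with
    MYB-core motifs CTGTTG and CTGTTA planted at 1-based LTR positions 176
    and 204. Synthetic — not the GenBank accession."""
    spec = SynthSpec(
        ltr_len=ltr_len,
        planted_motifs=[(MotifDef("MYBCORE_G", "CTGTTG"), 175),
                        (MotifDef("MYBCORE_A", "CTGTTA"), 203),
                        (MotifDef("CGCGBOXAT", "VCGCGB"), 88)],
        n_intact=1, n_solo_ltr=0, n_truncated=0,
    )
    rng = np.random.default_rng(seed)
    for _ in range(50):
        rec = build_element(spec, 0.0, rng, "reference_synthetic",
                            total_len=total_len)
        ltr = rec.seq[:ltr_len]
        # the planted MYB cores must be the first occurrences in the LTR
        if ltr.find("CTGTTG") == 175 and ltr.find("CTGTTA") == 203:
            return rec
    raise RuntimeError("could not realize the stand-in reference element")


def family_from_reference(reference: str, divergences: Sequence[float],
                          rng: np.random.Generator) -> dict[str, str]:
    """Diverged copies of one reference sequence (for clustering/family tests)."""
    return {f"copy_{i + 1}": _mutate(rng, reference, d)
            for i, d in enumerate(divergences)}


def write_outputs(genome: list[GenomeSequence], truth: pd.DataFrame,
                  prefix: str | Path) -> None:
    prefix = Path(prefix)
    write_fasta(genome, prefix.with_suffix(".fasta"))
    truth.to_csv(prefix.with_suffix(".truth.tsv"), sep="\t", index=False)
    with open(prefix.with_suffix(".truth.gff3"), "w") as fh:
        fh.write(gff3_header())
        for _, r in truth.iterrows():
            if r["start"] < 0:
                continue
            ftype = {"intact": "LTR_retrotransposon", "solo_ltr": "solo_LTR",
                     "truncated": "truncated_LTR_retrotransposon"}[r["kind"]]
            fh.write("\t".join([
                r["chrom"], "riderscout_synth", ftype,
                str(r["start"] + 1), str(r["end"]), ".", r["strand"], ".",
                f"ID={r['element_id']}"]) + "\n")
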