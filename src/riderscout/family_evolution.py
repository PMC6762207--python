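"""Family clustering, LTR-divergence dating and neighbour-joining phylogeny.

Family membership follows the centroid-clustering convention of greedy
length-sorted clustering at a global-identity threshold (0.85 by default).
Insertion ages come from the molecular clock t = d / (2r): after insertion the
two LTRs of one element diverge independently, so the pairwise divergence d
accumulates at twice the per-lineage substitution rate r.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
from Bio import Align

from .genome_io import revcomp

#: average substitution rate for tomato, substitutions per site per year
DEFAULT_RATE = 6.96e-9

AGE_CLASSES = ("98-100", "95-98", "85-95")


@dataclass(frozen=True)
class AlignmentIdentity:
    matches: int
    columns: int
    strand: str = "+"

    @property
    def identity(self) -> float:
        return self.matches / self.columns


@dataclass(frozen=True)
class AgeEstimate:
    element_id: str
    ltr_identity: float
    rate_r: float = DEFAULT_RATE

    @property
    def divergence(self) -> float:
        return 1.0 - self.ltr_identity

    @property
    def age_years(self) -> float:
        return self.divergence / (2.0 * self.rate_r)

    @property
    def age_my(self) -> float:
        return self.age_years / 1e6

    @property
    def age_class(self) -> Optional[str]:
        return classify_identity(self.ltr_identity)


@dataclass
class Cluster:
    centroid_id: str
    member_ids: list[str]
    member_strands: list[str]


def classify_identity(identity: float) -> Optional[str]:
    """Age class from LTR identity; None below the family floor of 0.85."""
    if identity >= 0.98:
        return "98-100"
    if identity >= 0.95:
        return "95-98"
    if identity >= 0.85:
        return "85-95"
    return None


# ---------------------------------------------------------------------------
# Global identity

_GLOBAL_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=2,
    mismatch_score=-2,
    open_gap_score=-10,
    extend_gap_score=-1,
)


def _identity_plus(a: str, b: str) -> AlignmentIdentity:
    aln = _GLOBAL_ALIGNER.align(a, b)[0]
    tgt, qry = aln.aligned
    if len(tgt) == 0:
        return AlignmentIdentity(0, max(len(a), len(b)))
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(tgt, qry):
        aligned_cols += te - ts
        matches += sum(1 for x, y in zip(a[ts:te], b[qs:qe]) if x == y)
    # internal gap columns count; terminal overhangs do not
    span_t = tgt[-1][1] - tgt[0][0]
    span_q = qry[-1][1] - qry[0][0]
    columns = aligned_cols + (span_t - aligned_cols) + (span_q - aligned_cols)
    return AlignmentIdentity(matches, max(columns, 1))


def global_identity(a: str, b: str, strand_mode: str = "plus") -> AlignmentIdentity:
    """Global alignment identity (match +2, mismatch −2, gap open −10,
    extend −1); identity = matches / columns excluding terminal-gap columns.

    Terminal gaps are scored in the dynamic programme (a fully free-end-gap
    objective lets unrelated sequences degenerate to short high-identity
    overlaps) but excluded from the identity denominator, so length
    differences at the ends do not dilute the identity of the aligned core.
    ``strand_mode='both'`` also tries the reverse complement of ``b`` and
    returns the better strand."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    fwd = _identity_plus(a, b)
    if strand_mode == "plus":
        return fwd
    if strand_mode != "both":
        raise ValueError("strand_mode must be 'plus' or 'both'")
    rev = _identity_plus(a, revcomp(b))
    if rev.identity > fwd.identity:
        return AlignmentIdentity(rev.matches, rev.columns, "-")
    return fwd


# ---------------------------------------------------------------------------
# Greedy centroid clustering


def cluster_greedy(seqs: dict[str, str] | Sequence[tuple[str, str]],
                   threshold: float = 0.85,
                   strand_mode: str = "both") -> list[Cluster]:
    """Greedy length-sorted centroid clustering.

    Sequences (a mapping or (id, seq) pairs) are processed in order of
    decreasing length (input order on ties); each query joins the first
    existing centroid whose global identity reaches the threshold, otherwise
    founds a new cluster.
    """
    if not isinstance(seqs, dict):
        pairs = list(seqs)
        ids = [i for i, _ in pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        seqs = dict(pairs)
    ids = list(seqs)
    order = sorted(range(len(ids)), key=lambda i: (-len(seqs[ids[i]]), i))
    clusters: list[Cluster] = []
    for i in order:
        sid = ids[i]
        placed = False
        for cl in clusters:
            ident = global_identity(seqs[cl.centroid_id], seqs[sid], strand_mode)
            if ident.identity >= threshold:
                cl.member_ids.append(sid)
                cl.member_strands.append(ident.strand)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(sid, [sid], ["+"]))
    return clusters


def assign_family(element_seqs: dict[str, str], reference_seq: str,
                  threshold: float = 0.85) -> list[str]:
    """Ids of elements whose full-element global identity to the reference
    (both strands) is strictly above the threshold."""
    if not reference_seq:
        raise ValueError("reference sequence must be non-empty")
    return [eid for eid, seq in element_seqs.items()
            if global_identity(reference_seq, seq, "both").identity > threshold]


# ---------------------------------------------------------------------------
# Dating


def date_element(element_id: str, ltr5_seq: str, ltr3_seq: str,
                 rate_r: float = DEFAULT_RATE,
                 correction: str = "p") -> AgeEstimate:
    """Insertion-age estimate from 5'/3' LTR divergence.

    Identity comes from the plus-strand global alignment; divergence is the
    p-distance 1 − identity (``correction='jc'`` applies a Jukes–Cantor
    multiple-hit correction instead); age = divergence / (2 r).
    """
    ident = global_identity(ltr5_seq, ltr3_seq, "plus").identity
    if correction == "jc":
        p = 1.0 - ident
        if p >= 0.75:
            raise ValueError("JC correction undefined for p >= 0.75")
        ident = 1.0 + 0.75 * math.log1p(-4.0 * p / 3.0)
    elif correction != "p":
        raise ValueError("correction must be 'p' or 'jc'")
    return AgeEstimate(element_id, ident, rate_r)


# ---------------------------------------------------------------------------
# Tamura–Nei (TN93) distance


def tn93_distance(a: str, b: str) -> float:
    """TN93 distance between two aligned equal-length sequences.

    Gap/N columns are dropped pairwise. Returns ``inf`` on saturation (any
    logarithm argument <= 0).
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    pairs = [(x, y) for x, y in zip(a.upper(), b.upper())
             if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    if n == 0:
        raise ValueError("no comparable sites")
    counts = {c: 0.0 for c in "ACGT"}
    p1 = p2 = q = 0  # A<->G transitions, C<->T transitions, transversions
    for x, y in pairs:
        counts[x] += 0.5
        counts[y] += 0.5
        if x == y:
            continue
        if {x, y} == {"A", "G"}:
            p1 += 1
        elif {x, y} == {"C", "T"}:
            p2 += 1
        else:
            q += 1
    gA, gC, gG, gT = (counts[c] / n for c in "ACGT")
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = p1 / n, p2 / n, q / n
    if gA * gG == 0 or gC * gT == 0 or gR * gY == 0:
        # degenerate composition: fall back to the defined terms only
        return math.inf if (P1 or P2 or Q) else 0.0
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return math.inf
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


# ---------------------------------------------------------------------------
# Neighbour joining


def nj_tree(distances: np.ndarray, labels: Sequence[str]) -> str:
    """Classic Saitou–Nei neighbour joining.

    Q-matrix minimization with ties broken by the lexicographically smallest
    label pair; negative branch lengths are clamped to zero with the deficit
    moved to the sibling branch. Returns an unrooted Newick string with branch
    lengths at 6 decimals.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and labels disagree")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes = [f"{lab}" for lab in labels]  # newick fragment per active node
    names = list(labels)                  # tie-break keys
    d = d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                qij = (m - 2) * sub[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((names[active[i]], names[active[j]])))
                cand = (qij, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        ai, aj = active[i], active[j]
        li = 0.5 * sub[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = sub[i, j] - li
        # clamp negatives, moving the deficit to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = len(nodes)
        nodes.append(f"({nodes[ai]}:{li:.6f},{nodes[aj]}:{lj:.6f})")
        names.append(min(names[ai], names[aj]))
        newrow = np.zeros(new + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (ai, aj):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[ai, k] + d[aj, k] - d[ai, aj])
        active = [k for k in active if k not in (ai, aj)] + [new]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    branches = [li, lj, lk]
    for idx in range(3):
        if branches[idx] < 0:
            deficit = branches[idx]
            branches[idx] = 0.0
            others = [o for o in range(3) if o != idx]
            branches[others[0]] += deficit / 2
            branches[others[1]] += deficit / 2
    return (f"({nodes[i]}:{branches[0]:.6f},{nodes[j]}:{branches[1]:.6f},"
            f"{nodes[k]}:{branches[2]:.6f});")


def patristic_distances(newick: str) -> tuple[np.ndarray, list[str]]:
    """Leaf-to-leaf path-length matrix from a Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return out, labels
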