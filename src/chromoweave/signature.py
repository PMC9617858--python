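"""Junction sequence signatures from soft-clipped short reads.

For each breakpoint, soft-clipped reads (>= 10 clipped bases, MAPQ >= 20)
near the called position are split into an L group (aligned to the left of
the breakpoint, clipped on the right) and an R group (aligned to the right,
clipped on the left).  The fetch window starts at 10 bp and doubles up to
10 kb for any empty side.

The signed distance between the median clip reference positions of the two
groups is the InDel size at the junction (requiring >= 3 reads clipped at one
identical reference position per side).  Microhomology is measured by locally
aligning the 50 bp source consensus (25 aligned + 25 clipped bases around the
median clip position) against the 25 bp aligned consensus at the target
breakend, under the scoring +2 match / -1 mismatch or gap open / -0.1 gap
extension.  A perfect alignment starting exactly at the clip boundary
(position 26) marks a blunt junction; a start shifted left by h marks h bases
of junction homology; imperfect alignments are probed for template-
independent insertions by aligning the 50 bp clipped consensus instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median_low

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ClippedRead:
    """One soft-clipped alignment relevant to a breakpoint."""

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int  # exclusive
    clip_side: str  # left | right
    clip_len: int
    mapq: int
    aligned_seq: str  # read bases aligned to the reference
    clipped_seq: str  # soft-clipped read bases, junction-proximal first

    @property
    def clip_pos(self) -> int:
        """Reference position of the clip (alignment end for right clips,
        alignment start for left clips)."""
        return self.ref_end if self.clip_side == "right" else self.ref_start


@dataclass
class JunctionSignature:
    adjacency_id: str
    indel: float | None  # bp; R median - L median; None = NA
    homology: int | None
    insertion: int | None
    final_homology: int | None  # homology + insertion, the combined junction length
    blunt: bool
    n_l: int
    n_r: int
    qc: str  # PASS or reason


# ---------------------------------------------------------------------------
# Read fetching
# ---------------------------------------------------------------------------

def iter_clipped_reads(sam_path, min_clip: int = 10, min_mapq: int = 20):
    """Extract soft-clipped read records from a SAM file."""
    import pysam

    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for read in sam:
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            cigar = read.cigartuples or []
            if not cigar:
                continue
            seq = read.query_sequence or ""
            # leading soft clip
            if cigar[0][0] == 4 and cigar[0][1] >= min_clip:
                clen = cigar[0][1]
                yield ClippedRead(
                    read_id=read.query_name,
                    chrom=read.reference_name,
                    ref_start=read.reference_start,
                    ref_end=read.reference_end,
                    clip_side="left",
                    clip_len=clen,
                    mapq=read.mapping_quality,
                    aligned_seq=seq[clen:],
                    clipped_seq=seq[:clen][::-1],  # junction-proximal first
                )
            if cigar[-1][0] == 4 and cigar[-1][1] >= min_clip:
                clen = cigar[-1][1]
                yield ClippedRead(
                    read_id=read.query_name,
                    chrom=read.reference_name,
                    ref_start=read.reference_start,
                    ref_end=read.reference_end,
                    clip_side="right",
                    clip_len=clen,
                    mapq=read.mapping_quality,
                    aligned_seq=seq[:len(seq) - clen],
                    clipped_seq=seq[len(seq) - clen:],
                )


def fetch_clipped(reads, chrom: str, pos: int, start_window: int = 10,
                  max_window: int = 10_000):
    """Split clipped reads near a breakpoint into (L, R) groups.

    L reads are clipped on the right with clip position near the breakpoint
    (their alignment lies left of it); R reads mirror this.  The window
    doubles from ``start_window`` up to ``max_window`` for any side still
    empty."""
    cands_l = [r for r in reads if r.chrom == chrom and r.clip_side == "right"]
    cands_r = [r for r in reads if r.chrom == chrom and r.clip_side == "left"]

    def within(group, window):
        return [r for r in group if abs(r.clip_pos - pos) <= window]

    l_group: list[ClippedRead] = []
    r_group: list[ClippedRead] = []
    window = start_window
    while True:
        if not l_group:
            l_group = within(cands_l, window)
        if not r_group:
            r_group = within(cands_r, window)
        if (l_group and r_group) or window >= max_window:
            break
        window = min(window * 2, max_window)
    return l_group, r_group


# ---------------------------------------------------------------------------
# InDel size
# ---------------------------------------------------------------------------

def _median_clip_pos(group, min_shared: int = 3):
    """Median clip reference position, or None unless >= min_shared reads are
    clipped at one identical reference position."""
    if not group:
        return None
    positions = [r.clip_pos for r in group]
    counts: dict[int, int] = {}
    for p in positions:
        counts[p] = counts.get(p, 0) + 1
    if max(counts.values()) < min_shared:
        return None
    return median_low(sorted(positions))


def indel_size(l_group, r_group, min_shared: int = 3):
    """Signed genomic distance (R median - L median) between the clip
    positions of the two read groups; positive values are reference bases
    absent from the junction.  NA (None) unless both sides have >= 3 reads
    clipped at one identical position."""
    lm = _median_clip_pos(l_group, min_shared)
    rm = _median_clip_pos(r_group, min_shared)
    if lm is None or rm is None:
        return None
    return rm - lm


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus(columns: list[dict[str, int]]) -> str:
    """Per-column majority base; ties and uncovered columns give N."""
    out = []
    for col in columns:
        if not col:
            out.append("N")
            continue
        best = max(col.values())
        winners = [b for b, c in col.items() if c == best]
        out.append(winners[0] if len(winners) == 1 else "N")
    return "".join(out)


def group_consensus(group: list[ClippedRead], flank: int = 25):
    """(aligned consensus, clipped consensus) around the group's median clip
    position: ``flank`` aligned bases adjacent to the clip and up to
    2 * flank clipped bases, both junction-proximal first for the clipped
    part ordering used by the homology test."""
    med = _median_clip_pos(group, min_shared=1)
    aligned_cols = [dict() for _ in range(flank)]
    clipped_cols = [dict() for _ in range(2 * flank)]
    for r in group:
        if r.clip_pos != med:
            continue
        if r.clip_side == "right":
            al = r.aligned_seq[-flank:]
            al = al.rjust(flank, "N")[::-1]  # position 0 = base adjacent to the clip
        else:
            al = r.aligned_seq[:flank].ljust(flank, "N")
        clip = r.clipped_seq[: 2 * flank]
        for i, b in enumerate(al):
            if b != "N":
                aligned_cols[i][b] = aligned_cols[i].get(b, 0) + 1
        for i, b in enumerate(clip):
            if b != "N":
                clipped_cols[i][b] = clipped_cols[i].get(b, 0) + 1
    al_cons = consensus(aligned_cols)
    if group and group[0].clip_side == "right":
        al_cons = al_cons[::-1]  # restore left-to-right reference order
    return al_cons, consensus(clipped_cols)


# ---------------------------------------------------------------------------
# Local alignment (+2 / -1 / -0.1 affine)
# ---------------------------------------------------------------------------

MATCH = 2.0
MISMATCH = -1.0
GAP_OPEN = -1.0  # first gap column
GAP_EXTEND = -0.1  # each additional gap column


def local_align(a: str, b: str):
    """Smith-Waterman local alignment under the junction scoring scheme.

    Returns (score, a_start, b_start, aligned_length) with 1-based start
    positions; ties resolved toward the lowest a_start, then b_start.
    Empty input gives score 0.
    """
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return 0.0, 0, 0, 0
    NEG = -1e18
    H = np.zeros((na + 1, nb + 1))
    E = np.full((na + 1, nb + 1), NEG)  # gap in a (consuming b)
    F = np.full((na + 1, nb + 1), NEG)  # gap in b (consuming a)
    # traceback: (matrix, i, j) origin; 0 = stop
    back = {}
    best = (0.0, None)
    for i in range(1, na + 1):
        ai = a[i - 1]
        for j in range(1, nb + 1):
            sub = MATCH if ai == b[j - 1] and ai != "N" else MISMATCH
            E[i, j] = max(H[i, j - 1] + GAP_OPEN, E[i, j - 1] + GAP_EXTEND)
            F[i, j] = max(H[i - 1, j] + GAP_OPEN, F[i - 1, j] + GAP_EXTEND)
            diag = H[i - 1, j - 1] + sub
            h = max(0.0, diag, E[i, j], F[i, j])
            H[i, j] = h
            if h > 0:
                if h == diag:
                    back[(i, j)] = ("H", i - 1, j - 1)
                elif h == E[i, j]:
                    back[(i, j)] = ("E", i, j - 1)
                else:
                    back[(i, j)] = ("F", i - 1, j)
    # choose the best cell; ties -> trace each and prefer lowest a_start, b_start
    best_score = H.max()
    if best_score <= 0:
        return 0.0, 0, 0, 0
    cells = np.argwhere(H == best_score)

    def trace(i, j):
        end_i, end_j = i, j
        while (i, j) in back and H[i, j] > 0:
            _, pi, pj = back[(i, j)]
            if pi == i and pj == j:
                break
            i, j = pi, pj
            if H[i, j] == 0 and (i, j) not in back:
                break
        return i + 1, j + 1, max(end_i - i, end_j - j)

    starts = sorted(trace(int(i), int(j)) for i, j in cells)
    a_start, b_start, length = starts[0]
    return float(best_score), a_start, b_start, length


def is_perfect(score: float, target: str) -> bool:
    """All target bases matched with no mismatch or gap."""
    return score == MATCH * len(target)


# ---------------------------------------------------------------------------
# Junction homology
# ---------------------------------------------------------------------------

def junction_homology(source_full: str, source_clipped: str, target_aligned: str,
                      flank: int = 25):
    """Homology / insertion call for one junction direction.

    ``source_full`` is the 50 bp source consensus (aligned flank + clipped
    flank), ``source_clipped`` the 50 bp clipped consensus, and
    ``target_aligned`` the 25 bp aligned consensus at the target breakend.
    Returns (homology_len, insertion_len, blunt) or (None, None, False) when
    the consensus material is insufficient.
    """
    if len(source_full) < 2 * flank or len(target_aligned) < flank:
        return None, None, False
    score, a_start, _, _ = local_align(source_full, target_aligned)
    if is_perfect(score, target_aligned):
        expected_start = flank + 1  # clip boundary, 1-based
        shift = expected_start - a_start
        if shift == 0:
            return 0, 0, True
        if shift > 0:
            return shift, 0, False
        # perfect alignment starting right of the boundary: untemplated bases
        return 0, -shift, False
    score2, a2_start, _, _ = local_align(source_clipped, target_aligned)
    if is_perfect(score2, target_aligned):
        return 0, a2_start - 1, False
    return None, None, False


def _target_consensus(l_group, r_group, side: str, flank: int = 25):
    """Aligned consensus presented in junction order for the target breakend.

    head side: the fused segment starts at the position -> R-group consensus
    read left-to-right.  tail side: the fused segment ends at the position ->
    L-group aligned consensus, reverse-complemented so the junction-proximal
    base comes first.
    """
    if side == "head":
        if not r_group:
            return None
        al, _ = group_consensus(r_group, flank)
        return al
    if not l_group:
        return None
    al, _ = group_consensus(l_group, flank)
    return revcomp(al)


def _source_consensus(l_group, r_group, side: str, flank: int = 25):
    """(aligned+clipped 50-mer, clipped 50-mer) for the source breakend.

    tail side: reads run rightward off the segment ending at the breakpoint
    -> L group (right-clipped).  head side: R group, reverse-complemented so
    the consensus still reads aligned-then-clipped across the junction.
    """
    if side == "tail":
        if not l_group:
            return None, None
        al, clip = group_consensus(l_group, flank)
        return al + clip[: flank], clip[: 2 * flank]
    if not r_group:
        return None, None
    al, clip = group_consensus(r_group, flank)
    # R-group clipped bases are stored junction-proximal first (already the
    # reverse of read order); complement to cross the junction in source sense
    clip_rc = clip.translate(_COMP)
    al_rc = revcomp(al)
    return al_rc + clip_rc[: flank], clip_rc[: 2 * flank]


def junction_signatures(sam_path, adjacencies, min_clip: int = 10,
                        min_mapq: int = 20, min_shared: int = 3,
                        flank: int = 25) -> list[JunctionSignature]:
    """Full signature table: per adjacency, the InDel size at the first
    breakend and the homology/insertion call from its first (source) to its
    second (target) breakend."""
    reads = list(iter_clipped_reads(sam_path, min_clip=min_clip, min_mapq=min_mapq))
    out = []
    for adj in adjacencies:
        l1, r1 = fetch_clipped(reads, adj.bnd1.chrom, adj.bnd1.pos)
        l2, r2 = fetch_clipped(reads, adj.bnd2.chrom, adj.bnd2.pos)
        indel = indel_size(l1, r1, min_shared=min_shared)
        src_full, src_clip = _source_consensus(l1, r1, adj.bnd1.side, flank)
        tgt = _target_consensus(l2, r2, adj.bnd2.side, flank)
        qc = "PASS"
        if src_full is None or tgt is None:
            hom = ins = None
            blunt = False
            qc = "no_reads_on_one_side"
        else:
            hom, ins, blunt = junction_homology(src_full, src_clip, tgt, flank)
            if hom is None:
                qc = "no_perfect_alignment"
        n_l = len([r for r in l1 if r.clip_pos == _median_clip_pos(l1, 1)]) if l1 else 0
        n_r = len([r for r in r1 if r.clip_pos == _median_clip_pos(r1, 1)]) if r1 else 0
        out.append(
            JunctionSignature(
                adjacency_id=adj.id,
                indel=indel,
                homology=hom,
                insertion=ins,
                final_homology=(hom + ins) if hom is not None else None,
                blunt=blunt,
                n_l=n_l,
                n_r=n_r,
                qc=qc,
            )
        )
    return out


def write_signature_tsv(signatures, path) -> None:
    with open(path, "w") as fh:
        fh.write("adjacency_id\tindel\thomology\tinsertion\tfinal_homology\tblunt\tn_L\tn_R\tqc\n")
        for s in signatures:
            def na(x):
                return "NA" if x is None else str(x)
            fh.write(
                f"{s.adjacency_id}\t{na(s.indel)}\t{na(s.homology)}\t{na(s.insertion)}\t"
                f"{na(s.final_homology)}\t{str(s.blunt).lower()}\t{s.n_l}\t{s.n_r}\t{s.qc}\n"
            )
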