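"""Grouping scaffolds into derivative chromosomes and ordering them by a
permutation score on the recomposed Hi-C map.

Scaffolds that share flagged ectopic Hi-C signal are assumed to belong to the
same derivative chromosome (union-find over flagged grid tiles).  For a group
with exactly two telomere-bearing scaffolds and N <= 5 members, the two
telomeric scaffolds fix the ends (telomere outward) and all orders and
orientations of the middle scaffolds are enumerated: (N-2)! * 2^(N-2)
candidates.  Each candidate is scored on its recomposed map: the map is
partitioned into tiles by the underlying fragments, the Hi-C signal at pixel
(i, j) is weighted by its distance |i - j| to the main diagonal, and the
weighted values are summed in the four w x w corners of every tile over all
unordered fragment pairs.  A correct reconstruction concentrates signal at
the diagonal, so the candidate with the *lowest* score is selected.

The corner window w is 5, reduced to the tile extent when a dimension is
smaller; corners of small tiles may overlap, in which case overlapping pixels
are counted in each corner term they fall in (the formula is applied
literally).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np

from chromoweave.hic import (
    BinFragment,
    ContactMatrix,
    DecayModel,
    ectopic_score,
    layout_bin_index,
    make_bin_fragment,
)
from chromoweave.reconstruction import FORWARD, INVERTED, DerivativeLayout


class GroupingError(ValueError):
    pass


@dataclass
class ScaffoldGroup:
    scaffolds: list[DerivativeLayout]
    telomeric_end_count: int
    evidence: list[tuple[str, str]]  # (fragment id, fragment id) of flagged tiles


@dataclass
class CandidateLayout:
    layout: DerivativeLayout
    score: float


def _count_telomeric_ends(scaffold: DerivativeLayout) -> int:
    left, right = scaffold.telomeric_ends()
    return int(left) + int(right)


def group_scaffolds(scaffolds: list[DerivativeLayout], matrix: ContactMatrix,
                    decay: DecayModel, threshold: float = 3.0,
                    min_bins: int = 4) -> list[ScaffoldGroup]:
    """Union-find over scaffolds: two scaffolds link iff any fragment of one
    and any fragment of the other share a flagged ectopic grid tile."""
    owner: dict[str, int] = {}
    frag_bins: dict[str, BinFragment] = {}
    for si, sc in enumerate(scaffolds):
        for frag, _ in sc.members:
            if frag.id in owner:
                raise GroupingError(f"fragment {frag.id} present in two scaffolds")
            owner[frag.id] = si
            frag_bins[frag.id] = make_bin_fragment(matrix, frag.chrom, frag.start, frag.end)

    parent = list(range(len(scaffolds)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    evidence: dict[int, list] = {i: [] for i in range(len(scaffolds))}
    fids = sorted(owner)
    links = []
    for a_pos, fa in enumerate(fids):
        for fb in fids[a_pos + 1:]:
            if owner[fa] == owner[fb]:
                continue
            _, flagged = ectopic_score(
                matrix, decay, frag_bins[fa], frag_bins[fb],
                threshold=threshold, min_bins=min_bins,
            )
            if flagged:
                links.append((fa, fb))
                union(owner[fa], owner[fb])

    for fa, fb in links:
        evidence[find(owner[fa])].append((fa, fb))

    groups = []
    roots: dict[int, list[int]] = {}
    for i in range(len(scaffolds)):
        roots.setdefault(find(i), []).append(i)
    for root, members in sorted(roots.items()):
        scs = [scaffolds[i] for i in members]
        groups.append(
            ScaffoldGroup(
                scaffolds=scs,
                telomeric_end_count=sum(_count_telomeric_ends(s) for s in scs),
                evidence=evidence.get(root, []),
            )
        )
    return groups


def _orient(scaffold: DerivativeLayout, flip: bool) -> list:
    return scaffold.reversed_().members if flip else list(scaffold.members)


def enumerate_layouts(group: ScaffoldGroup, max_components: int = 5):
    """All candidate derivative layouts of a scaffold group.

    Requires exactly two telomeric ends over the group and N <= max
    components; the two telomere-bearing scaffolds sit at the ends oriented
    telomere-outward, middle scaffolds take every order and orientation:
    exactly (N-2)! * 2^(N-2) candidates.
    """
    scaffolds = group.scaffolds
    n = len(scaffolds)
    if group.telomeric_end_count != 2:
        raise GroupingError(
            f"group has {group.telomeric_end_count} telomeric ends; "
            f"permutation requires exactly 2"
        )
    if n > max_components:
        raise GroupingError(f"group of {n} scaffolds exceeds limit of {max_components}")

    telomeric = [s for s in scaffolds if _count_telomeric_ends(s) >= 1]
    if len(telomeric) != 2:
        raise GroupingError("the two telomeric ends must lie on two different scaffolds")
    middles = [s for s in scaffolds if _count_telomeric_ends(s) == 0]

    def key(s: DerivativeLayout):
        f = s.members[0][0]
        return (f.chrom, f.start)

    left, right = sorted(telomeric, key=key)
    # orient the end scaffolds telomere-outward
    if not left.telomeric_ends()[0]:
        left = left.reversed_()
    if not right.telomeric_ends()[1]:
        right = right.reversed_()

    count = 0
    for perm in itertools.permutations(middles):
        for flips in itertools.product([False, True], repeat=len(middles)):
            members = list(left.members)
            for s, flip in zip(perm, flips):
                members.extend(_orient(s, flip))
            members.extend(right.members)
            count += 1
            yield DerivativeLayout(
                name=f"candidate_{count}", members=members, completeness="complete"
            )
    expected = math.factorial(max(n - 2, 0)) * 2 ** max(n - 2, 0)
    assert count == expected, (count, expected)


def tile_subscore(m: np.ndarray, s1: int, e1: int, s2: int, e2: int, w: int = 5) -> float:
    """Four-corner diagonal-distance-weighted sum of a tile.

    ``s``/``e`` are inclusive bin indices of the two fragments in the
    recomposed map ``m``; the window is reduced per-dimension to the tile
    extent and overlapping corner pixels are double-counted.
    """
    n = m.shape[0]
    if not (0 <= s1 <= e1 < n and 0 <= s2 <= e2 < n):
        raise GroupingError(f"tile indices ({s1},{e1},{s2},{e2}) out of range for {n} bins")
    w1 = min(w, e1 - s1 + 1)
    w2 = min(w, e2 - s2 + 1)

    def corner(r0, r1, c0, c1):
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        weights = np.abs(rows[:, None] - cols[None, :])
        return float((weights * m[r0:r1 + 1, c0:c1 + 1]).sum())

    return (
        corner(s1, s1 + w1 - 1, s2, s2 + w2 - 1)
        + corner(s1, s1 + w1 - 1, e2 - w2 + 1, e2)
        + corner(e1 - w1 + 1, e1, s2, s2 + w2 - 1)
        + corner(e1 - w1 + 1, e1, e2 - w2 + 1, e2)
    )


def layout_fragment_spans(matrix: ContactMatrix, layout: DerivativeLayout):
    """Inclusive (start, end) bin spans of each bin-aligned fragment in the
    layout's recomposed map, plus the recomposed dense map itself."""
    idx = layout_bin_index(matrix, layout)
    m_re = matrix.dense()[np.ix_(idx, idx)]
    spans = []
    cursor = 0
    for frag, _ in layout.members:
        b0, b1, sub = matrix.fragment_bins(frag.chrom, frag.start, frag.end)
        if sub:
            continue
        nb = b1 - b0
        spans.append((cursor, cursor + nb - 1))
        cursor += nb
    return m_re, spans


def layout_score(matrix: ContactMatrix, layout: DerivativeLayout, w: int = 5) -> float:
    """Permutation score: sum of tile subscores over all unordered fragment
    pairs of the layout's recomposed map.  Lower is better."""
    m_re, spans = layout_fragment_spans(matrix, layout)
    total = 0.0
    for p in range(len(spans)):
        s1, e1 = spans[p]
        for q in range(p + 1, len(spans)):
            s2, e2 = spans[q]
            total += tile_subscore(m_re, s1, e1, s2, e2, w=w)
    return total


def select_best(candidates, matrix: ContactMatrix, w: int = 5):
    """Score all candidates and return (best, ranked table).

    The ranked table lists (layout, score) ascending; ties on the minimum are
    broken by canonical layout ordering (fragment id/orientation signature)
    and reported via the returned tie flag.
    """
    scored = [CandidateLayout(c, layout_score(matrix, c, w=w)) for c in candidates]
    if not scored:
        raise GroupingError("no candidates to select from")
    scored.sort(key=lambda cl: (cl.score, cl.layout.signature()))
    tie = len(scored) > 1 and scored[0].score == scored[1].score
    return scored[0], scored, tie


def write_ranked_tsv(ranked: list[CandidateLayout], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tscore\tlayout\n")
        for rank, cl in enumerate(ranked, start=1):
            desc = ";".join(f"{fid}:{o}" for fid, o in cl.layout.signature())
            fh.write(f"{rank}\t{cl.score:.6g}\t{desc}\n")
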