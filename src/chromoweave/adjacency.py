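"""Novel-adjacency I/O, filtering, and two-technology merging.

A novel adjacency is a pair of oriented breakends created by a rearrangement.
Each breakend has a *side*: ``tail`` means the reference segment ending at the
position (its 3' boundary) participates in the fusion; ``head`` means the
segment starting at the position (its 5' boundary) does.  In BEDPE strand
notation '+' maps to tail and '-' to head.

The filter chain mirrors a long-read SV-calling pipeline: support below 5% of
the genome-wide mean alignment coverage, breakends in windows above 3x mean
coverage, breakends within 10 kb of a reference gap, breakends inside
segmental duplications, and adjacencies shared between samples of a cohort
(breakend distance cutoff 1 kb) are all removed.  Matched long/short-read
calls are merged by preferring the short-read coordinates when flagged
precise, otherwise the long-read call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

from chromoweave.genome import CoverageTrack, GenomeError, GenomeModel

TAIL = "tail"
HEAD = "head"

_STRAND_TO_SIDE = {"+": TAIL, "-": HEAD}
_SIDE_TO_STRAND = {TAIL: "+", HEAD: "-"}


class BedpeParseError(ValueError):
    pass


class Breakend(NamedTuple):
    chrom: str
    pos: int
    side: str  # tail | head

    @property
    def strand(self) -> str:
        return _SIDE_TO_STRAND[self.side]


@dataclass
class NovelAdjacency:
    """A pair of oriented breakends with caller provenance and read support."""

    id: str
    bnd1: Breakend
    bnd2: Breakend
    caller: str  # longread | shortread
    support: int | None = None
    precise: bool = False
    curated: bool = False
    sample: str | None = None
    techs: frozenset = field(default_factory=frozenset)
    filter_reason: str | None = None

    def __post_init__(self) -> None:
        if self.support is not None and self.support < 0:
            raise ValueError(f"negative support on {self.id}")
        if not self.techs:
            self.techs = frozenset({self.caller})

    @property
    def span(self) -> float:
        if self.bnd1.chrom == self.bnd2.chrom:
            return abs(self.bnd1.pos - self.bnd2.pos)
        return math.inf

    @property
    def is_trans(self) -> bool:
        return self.bnd1.chrom != self.bnd2.chrom

    def canonicalized(self, genome: GenomeModel) -> "NovelAdjacency":
        k1 = (genome.chrom_index(self.bnd1.chrom), self.bnd1.pos)
        k2 = (genome.chrom_index(self.bnd2.chrom), self.bnd2.pos)
        if k2 < k1:
            return replace(self, bnd1=self.bnd2, bnd2=self.bnd1)
        return self

    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.bnd1, self.bnd2)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bedpe(path, genome: GenomeModel, sample: str | None = None) -> list[NovelAdjacency]:
    """Read a BEDPE file (10+ columns, extra ``key=value`` columns) into
    canonicalized adjacencies.  Breakend positions are the BEDPE *start*
    coordinates (0-based)."""
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 10:
                raise BedpeParseError(f"{path}:{lineno}: expected >=10 BEDPE columns")
            try:
                c1, s1 = fields[0], int(fields[1])
                c2, s2 = fields[3], int(fields[4])
                name = fields[6]
                strand1, strand2 = fields[8], fields[9]
            except ValueError as exc:
                raise BedpeParseError(f"{path}:{lineno}: {exc}") from None
            if strand1 not in _STRAND_TO_SIDE or strand2 not in _STRAND_TO_SIDE:
                raise BedpeParseError(f"{path}:{lineno}: bad strand {strand1}/{strand2}")
            extras = {}
            for extra in fields[10:]:
                if "=" in extra:
                    k, v = extra.split("=", 1)
                    extras[k] = v
            genome.validate_position(c1, s1)
            genome.validate_position(c2, s2)
            adj = NovelAdjacency(
                id=name,
                bnd1=Breakend(c1, s1, _STRAND_TO_SIDE[strand1]),
                bnd2=Breakend(c2, s2, _STRAND_TO_SIDE[strand2]),
                caller=extras.get("caller", "longread"),
                support=int(extras["support"]) if "support" in extras else None,
                precise=extras.get("precise", "false").lower() in ("true", "1", "yes"),
                sample=sample,
            )
            calls.append(adj.canonicalized(genome))
    return calls


def write_bedpe(calls, path) -> None:
    with open(path, "w") as fh:
        for adj in calls:
            extras = [f"caller={adj.caller}"]
            if adj.support is not None:
                extras.append(f"support={adj.support}")
            extras.append(f"precise={'true' if adj.precise else 'false'}")
            fh.write(
                "\t".join(
                    [
                        adj.bnd1.chrom, str(adj.bnd1.pos), str(adj.bnd1.pos + 1),
                        adj.bnd2.chrom, str(adj.bnd2.pos), str(adj.bnd2.pos + 1),
                        adj.id, ".", adj.bnd1.strand, adj.bnd2.strand, *extras,
                    ]
                )
                + "\n"
            )


def write_filtered_tsv(kept, removed, path) -> None:
    """Tidy output of a filter chain with a ``filter_reason`` column."""
    with open(path, "w") as fh:
        fh.write(
            "id\tchrom1\tpos1\tside1\tchrom2\tpos2\tside2\t"
            "caller\tsupport\tprecise\tfilter_reason\n"
        )
        for adj in list(kept) + list(removed):
            fh.write(
                "\t".join(
                    [
                        adj.id,
                        adj.bnd1.chrom, str(adj.bnd1.pos), adj.bnd1.side,
                        adj.bnd2.chrom, str(adj.bnd2.pos), adj.bnd2.side,
                        adj.caller,
                        "." if adj.support is None else str(adj.support),
                        "true" if adj.precise else "false",
                        adj.filter_reason or "PASS",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Filters.  Each returns (kept, removed); removed calls carry filter_reason.
# ---------------------------------------------------------------------------

def _partition(calls, predicate_remove, reason):
    kept, removed = [], []
    for adj in calls:
        if predicate_remove(adj):
            removed.append(replace(adj, filter_reason=reason))
        else:
            kept.append(adj)
    return kept, removed


def filter_support(calls, coverage: CoverageTrack, frac: float = 0.05):
    """Remove calls supported by fewer reads than ``frac`` of the genome-wide
    mean alignment coverage.  Calls without a support count (short-read calls
    may lack one) pass through."""
    mean = coverage.genome_mean
    if mean <= 0:
        raise GenomeError("genome-wide mean coverage must be positive")
    threshold = frac * mean

    def low(adj):
        return adj.support is not None and adj.support < threshold

    return _partition(calls, low, "low_support")


def filter_high_coverage(calls, coverage: CoverageTrack, factor: float = 3.0):
    """Remove calls with either breakend in a window above ``factor`` times
    the genome-wide mean coverage (artificially high-coverage regions)."""
    threshold = factor * coverage.genome_mean

    def high(adj):
        return any(coverage.at(b.chrom, b.pos) > threshold for b in adj.breakends())

    return _partition(calls, high, "high_coverage")


def filter_near_gaps(calls, genome: GenomeModel, dist: int = 10_000):
    """Remove calls with either breakend closer than ``dist`` to a reference
    gap (distance 0 when inside a gap)."""

    def near(adj):
        return any(genome.gap_distance(b.chrom, b.pos) < dist for b in adj.breakends())

    return _partition(calls, near, "near_gap")


def filter_segdup(calls, genome: GenomeModel):
    """Remove calls with either breakend inside an annotated segmental
    duplication."""

    def inside(adj):
        return any(genome.in_segdup(b.chrom, b.pos) for b in adj.breakends())

    return _partition(calls, inside, "segdup")


def _breakends_match(a: NovelAdjacency, b: NovelAdjacency, cutoff: int) -> bool:
    """Same chromosome pair, same sides, both breakend distances <= cutoff.
    Calls are assumed canonicalized, so breakends are directly comparable."""
    return (
        a.bnd1.chrom == b.bnd1.chrom
        and a.bnd2.chrom == b.bnd2.chrom
        and a.bnd1.side == b.bnd1.side
        and a.bnd2.side == b.bnd2.side
        and abs(a.bnd1.pos - b.bnd1.pos) <= cutoff
        and abs(a.bnd2.pos - b.bnd2.pos) <= cutoff
    )


def filter_cohort(callsets: dict[str, list[NovelAdjacency]], cutoff: int = 1000):
    """Single-linkage clustering of adjacencies across cohort samples; clusters
    containing calls from more than one sample are removed in every sample.

    Returns ``{sample: (kept, removed)}``.  With a single sample this is a
    no-op (a warning is implied by the unchanged output).
    """
    samples = list(callsets)
    if len(samples) < 2:
        return {s: (list(calls), []) for s, calls in callsets.items()}

    flat = [(s, adj) for s in samples for adj in callsets[s]]
    n = len(flat)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    # group by (chrom pair, side pair) to limit pairwise comparisons
    buckets: dict[tuple, list[int]] = {}
    for i, (_, adj) in enumerate(flat):
        key = (adj.bnd1.chrom, adj.bnd2.chrom, adj.bnd1.side, adj.bnd2.side)
        buckets.setdefault(key, []).append(i)
    for idxs in buckets.values():
        idxs.sort(key=lambda i: flat[i][1].bnd1.pos)
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                if flat[j][1].bnd1.pos - flat[i][1].bnd1.pos > cutoff:
                    break
                if _breakends_match(flat[i][1], flat[j][1], cutoff):
                    union(i, j)

    cluster_samples: dict[int, set[str]] = {}
    for i, (s, _) in enumerate(flat):
        cluster_samples.setdefault(find(i), set()).add(s)

    out = {s: ([], []) for s in samples}
    for i, (s, adj) in enumerate(flat):
        if len(cluster_samples[find(i)]) > 1:
            out[s][1].append(replace(adj, filter_reason="cohort_shared"))
        else:
            out[s][0].append(adj)
    return out


def apply_filter_chain(calls, coverage, genome, cohort: dict | None = None,
                       sample: str | None = None, frac=0.05, factor=3.0,
                       gap_dist=10_000, cohort_cutoff=1000):
    """Run the five-filter chain in pipeline order; returns (kept, removed)."""
    removed_all = []
    kept, removed = filter_support(calls, coverage, frac=frac)
    removed_all += removed
    kept, removed = filter_high_coverage(kept, coverage, factor=factor)
    removed_all += removed
    kept, removed = filter_near_gaps(kept, genome, dist=gap_dist)
    removed_all += removed
    kept, removed = filter_segdup(kept, genome)
    removed_all += removed
    if cohort:
        sets = {sample or "sample": kept, **cohort}
        result = filter_cohort(sets, cutoff=cohort_cutoff)
        kept, removed = result[sample or "sample"]
        removed_all += removed
    return kept, removed_all


# ---------------------------------------------------------------------------
# Technology merge and span selection
# ---------------------------------------------------------------------------

def merge_technologies(long_calls, short_calls, match_dist: int = 1000):
    """Merge filtered long- and short-read call sets.

    Matched pairs (both breakends within ``match_dist``, sides equal) emit one
    representative: the short-read call when flagged precise, otherwise the
    long-read call; its ``techs`` records both technologies.  Unmatched calls
    pass through tagged by caller.
    """
    used_short: set[int] = set()
    merged = []
    for lc in long_calls:
        best = None
        best_d = None
        for j, sc in enumerate(short_calls):
            if j in used_short:
                continue
            if _breakends_match(lc, sc, match_dist):
                d = abs(lc.bnd1.pos - sc.bnd1.pos) + abs(lc.bnd2.pos - sc.bnd2.pos)
                if best_d is None or d < best_d:
                    best, best_d = j, d
        if best is None:
            merged.append(lc)
            continue
        used_short.add(best)
        sc = short_calls[best]
        rep = sc if sc.precise else lc
        merged.append(replace(rep, techs=frozenset({"longread", "shortread"})))
    for j, sc in enumerate(short_calls):
        if j not in used_short:
            merged.append(sc)
    return merged


def select_large_scale(calls, min_span: int = 100_000):
    """Split calls into large scale (trans, or cis span strictly > min_span)
    and the small-scale remainder."""
    large = [a for a in calls if a.is_trans or a.span > min_span]
    small = [a for a in calls if not (a.is_trans or a.span > min_span)]
    return large, small


def attach_small_scale(large_curated, small_calls, tol: int = 50,
                       min_span: int = 1000, max_span: int = 100_000):
    """Append small-scale calls (1-100 kb span) whose breakends lie within
    ``tol`` of any curated large-scale anchor point."""
    anchors: dict[str, list[int]] = {}
    for adj in large_curated:
        for b in adj.breakends():
            anchors.setdefault(b.chrom, []).append(b.pos)

    def near_anchor(b: Breakend) -> bool:
        return any(abs(b.pos - p) <= tol for p in anchors.get(b.chrom, []))

    out = list(large_curated)
    for adj in small_calls:
        if not (min_span <= adj.span <= max_span):
            continue
        if any(near_anchor(b) for b in adj.breakends()):
            out.append(replace(adj, curated=True))
    return out
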