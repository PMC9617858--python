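"""Reference-genome model: chromosome table, gaps, segmental duplications,
and binned alignment coverage.

All coordinates are 0-based, half-open.  The genome model is the coordinate
universe for every other module: breakends are validated against it, fragments
tile it, and the empirical null models exclude its gap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree


class GenomeError(ValueError):
    pass


def _build_trees(intervals: dict[str, list[tuple[int, int]]]) -> dict[str, IntervalTree]:
    trees = {}
    for chrom, ivs in intervals.items():
        trees[chrom] = IntervalTree.from_tuples((s, e) for s, e in ivs if e > s)
    return trees


@dataclass
class GenomeModel:
    """Chromosome names/lengths plus gap and segmental-duplication intervals."""

    chroms: list[tuple[str, int]]
    gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    segdups: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lengths = dict(self.chroms)
        for name, length in self.chroms:
            if length <= 0:
                raise GenomeError(f"chromosome {name} has non-positive length {length}")
        for label, ivset in (("gap", self.gaps), ("segdup", self.segdups)):
            for chrom, ivs in ivset.items():
                if chrom not in self.lengths:
                    raise GenomeError(f"{label} interval on unknown chromosome {chrom}")
                for s, e in ivs:
                    if not (0 <= s < e <= self.lengths[chrom]):
                        raise GenomeError(
                            f"{label} interval [{s},{e}) outside chromosome {chrom}"
                        )
        self._gap_trees = _build_trees(self.gaps)
        self._segdup_trees = _build_trees(self.segdups)
        self._order = {name: i for i, (name, _) in enumerate(self.chroms)}

    # -- coordinate helpers -------------------------------------------------

    def chrom_index(self, chrom: str) -> int:
        try:
            return self._order[chrom]
        except KeyError:
            raise GenomeError(f"unknown chromosome {chrom}") from None

    def validate_position(self, chrom: str, pos: int) -> None:
        idx = self.chrom_index(chrom)  # noqa: F841 -- raises on unknown chrom
        if not (0 <= pos < self.lengths[chrom]):
            raise GenomeError(f"position {chrom}:{pos} outside [0,{self.lengths[chrom]})")

    def gap_distance(self, chrom: str, pos: int) -> float:
        """Distance of a position to the nearest gap interval (0 when inside).

        Distance to an interval [s, e) is measured to its closed hull [s, e]:
        a position d bases right of e is at distance d.
        """
        ivs = self.gaps.get(chrom, [])
        if not ivs:
            return float("inf")
        return min(max(s - pos, pos - e, 0) for s, e in ivs)

    def in_segdup(self, chrom: str, pos: int) -> bool:
        tree = self._segdup_trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos))

    def in_gap(self, chrom: str, pos: int) -> bool:
        tree = self._gap_trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos))

    def total_length(self) -> int:
        return sum(length for _, length in self.chroms)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_files(cls, genome_tsv, gaps_bed=None, segdups_bed=None) -> "GenomeModel":
        chroms = []
        with open(genome_tsv) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                name, length = line.split()[:2]
                chroms.append((name, int(length)))
        gaps = read_bed(gaps_bed) if gaps_bed else {}
        segdups = read_bed(segdups_bed) if segdups_bed else {}
        return cls(chroms, gaps, segdups)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chroms:
                fh.write(f"{name}\t{length}\n")


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED3(+) file into per-chromosome interval lists."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    for ivs in out.values():
        ivs.sort()
    return out


def write_bed(intervals: dict[str, list[tuple[int, int]]], path, scores=None) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for i, (s, e) in enumerate(intervals[chrom]):
                if scores is not None:
                    fh.write(f"{chrom}\t{s}\t{e}\t{scores[chrom][i]}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


@dataclass
class CoverageTrack:
    """Mean alignment coverage in non-overlapping fixed-size windows.

    ``coverage[chrom]`` is a numpy array of per-window means; window ``w``
    covers ``[w * window_size, (w+1) * window_size)``.  The genome-wide mean
    is the mean over all windows.
    """

    window_size: int
    coverage: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise GenomeError("window size must be positive")
        self.coverage = {c: np.asarray(v, dtype=float) for c, v in self.coverage.items()}
        for chrom, v in self.coverage.items():
            if (v < 0).any():
                raise GenomeError(f"negative coverage on {chrom}")

    @property
    def genome_mean(self) -> float:
        total = sum(v.sum() for v in self.coverage.values())
        n = sum(v.size for v in self.coverage.values())
        if n == 0:
            raise GenomeError("coverage track is empty")
        return total / n

    def at(self, chrom: str, pos: int) -> float:
        if chrom not in self.coverage:
            raise GenomeError(f"no coverage windows for chromosome {chrom}")
        w = pos // self.window_size
        v = self.coverage[chrom]
        if w >= v.size:
            raise GenomeError(f"position {chrom}:{pos} outside coverage windows")
        return float(v[w])

    @classmethod
    def from_bed(cls, path) -> "CoverageTrack":
        rows: dict[str, list[tuple[int, float]]] = {}
        window = None
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, s, e, val = line.split()[:4]
                s, e = int(s), int(e)
                if window is None:
                    window = e - s
                rows.setdefault(chrom, []).append((s, float(val)))
        if window is None:
            raise GenomeError(f"empty coverage file {path}")
        cov = {}
        for chrom, entries in rows.items():
            entries.sort()
            arr = np.zeros(entries[-1][0] // window + 1)
            for s, val in entries:
                arr[s // window] = val
            cov[chrom] = arr
        return cls(window, cov)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.coverage):
                for w, val in enumerate(self.coverage[chrom]):
                    s = w * self.window_size
                    fh.write(f"{chrom}\t{s}\t{s + self.window_size}\t{val:g}\n")
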