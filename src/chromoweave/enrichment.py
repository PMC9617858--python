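"""Breakpoint enrichment against chromatin-feature tracks with empirical
permutation nulls.

Three background models mirror common practice for genomic-interval
statistics: (1) per-chromosome circular shifts of all breakpoint coordinates
(preserving their relative spacing, rejecting configurations that land a
coordinate in a reference gap); (2) rewiring of the connections between
breakend coordinates (coordinates fixed, pairing permuted), for fusion-type
statistics; (3) permutation of expression values over genes (coordinates
fixed), for allelic-imbalance-vs-distance statistics.  Empirical P-values
are right-sided with p = #(null >= observed) / n_iter, no pseudocount and no
multiple-testing adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from chromoweave.adjacency import Breakend, NovelAdjacency
from chromoweave.genome import GenomeModel


class EnrichmentError(ValueError):
    pass


@dataclass
class FeatureTrack:
    """Labeled intervals per chromosome (TADs, compartments, LADs, repeats)."""

    name: str
    intervals: dict[str, np.ndarray]  # (n, 2) int arrays, sorted, non-overlapping
    labels: dict[str, list] | None = None  # optional per-interval labels

    def __post_init__(self):
        self.intervals = {
            c: np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            for c, iv in self.intervals.items()
        }

    def label_at(self, chrom: str, pos: int):
        """Label of the interval containing pos; None outside all intervals."""
        iv = self.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return None
        i = int(np.searchsorted(iv[:, 0], pos, side="right")) - 1
        if i >= 0 and iv[i, 0] <= pos < iv[i, 1]:
            return self.labels[chrom][i] if self.labels else self.name
        return None

    def contains(self, chrom: str, pos) -> np.ndarray:
        """Vectorized membership of positions in any interval."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        iv = self.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
        ok = idx >= 0
        idx = np.maximum(idx, 0)
        return ok & (pos < iv[idx, 1])

    @classmethod
    def from_bed(cls, name, path, collapse_subcompartments: bool = True):
        """Load a BED track; 4th column becomes the label.  Sub-compartment
        labels (A1, B2, ...) are collapsed to A/B."""
        intervals: dict[str, list] = {}
        labels: dict[str, list] = {}
        have_labels = False
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.split()
                chrom, s, e = fields[0], int(fields[1]), int(fields[2])
                intervals.setdefault(chrom, []).append((s, e))
                lab = fields[3] if len(fields) > 3 else None
                if lab is not None:
                    have_labels = True
                    if collapse_subcompartments and lab and lab[0] in "AB" and lab[1:].isdigit():
                        lab = lab[0]
                labels.setdefault(chrom, []).append(lab)
        ivs = {}
        labs = {}
        for chrom in intervals:
            order = sorted(range(len(intervals[chrom])), key=lambda i: intervals[chrom][i])
            ivs[chrom] = np.array([intervals[chrom][i] for i in order])
            labs[chrom] = [labels[chrom][i] for i in order]
        return cls(name, ivs, labs if have_labels else None)


# ---------------------------------------------------------------------------
# Interval arithmetic (small helpers; tracks are modest in size)
# ---------------------------------------------------------------------------

def _merge(ivs) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted((int(s), int(e)) for s, e in ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _subtract(ivs, cut) -> list[tuple[int, int]]:
    cut = _merge(cut)
    out = []
    for s, e in _merge(ivs):
        cur = s
        for cs, ce in cut:
            if ce <= cur or cs >= e:
                continue
            if cs > cur:
                out.append((cur, min(cs, e)))
            cur = max(cur, ce)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def expected_fraction(track: FeatureTrack, genome: GenomeModel) -> float:
    """Genome fraction of the feature, excluding reference gaps from both the
    feature and the denominator."""
    feat = 0
    total = 0
    for chrom, length in genome.chroms:
        gaps = genome.gaps.get(chrom, [])
        non_gap = _subtract([(0, length)], gaps)
        total += sum(e - s for s, e in non_gap)
        iv = track.intervals.get(chrom)
        if iv is not None and len(iv):
            feat += sum(e - s for s, e in _subtract([tuple(x) for x in iv], gaps))
    if total == 0:
        raise EnrichmentError("genome is fully gapped")
    return feat / total


# ---------------------------------------------------------------------------
# Annotation and fusion classification
# ---------------------------------------------------------------------------

def annotate_breakpoints(breakpoints: list[tuple[str, int]],
                         tracks: dict[str, FeatureTrack],
                         boundary_pad: int = 50_000) -> pd.DataFrame:
    """Per-breakpoint feature labels.

    ``tracks`` may include 'tad_boundary' (point/interval boundaries; a
    breakpoint within +/- pad counts as in-boundary), 'compartment' (A/B
    labels), 'lad', and 'repeat' (class labels).
    """
    rows = []
    for chrom, pos in breakpoints:
        row: dict = {"chrom": chrom, "pos": pos}
        tb = tracks.get("tad_boundary")
        if tb is not None:
            iv = tb.intervals.get(chrom)
            if iv is None or len(iv) == 0:
                row["in_boundary"] = False
            else:
                centers = (iv[:, 0] + iv[:, 1]) // 2
                row["in_boundary"] = bool(np.min(np.abs(centers - pos)) <= boundary_pad)
        comp = tracks.get("compartment")
        if comp is not None:
            row["compartment"] = comp.label_at(chrom, pos) or "NA"
        lad = tracks.get("lad")
        if lad is not None:
            row["lad"] = "LAD" if lad.label_at(chrom, pos) is not None else "nonLAD"
        rep = tracks.get("repeat")
        if rep is not None:
            row["repeat"] = rep.label_at(chrom, pos) or "none"
        rows.append(row)
    return pd.DataFrame(rows)


def classify_fusions(adjacencies: list[NovelAdjacency], track: FeatureTrack,
                     binary_label: str | None = None):
    """Unordered label-pair counts over adjacencies (e.g. A-A / A-B / B-B, or
    LAD / nonLAD fusions when ``binary_label`` is given).  Pairs with an
    unannotatable breakend are excluded and counted separately."""
    counts: dict[tuple, int] = {}
    n_excluded = 0
    for adj in adjacencies:
        labels = []
        for b in adj.breakends():
            lab = track.label_at(b.chrom, b.pos)
            if binary_label is not None:
                lab = binary_label if lab is not None else f"non{binary_label}"
            labels.append(lab)
        if any(lab is None for lab in labels):
            n_excluded += 1
            continue
        key = tuple(sorted(labels))
        counts[key] = counts.get(key, 0) + 1
    return counts, n_excluded


def intra_tad_classification(adjacencies: list[NovelAdjacency],
                             tads: FeatureTrack):
    """Classify each adjacency as same TAD / neighboring TADs / spanning at
    least one TAD / trans; breakends outside any TAD give NA."""
    counts = {"same_tad": 0, "neighboring_tads": 0, "spanning": 0, "trans": 0, "NA": 0}
    for adj in adjacencies:
        if adj.is_trans:
            counts["trans"] += 1
            continue
        iv = tads.intervals.get(adj.bnd1.chrom)
        idxs = []
        for b in adj.breakends():
            if iv is None or len(iv) == 0:
                idxs.append(None)
                continue
            i = int(np.searchsorted(iv[:, 0], b.pos, side="right")) - 1
            idxs.append(i if (i >= 0 and iv[i, 0] <= b.pos < iv[i, 1]) else None)
        if None in idxs:
            counts["NA"] += 1
        elif idxs[0] == idxs[1]:
            counts["same_tad"] += 1
        elif abs(idxs[0] - idxs[1]) == 1:
            counts["neighboring_tads"] += 1
        else:
            counts["spanning"] += 1
    return counts


# ---------------------------------------------------------------------------
# Null models
# ---------------------------------------------------------------------------

def null_shift(breakpoints: dict[str, np.ndarray], genome: GenomeModel,
               rng: np.random.Generator, max_attempts: int = 1000):
    """One random configuration: all coordinates of a chromosome shifted by
    the same uniform offset with wrap-around; the whole configuration is
    redrawn while any coordinate lands in a reference gap."""
    gap_arrays = {
        c: np.asarray(genome.gaps.get(c, []), dtype=np.int64).reshape(-1, 2)
        for c in breakpoints
    }
    for _ in range(max_attempts):
        shifted = {}
        ok = True
        for chrom, pos in breakpoints.items():
            length = genome.lengths[chrom]
            if chrom in genome.gaps:
                gap_len = sum(e - s for s, e in genome.gaps[chrom])
                if gap_len >= length:
                    raise EnrichmentError(f"chromosome {chrom} is fully gapped")
            off = int(rng.integers(0, length))
            new = (np.asarray(pos, dtype=np.int64) + off) % length
            iv = gap_arrays[chrom]
            if len(iv):
                idx = np.searchsorted(iv[:, 0], new, side="right") - 1
                in_gap = (idx >= 0) & (new < iv[np.maximum(idx, 0), 1])
                if in_gap.any():
                    ok = False
                    break
            shifted[chrom] = new
        if ok:
            return shifted
    raise EnrichmentError(f"no gap-free configuration found in {max_attempts} attempts")


def null_rewire(adjacencies: list[NovelAdjacency],
                rng: np.random.Generator) -> list[NovelAdjacency]:
    """Permute the pairing of second breakends across adjacencies; the
    coordinate multiset is unchanged."""
    n = len(adjacencies)
    perm = rng.permutation(n)
    return [
        replace(adj, bnd2=adjacencies[perm[i]].bnd2)
        for i, adj in enumerate(adjacencies)
    ]


def null_expression(genes: pd.DataFrame, rng: np.random.Generator,
                    columns=("aig",)) -> pd.DataFrame:
    """Permute expression columns over genes; coordinates stay fixed."""
    out = genes.copy()
    perm = rng.permutation(len(genes))
    for col in columns:
        out[col] = genes[col].to_numpy()[perm]
    return out


# ---------------------------------------------------------------------------
# Empirical testing
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalTestResult:
    statistic: str
    observed: float
    null_sample: np.ndarray
    p_right: float
    expected: float | None = None


def empirical_test(observed: float, null_generator, n_iter: int = 1000,
                   rng: np.random.Generator | None = None,
                   statistic: str = "statistic",
                   expected: float | None = None) -> EmpiricalTestResult:
    """Right-sided empirical test: p = #(null >= observed) / n_iter.

    ``null_generator(rng)`` returns one null statistic per call.  No
    pseudocount is added, so p may be exactly 0.
    """
    rng = rng if rng is not None else np.random.default_rng()
    nulls = np.array([null_generator(rng) for _ in range(n_iter)], dtype=float)
    p = float(np.count_nonzero(nulls >= observed)) / n_iter
    return EmpiricalTestResult(statistic, float(observed), nulls, p, expected)


def feature_fraction(breakpoints: dict[str, np.ndarray], track: FeatureTrack) -> float:
    """Fraction of breakpoints inside the track's intervals (vectorized)."""
    inside = 0
    total = 0
    for chrom, pos in breakpoints.items():
        hits = track.contains(chrom, pos)
        inside += int(hits.sum())
        total += hits.size
    if total == 0:
        raise EnrichmentError("no breakpoints")
    return inside / total


def shift_null_test(breakpoints: dict[str, np.ndarray], track: FeatureTrack,
                    genome: GenomeModel, n_iter: int = 1000,
                    rng: np.random.Generator | None = None) -> EmpiricalTestResult:
    """Enrichment of breakpoints in a feature track against the shift null."""
    rng = rng if rng is not None else np.random.default_rng()
    observed = feature_fraction(breakpoints, track)

    def gen(r):
        return feature_fraction(null_shift(breakpoints, genome, r), track)

    return empirical_test(
        observed, gen, n_iter=n_iter, rng=rng,
        statistic=f"{track.name}_fraction",
        expected=expected_fraction(track, genome),
    )


# ---------------------------------------------------------------------------
# AIG distance curves
# ---------------------------------------------------------------------------

def _nearest_breakpoint_distance(genes: pd.DataFrame,
                                 breakpoints: dict[str, np.ndarray]) -> np.ndarray:
    """Distance of each gene's TSS to the closest breakpoint on its
    chromosome; inf for chromosomes without breakpoints."""
    dist = np.full(len(genes), np.inf)
    for chrom, pos in breakpoints.items():
        pos = np.sort(np.asarray(pos, dtype=np.int64))
        if pos.size == 0:
            continue
        mask = (genes["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        tss = genes.loc[mask, "tss"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(pos, tss)
        left = np.where(idx > 0, np.abs(tss - pos[np.maximum(idx - 1, 0)]), np.inf)
        right = np.where(idx < pos.size, np.abs(pos[np.minimum(idx, pos.size - 1)] - tss), np.inf)
        dist[mask] = np.minimum(left, right)
    return dist


def _tad_unit_distance(genes: pd.DataFrame, breakpoints: dict[str, np.ndarray],
                       tads: FeatureTrack) -> np.ndarray:
    """Distance in TAD units: 0 = same TAD, 1 = one TAD away, etc.; inf when
    gene or breakpoint falls outside the TAD partition or no breakpoint on
    the chromosome."""
    dist = np.full(len(genes), np.inf)
    for chrom in genes["chrom"].unique():
        iv = tads.intervals.get(chrom)
        bps = np.asarray(breakpoints.get(chrom, []), dtype=np.int64)
        if iv is None or len(iv) == 0 or bps.size == 0:
            continue
        def tad_index(p):
            i = np.searchsorted(iv[:, 0], p, side="right") - 1
            inside = (i >= 0) & (p < iv[np.maximum(i, 0), 1])
            return np.where(inside, i, -1)
        bp_tads = np.unique(tad_index(bps))
        bp_tads = bp_tads[bp_tads >= 0]
        if bp_tads.size == 0:
            continue
        mask = (genes["chrom"] == chrom).to_numpy()
        g_tads = tad_index(genes.loc[mask, "tss"].to_numpy(dtype=np.int64))
        d = np.full(g_tads.shape, np.inf)
        ok = g_tads >= 0
        if ok.any():
            d[ok] = np.min(np.abs(g_tads[ok][:, None] - bp_tads[None, :]), axis=1)
        dist[mask] = d
    return dist


@dataclass
class DistanceCurve:
    bin_edges: np.ndarray  # len k+1; the last bin collects "unaffected" genes
    bin_labels: list[str]
    observed_fraction: np.ndarray
    null_percentiles: np.ndarray  # (3, k): 5th, 50th, 95th
    p_right: np.ndarray
    n_genes: np.ndarray


def aig_distance_curve(genes: pd.DataFrame, breakpoints: dict[str, np.ndarray],
                       genome: GenomeModel, bins=None, mode: str = "bp",
                       tads: FeatureTrack | None = None, n_iter: int = 1000,
                       rng: np.random.Generator | None = None,
                       null: str = "shift") -> DistanceCurve:
    """Fraction of allelic-imbalance genes vs distance to the nearest
    breakpoint, with a permutation-null envelope and per-bin right-sided
    empirical P-values.

    ``genes`` columns: gene, chrom, tss, aig (bool).  Distances are in bp
    (default bins up to 1 Mb) or TAD units.  Genes on chromosomes without a
    breakpoint fall in the final, unbounded bin.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if mode == "bp":
        if bins is None:
            bins = [0, 100_000, 200_000, 400_000, 600_000, 800_000, 1_000_000]
        edges = np.array(list(bins) + [np.inf])
        labels = [
            f"[{int(edges[i])},{int(edges[i+1])})" if np.isfinite(edges[i + 1])
            else f">={int(edges[i])}"
            for i in range(len(edges) - 1)
        ]
        def distances(bp_cfg):
            return _nearest_breakpoint_distance(genes, bp_cfg)
    elif mode == "tad_units":
        if tads is None:
            raise EnrichmentError("tad_units mode requires a TAD track")
        if bins is None:
            bins = [0, 1, 2, 3, 4, 5]
        edges = np.array(list(bins) + [np.inf])
        labels = [
            ("same_TAD" if edges[i] == 0 else f"{int(edges[i])}_TAD")
            if np.isfinite(edges[i + 1]) else "farther"
            for i in range(len(edges) - 1)
        ]
        def distances(bp_cfg):
            return _tad_unit_distance(genes, bp_cfg, tads)
    else:
        raise EnrichmentError(f"unknown mode {mode!r}")

    aig = genes["aig"].to_numpy(dtype=bool)
    k = len(edges) - 1

    def binned_fractions(bp_cfg, aig_flags):
        d = distances(bp_cfg)
        idx = np.searchsorted(edges, d, side="right") - 1
        idx = np.clip(idx, 0, k - 1)
        frac = np.full(k, np.nan)
        n = np.zeros(k, dtype=int)
        for b in range(k):
            sel = idx == b
            n[b] = int(sel.sum())
            if n[b]:
                frac[b] = float(aig_flags[sel].mean())
        return frac, n

    observed, n_genes = binned_fractions(breakpoints, aig)
    nulls = np.empty((n_iter, k))
    for it in range(n_iter):
        if null == "shift":
            cfg = null_shift(breakpoints, genome, rng)
            nulls[it], _ = binned_fractions(cfg, aig)
        elif null == "expression":
            permuted = null_expression(genes, rng)
            nulls[it], _ = binned_fractions(breakpoints, permuted["aig"].to_numpy(bool))
        else:
            raise EnrichmentError(f"unknown null {null!r}")

    with np.errstate(invalid="ignore"):
        pct = np.nanpercentile(nulls, [5, 50, 95], axis=0)
        p = np.full(k, np.nan)
        for b in range(k):
            if np.isnan(observed[b]):
                continue
            col = nulls[:, b]
            valid = ~np.isnan(col)
            if valid.any():
                p[b] = float(np.count_nonzero(col[valid] >= observed[b])) / n_iter
    return DistanceCurve(edges, labels, observed, pct, p, n_genes)


def write_results_tsv(results: list[EmpiricalTestResult], path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write("statistic\tobserved\texpected\tp_right\tn_iter\tseed\n")
        for r in results:
            exp = "NA" if r.expected is None else f"{r.expected:.6g}"
            fh.write(
                f"{r.statistic}\t{r.observed:.6g}\t{exp}\t{r.p_right:.6g}\t"
                f"{len(r.null_sample)}\t{seed if seed is not None else 'NA'}\n"
            )
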