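"""Binned symmetric Hi-C contact matrices.

The matrix is stored densely (symmetric, raw counts) with a chromosome table
and per-chromosome bin offsets; text I/O uses a sparse upper-triangle COO
format with a JSON header.  Operations cover tile extraction with axis
inversion, breakpoint grid partitioning, a distance-decay expectation for
flagging ectopic (rearrangement-induced) signal, recomposition of the map
along derivative-chromosome layouts, and scaled control subtraction.

Fragment-to-bin rounding follows the recomposition convention: fragment
starts are rounded *up* to the next bin start, ends rounded *down*; fragments
smaller than one bin are flagged sub-bin and dropped from recomposition.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np


class MatrixError(ValueError):
    pass


class SubBinFragment(MatrixError):
    pass


class ContactMatrix:
    """Symmetric binned contact map over an ordered chromosome table."""

    def __init__(self, bin_size: int, chroms: list[tuple[str, int]], dense=None):
        if bin_size <= 0:
            raise MatrixError("bin size must be positive")
        self.bin_size = bin_size
        self.chroms = list(chroms)
        self.n_bins_per_chrom = {
            name: -(-length // bin_size) for name, length in self.chroms
        }
        self.offsets = {}
        off = 0
        for name, _ in self.chroms:
            self.offsets[name] = off
            off += self.n_bins_per_chrom[name]
        self.n_bins = off
        if dense is None:
            self._m = np.zeros((self.n_bins, self.n_bins))
        else:
            dense = np.asarray(dense, dtype=float)
            if dense.shape != (self.n_bins, self.n_bins):
                raise MatrixError(
                    f"dense shape {dense.shape} != bin table ({self.n_bins})"
                )
            if (dense < 0).any():
                raise MatrixError("negative contact counts")
            if not np.allclose(dense, dense.T):
                raise MatrixError("contact matrix must be symmetric")
            self._m = dense.copy()

    # -- basic access -------------------------------------------------------

    def dense(self) -> np.ndarray:
        return self._m

    def get(self, i: int, j: int) -> float:
        return float(self._m[i, j])

    def set(self, i: int, j: int, value: float) -> None:
        if value < 0:
            raise MatrixError("negative contact count")
        self._m[i, j] = value
        self._m[j, i] = value

    def total_signal(self) -> float:
        return float(self._m.sum())

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.bin_size, self.chroms, self._m)

    def chrom_of_bin(self, b: int) -> str:
        for name, _ in reversed(self.chroms):
            if b >= self.offsets[name]:
                return name
        raise MatrixError(f"bin {b} out of range")

    # -- coordinate mapping -------------------------------------------------

    def bin_of(self, chrom: str, pos: int) -> int:
        if chrom not in self.offsets:
            raise MatrixError(f"unknown chromosome {chrom}")
        return self.offsets[chrom] + pos // self.bin_size

    def fragment_bins(self, chrom: str, start: int, end: int) -> tuple[int, int, bool]:
        """Global (start_bin, end_bin_exclusive, sub_bin) of a fragment.

        Start rounded up to the next bin start, end rounded down; ``sub_bin``
        is true when no whole bin is covered.
        """
        if chrom not in self.offsets:
            raise MatrixError(f"unknown chromosome {chrom}")
        b0 = -(-start // self.bin_size)  # ceil
        b1 = end // self.bin_size  # floor
        off = self.offsets[chrom]
        return off + b0, off + b1, b1 <= b0

    # -- I/O ----------------------------------------------------------------

    def write_coo(self, path) -> None:
        with open(path, "w") as fh:
            header = {"bin_size": self.bin_size, "chroms": [list(c) for c in self.chroms]}
            fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
            iu = np.triu_indices(self.n_bins)
            vals = self._m[iu]
            nz = vals != 0
            for i, j, v in zip(iu[0][nz], iu[1][nz], vals[nz]):
                fh.write(f"{i}\t{j}\t{v:g}\n")

    @classmethod
    def read_coo(cls, path) -> "ContactMatrix":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise MatrixError(f"{path}: missing JSON header line")
            header = json.loads(first[1:])
            m = cls(header["bin_size"], [tuple(c) for c in header["chroms"]])
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                i, j, v = line.split()
                i, j, v = int(i), int(j), float(v)
                if v < 0:
                    raise MatrixError(f"{path}:{lineno}: negative count")
                if not (0 <= i < m.n_bins and 0 <= j < m.n_bins):
                    raise MatrixError(f"{path}:{lineno}: bin index out of range")
                if j < i:
                    warnings.warn(f"{path}:{lineno}: lower-triangle entry normalized")
                    i, j = j, i
                m._m[i, j] = v
                m._m[j, i] = v
        return m

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ContactMatrix)
            and self.bin_size == other.bin_size
            and self.chroms == other.chroms
            and np.array_equal(self._m, other._m)
        )


# ---------------------------------------------------------------------------
# Tiles and grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinFragment:
    """A bin-aligned genomic fragment inside a contact matrix."""

    chrom: str
    start: int  # bp
    end: int  # bp
    start_bin: int  # global, inclusive
    end_bin: int  # global, exclusive
    sub_bin: bool

    @property
    def n_bins(self) -> int:
        return max(self.end_bin - self.start_bin, 0)


def make_bin_fragment(matrix: ContactMatrix, chrom: str, start: int, end: int) -> BinFragment:
    b0, b1, sub = matrix.fragment_bins(chrom, start, end)
    return BinFragment(chrom, start, end, b0, b1, sub)


def extract_tile(matrix: ContactMatrix, row_frag: BinFragment, col_frag: BinFragment,
                 invert_rows: bool = False, invert_cols: bool = False) -> np.ndarray:
    """Dense tile of the matrix spanned by two bin-aligned fragments, with
    optional axis reversals (used for inverted fragments)."""
    for frag in (row_frag, col_frag):
        if frag.sub_bin:
            raise SubBinFragment(f"fragment {frag.chrom}:{frag.start}-{frag.end} covers no whole bin")
    tile = matrix.dense()[row_frag.start_bin:row_frag.end_bin,
                          col_frag.start_bin:col_frag.end_bin].copy()
    if invert_rows:
        tile = tile[::-1, :]
    if invert_cols:
        tile = tile[:, ::-1]
    return tile


@dataclass
class GridPartition:
    """2D partition of a contact map by per-chromosome breakpoint bin lines."""

    matrix: ContactMatrix
    fragments: list[BinFragment]

    @classmethod
    def from_breakpoints(cls, matrix: ContactMatrix,
                         breakpoints: dict[str, list[int]]) -> "GridPartition":
        frags = []
        for chrom, length in matrix.chroms:
            bps = sorted(set(breakpoints.get(chrom, [])))
            bounds = [0] + [b for b in bps if 0 < b < length] + [length]
            for s, e in zip(bounds[:-1], bounds[1:]):
                frags.append(make_bin_fragment(matrix, chrom, s, e))
        return cls(matrix, frags)

    def tiles(self):
        for p, rf in enumerate(self.fragments):
            for cf in self.fragments[p:]:
                yield rf, cf


# ---------------------------------------------------------------------------
# Distance decay and ectopic-signal detection
# ---------------------------------------------------------------------------

@dataclass
class DecayModel:
    """Expected contact count vs cis bin distance, plus a trans constant.

    ``expected`` is indexed by bin distance and nonincreasing (isotonic fit of
    the per-distance mean count); distances beyond the table use the last
    value.
    """

    expected: np.ndarray
    trans_expectation: float

    def cis(self, d) -> np.ndarray:
        d = np.minimum(np.abs(d), len(self.expected) - 1)
        return self.expected[d]


def fit_decay(matrix: ContactMatrix) -> DecayModel:
    """Per-distance mean over all cis bin pairs, isotonic-smoothed to be
    nonincreasing; trans expectation is the mean over all trans pairs."""
    if matrix.n_bins == 0:
        raise MatrixError("empty matrix")
    m = matrix.dense()
    max_n = max(matrix.n_bins_per_chrom[name] for name, _ in matrix.chroms)
    sums = np.zeros(max_n)
    counts = np.zeros(max_n)
    for name, _ in matrix.chroms:
        off, n = matrix.offsets[name], matrix.n_bins_per_chrom[name]
        block = m[off:off + n, off:off + n]
        for d in range(n):
            diag = np.diagonal(block, d)
            sums[d] += diag.sum()
            counts[d] += diag.size
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    valid = counts > 0
    if valid.any():
        from sklearn.isotonic import IsotonicRegression

        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        d_idx = np.nonzero(valid)[0]
        fitted = iso.fit_transform(d_idx, means[d_idx], sample_weight=counts[d_idx])
        means[d_idx] = fitted
        # fill gaps by clipping to neighbours (nonincreasing)
        means = np.minimum.accumulate(np.where(valid, means, np.inf))
        means[~np.isfinite(means)] = 0.0

    cis_total = sum(
        m[matrix.offsets[n]:matrix.offsets[n] + matrix.n_bins_per_chrom[n],
          matrix.offsets[n]:matrix.offsets[n] + matrix.n_bins_per_chrom[n]].sum()
        for n, _ in matrix.chroms
    )
    trans_total = m.sum() - cis_total
    n_trans_pairs = matrix.n_bins**2 - sum(
        matrix.n_bins_per_chrom[n]**2 for n, _ in matrix.chroms
    )
    trans_exp = trans_total / n_trans_pairs if n_trans_pairs else 0.0
    return DecayModel(expected=means, trans_expectation=trans_exp)


def ectopic_score(matrix: ContactMatrix, decay: DecayModel,
                  row_frag: BinFragment, col_frag: BinFragment,
                  threshold: float = 3.0, min_bins: int = 4,
                  corner: int = 5) -> tuple[float, bool]:
    """Corner-concentrated observed/expected score of a grid tile, and
    whether it is flagged ectopic.

    A junction between two fragments produces signal concentrated at one
    corner of their grid tile (the two fused ends), so the score is the
    maximum over the four ``corner`` x ``corner`` tile corners of the mean
    observed/expected ratio there.  Expected counts come from the decay
    model: cis pairs use the distance curve, trans pairs the trans constant.
    Flagged when score >= threshold and the best corner has >= min_bins
    nonzero bins.  Deterministic.
    """
    if row_frag.sub_bin or col_frag.sub_bin or row_frag.n_bins == 0 or col_frag.n_bins == 0:
        return 0.0, False
    obs = matrix.dense()[row_frag.start_bin:row_frag.end_bin,
                         col_frag.start_bin:col_frag.end_bin]
    if row_frag.chrom == col_frag.chrom:
        rows = np.arange(row_frag.start_bin, row_frag.end_bin)
        cols = np.arange(col_frag.start_bin, col_frag.end_bin)
        exp = decay.cis(rows[:, None] - cols[None, :])
    else:
        exp = np.full(obs.shape, decay.trans_expectation)
    exp = np.maximum(exp, 1e-12)
    ratio = obs / exp
    wr = min(corner, ratio.shape[0])
    wc = min(corner, ratio.shape[1])
    best_score = 0.0
    best_nonzero = 0
    for rs in (slice(0, wr), slice(ratio.shape[0] - wr, ratio.shape[0])):
        for cs in (slice(0, wc), slice(ratio.shape[1] - wc, ratio.shape[1])):
            sub = ratio[rs, cs]
            score = float(np.mean(sub))
            if score > best_score:
                best_score = score
                best_nonzero = int(np.count_nonzero(obs[rs, cs]))
    return best_score, bool(best_score >= threshold and best_nonzero >= min_bins)


# ---------------------------------------------------------------------------
# Recomposition and control subtraction
# ---------------------------------------------------------------------------

def layout_bin_index(matrix: ContactMatrix, layout) -> np.ndarray:
    """Source-bin index vector of a derivative layout (inverted fragments
    reversed); sub-bin fragments are dropped with a warning."""
    idx: list[int] = []
    for frag, orient in layout.members:
        b0, b1, sub = matrix.fragment_bins(frag.chrom, frag.start, frag.end)
        if sub:
            warnings.warn(
                f"fragment {frag.chrom}:{frag.start}-{frag.end} smaller than one "
                f"bin; dropped from recomposition"
            )
            continue
        rng = range(b0, b1)
        idx.extend(reversed(rng) if orient == "inverted" else rng)
    return np.asarray(idx, dtype=int)


def recompose(matrix: ContactMatrix, layouts) -> ContactMatrix:
    """Reorder and reorient matrix rows/columns along derivative layouts.

    The output chromosome table is the derivative chromosomes; block (p, q)
    equals the source tile of fragments p, q with inversions matching their
    orientations.  Overlapping fragments across layouts (copy gains) raise.
    """
    index_vectors = []
    seen: set[int] = set()
    for layout in layouts:
        vec = layout_bin_index(matrix, layout)
        overlap = seen.intersection(vec.tolist())
        if len(set(vec.tolist())) != vec.size:
            raise MatrixError(
                f"layout {layout.name} contains overlapping fragments; "
                f"copy gains are not supported"
            )
        if overlap:
            raise MatrixError(
                f"layout {layout.name} reuses source bins {sorted(overlap)[:5]}; "
                f"copy gains are not supported"
            )
        seen.update(vec.tolist())
        index_vectors.append(vec)

    out_chroms = [
        (layout.name, len(vec) * matrix.bin_size)
        for layout, vec in zip(layouts, index_vectors)
    ]
    all_idx = np.concatenate([v for v in index_vectors]) if index_vectors else np.array([], int)
    out = ContactMatrix(matrix.bin_size, out_chroms)
    if all_idx.size:
        out._m = matrix.dense()[np.ix_(all_idx, all_idx)].copy()
    return out


def inverse_layouts(matrix: ContactMatrix, layouts, recomposed: ContactMatrix):
    """Layouts that map a recomposed matrix back onto the source bin order.

    Only meaningful for loss-free, bin-aligned layouts; used to assert the
    recomposition involution.
    """
    from chromoweave.reconstruction import DerivativeLayout, Fragment

    pos_of_source: dict[int, int] = {}
    cursor = 0
    for layout in layouts:
        vec = layout_bin_index(matrix, layout)
        for u, src in enumerate(vec):
            pos_of_source[int(src)] = cursor + u
        cursor += len(vec)

    inv = []
    for name, length in matrix.chroms:
        off, n = matrix.offsets[name], matrix.n_bins_per_chrom[name]
        members = []
        runs: list[tuple[int, int, int]] = []  # recomposed-bin start, step, length
        series = [
            pos_of_source[off + b] for b in range(n) if (off + b) in pos_of_source
        ]
        n = len(series)
        if n == 0:
            continue
        i = 0
        while i < n:
            j = i + 1
            if j < n and abs(series[j] - series[i]) == 1:
                step = series[j] - series[i]
                while j + 1 < n and series[j + 1] - series[j] == step:
                    j += 1
            else:
                step = 1
                j = i
            runs.append((series[i] if step > 0 else series[j], step, j - i + 1))
            i = j + 1
        for start_bin, step, run_len in runs:
            chrom_r = recomposed.chrom_of_bin(start_bin)
            local = start_bin - recomposed.offsets[chrom_r]
            frag = Fragment(
                id=f"{chrom_r}:{local}",
                chrom=chrom_r,
                start=local * recomposed.bin_size,
                end=(local + run_len) * recomposed.bin_size,
                telomeric_5p=False,
                telomeric_3p=False,
            )
            members.append((frag, "forward" if step > 0 else "inverted"))
        inv.append(DerivativeLayout(name=name, members=members, completeness="complete"))
    return inv


def subtract_control(sample: ContactMatrix, control: ContactMatrix,
                     exclude: str = "main_diag") -> ContactMatrix:
    """Subtract a control map scaled to 50% of the sample's overall signal.

    ``exclude`` names the diagonal(s) left out of the scaling-factor
    computation: ``main_diag`` (recomposition workflow) or ``main_and_first``
    (custom-genome evaluation variant).  Negative results are clipped to 0.
    """
    if sample.chroms != control.chroms or sample.bin_size != control.bin_size:
        raise MatrixError("sample and control bin tables differ")
    if exclude not in ("main_diag", "main_and_first"):
        raise MatrixError(f"unknown exclude mode {exclude!r}")
    n = sample.n_bins
    mask = np.ones((n, n), dtype=bool)
    np.fill_diagonal(mask, False)
    if exclude == "main_and_first":
        idx = np.arange(n - 1)
        mask[idx, idx + 1] = False
        mask[idx + 1, idx] = False
    s_sample = sample.dense()[mask].sum()
    s_control = control.dense()[mask].sum()
    if s_control == 0:
        raise MatrixError("control map has zero signal outside excluded diagonals")
    f = 0.5 * s_sample / s_control
    out = np.maximum(sample.dense() - f * control.dense(), 0.0)
    return ContactMatrix(sample.bin_size, sample.chroms, out)


def write_2d_annotations(calls, path, color: str = "0,0,255") -> None:
    """Juicebox-style 2D annotation TSV for overlaying adjacencies on maps."""
    with open(path, "w") as fh:
        fh.write("chr1\tx1\tx2\tchr2\ty1\ty2\tcolor\n")
        for adj in calls:
            fh.write(
                f"{adj.bnd1.chrom}\t{adj.bnd1.pos}\t{adj.bnd1.pos + 1}\t"
                f"{adj.bnd2.chrom}\t{adj.bnd2.pos}\t{adj.bnd2.pos + 1}\t{color}\n"
            )
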