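"""Ground-truthed synthetic inputs for every pipeline stage.

The simulator builds a small multi-chromosome genome with reserved gap,
segmental-duplication, and high-coverage zones, rearranges it in one of two
regimes — chromoplexy (a balanced cyclic exchange of large fragments between
chromosomes, few junctions, no gains) or chromothripsis (dense clustered
breakpoints inside shatter regions, random fragment loss, random rejoin
order/orientation) — and derives every observable from the planted truth:

* two-caller BEDPE call sets with positional jitter, false negatives, and
  planted false positives of each filterable class (plus a decoy cohort
  sample for the sharing filter);
* a two-allele Hi-C matrix: a 50/50 overlay of the wild-type homolog and the
  derivative allele, each following a power-law distance decay, Poisson
  sampled;
* soft-clipped junction reads with planted microhomology/InDel signatures;
* chromatin-feature tracks, gene tables with planted allelic-imbalance
  effects decaying with breakpoint distance, and haplotagged read tables
  consistent with a planted rearranged haplotype.

All randomness flows from a single seed; identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from chromoweave.adjacency import HEAD, TAIL, Breakend, NovelAdjacency
from chromoweave.genome import CoverageTrack, GenomeModel
from chromoweave.hic import ContactMatrix, layout_bin_index
from chromoweave.reconstruction import (
    FORWARD,
    INVERTED,
    DerivativeLayout,
    Fragment,
    canonicalize_layout,
    make_fragments,
)

BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class HiCConfig:
    bin_size: int = 25_000
    depth: float = 20.0  # expected counts at distance 0
    alpha: float = 1.0  # power-law decay exponent
    trans_level: float = 0.02  # trans expectation as a fraction of depth
    wt_mixture: float = 0.5  # WT allele share of the signal


@dataclass
class CallerNoise:
    jitter_sd_long: float = 0.0
    jitter_sd_short: float = 0.0
    fn_rate: float = 0.0
    n_fp_per_class: int = 10
    precise_rate: float = 0.7
    cov_mean: float = 30.0
    high_cov_value: float = 150.0
    window_size: int = 10_000


@dataclass
class JunctionConfig:
    depth: int = 6
    error_rate: float = 0.0
    max_homology: int = 10
    max_indel: int = 20
    aligned_len: int = 25
    clip_len: int = 50


@dataclass
class ExpressionConfig:
    n_genes: int = 200
    aig_near_rate: float = 0.5
    aig_background_rate: float = 0.05
    near_dist: int = 100_000
    reads_per_replicate: float = 40.0
    n_replicates: int = 3
    aig_cgr_fraction: float = 0.78


@dataclass
class HaplotypeSimConfig:
    n_phase_sets: int = 200
    reads_per_set: int = 30
    mislabel_rate: float = 0.0
    cgr_hap: str = "H2"


@dataclass
class TrackConfig:
    lad_fraction: float = 0.4
    tad_size: tuple = (400_000, 700_000)
    compartment_size: tuple = (800_000, 1_500_000)
    repeat_fraction: float = 0.05


@dataclass
class SimConfig:
    seed: int = 0
    mode: str = "chromothripsis"  # chromoplexy | chromothripsis
    n_chroms: int = 4
    chrom_length: int = 8_000_000
    n_breakpoints: int = 20  # chromothripsis total
    n_affected: int = 2  # chromothripsis chroms carrying shatter regions
    deletion_prob: float = 0.2
    min_fragment: int = 75_000
    hic: HiCConfig = field(default_factory=HiCConfig)
    caller: CallerNoise = field(default_factory=CallerNoise)
    junction: JunctionConfig = field(default_factory=JunctionConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    haplotype: HaplotypeSimConfig = field(default_factory=HaplotypeSimConfig)
    tracks: TrackConfig = field(default_factory=TrackConfig)

    def __post_init__(self):
        for p in (self.deletion_prob, self.caller.fn_rate if isinstance(self.caller, CallerNoise) else 0):
            if not (0 <= p <= 1):
                raise SimulationError(f"probability {p} outside [0, 1]")


@dataclass
class GroundTruth:
    genome: GenomeModel
    mode: str
    layouts: list[DerivativeLayout]
    adjacencies: list[NovelAdjacency]
    breakpoints: dict[str, list[int]]
    fragments: list[Fragment]
    deleted: list[Fragment]
    junction_signatures: dict[str, tuple[int, int]] = field(default_factory=dict)

    def layout_signatures(self) -> set:
        return {lay.signature() for lay in self.layouts}


# ---------------------------------------------------------------------------
# Genome with reserved zones
# ---------------------------------------------------------------------------

def build_genome(config: SimConfig) -> GenomeModel:
    """Synthetic genome: per chromosome one gap (5-7% mark), one segmental
    duplication (88% mark); a high-coverage zone at 94% is reflected in the
    coverage track, not the genome model."""
    chroms = [(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)]
    gaps = {}
    segdups = {}
    for name, length in chroms:
        gaps[name] = [(int(0.05 * length), int(0.05 * length) + 150_000)]
        segdups[name] = [(int(0.88 * length), int(0.88 * length) + 100_000)]
    return GenomeModel(chroms, gaps, segdups)


def _clean_zone(length: int) -> tuple[int, int]:
    # away from the gap (5-7%), segdup (88%), and high-coverage (94%) zones
    return int(0.15 * length), int(0.85 * length)


def _frag(chrom: str, start: int, end: int, length: int) -> Fragment:
    return Fragment(
        id=f"{chrom}:{start}-{end}",
        chrom=chrom,
        start=start,
        end=end,
        telomeric_5p=(start == 0),
        telomeric_3p=(end == length),
    )


# ---------------------------------------------------------------------------
# Rearrangement truth
# ---------------------------------------------------------------------------

def _adjacencies_from_layouts(layouts, genome) -> list[NovelAdjacency]:
    adjacencies = []
    k = 0
    for layout in layouts:
        for (fa, oa), (fb, ob) in zip(layout.members[:-1], layout.members[1:]):
            b1 = (
                Breakend(fa.chrom, fa.end, TAIL)
                if oa == FORWARD
                else Breakend(fa.chrom, fa.start, HEAD)
            )
            b2 = (
                Breakend(fb.chrom, fb.start, HEAD)
                if ob == FORWARD
                else Breakend(fb.chrom, fb.end, TAIL)
            )
            k += 1
            adjacencies.append(
                NovelAdjacency(
                    id=f"nadj_{k:04d}", bnd1=b1, bnd2=b2, caller="truth", curated=True
                ).canonicalized(genome)
            )
    return adjacencies


def simulate_rearrangement(config: SimConfig) -> GroundTruth:
    rng = np.random.default_rng(config.seed)
    genome = build_genome(config)
    if config.mode == "chromoplexy":
        truth = _simulate_chromoplexy(config, genome, rng)
    elif config.mode == "chromothripsis":
        truth = _simulate_chromothripsis(config, genome, rng)
    else:
        raise SimulationError(f"unknown mode {config.mode!r}")
    # conservation check: every fragment exactly once across layouts + deleted
    placed = [f.id for lay in truth.layouts for f, _ in lay.members]
    placed += [f.id for f in truth.deleted]
    if len(placed) != len(set(placed)):
        raise SimulationError("fragment placed twice (copy gain); not supported")
    total = sum(f.length for lay in truth.layouts for f, _ in lay.members)
    total += sum(f.length for f in truth.deleted)
    if total != genome.total_length():
        raise SimulationError("fragment lengths do not conserve genome length")
    return truth


def _simulate_chromoplexy(config, genome, rng) -> GroundTruth:
    n = config.n_chroms
    breakpoints = {}
    cut = {}
    for name, length in genome.chroms:
        lo, hi = _clean_zone(length)
        b = int(rng.integers(lo, hi))
        cut[name] = b
        breakpoints[name] = [b]
    layouts = []
    names = [c for c, _ in genome.chroms]
    for i, name in enumerate(names):
        nxt = names[(i + 1) % n]
        length = genome.lengths[name]
        frag_a = _frag(name, 0, cut[name], length)
        frag_b = _frag(nxt, cut[nxt], genome.lengths[nxt], genome.lengths[nxt])
        layouts.append(
            DerivativeLayout(
                name=f"der_{i + 1}",
                members=[(frag_a, FORWARD), (frag_b, FORWARD)],
                completeness="complete",
            )
        )
    layouts = [canonicalize_layout(lay, genome) for lay in layouts]
    fragments = make_fragments(genome, breakpoints)
    return GroundTruth(
        genome=genome,
        mode="chromoplexy",
        layouts=layouts,
        adjacencies=_adjacencies_from_layouts(layouts, genome),
        breakpoints=breakpoints,
        fragments=fragments,
        deleted=[],
    )


def _simulate_chromothripsis(config, genome, rng) -> GroundTruth:
    names = [c for c, _ in genome.chroms]
    affected = names[: config.n_affected]
    per_chrom = np.full(len(affected), config.n_breakpoints // len(affected))
    per_chrom[: config.n_breakpoints % len(affected)] += 1

    breakpoints: dict[str, list[int]] = {}
    flanks = {}
    pool: list[Fragment] = []
    if config.n_breakpoints < len(affected):
        raise SimulationError(
            "chromothripsis needs at least one breakpoint per affected chromosome"
        )
    for name, k in zip(affected, per_chrom):
        length = genome.lengths[name]
        lo = int(0.30 * length)
        hi = int(0.80 * length)
        span = hi - lo
        if k * config.min_fragment >= span:
            raise SimulationError(
                f"{k} breakpoints with min spacing {config.min_fragment} exceed "
                f"shatter region of {span} bp"
            )
        # spaced positions: sorted uniform draws with a minimum gap
        slack = span - (int(k) + 1) * config.min_fragment
        gaps = rng.multinomial(slack, np.ones(int(k) + 1) / (int(k) + 1))
        pos = []
        cursor = lo
        for i in range(int(k)):
            cursor += gaps[i] + config.min_fragment
            pos.append(int(cursor))
        breakpoints[name] = pos
        flanks[name] = (
            _frag(name, 0, pos[0], length),
            _frag(name, pos[-1], length, length),
        )
        for s, e in zip(pos[:-1], pos[1:]):
            pool.append(_frag(name, s, e, length))

    deleted = [f for f in pool if rng.random() < config.deletion_prob]
    deleted_ids = {f.id for f in deleted}
    survivors = [f for f in pool if f.id not in deleted_ids]
    order = rng.permutation(len(survivors))
    assignment = rng.integers(0, len(affected), size=len(survivors))

    layouts = []
    for ci, name in enumerate(affected):
        left, right = flanks[name]
        members = [(left, FORWARD)]
        for idx in order:
            if assignment[idx] == ci:
                frag = survivors[idx]
                orient = FORWARD if rng.random() < 0.5 else INVERTED
                members.append((frag, orient))
        members.append((right, FORWARD))
        layouts.append(
            DerivativeLayout(name=f"der_{ci + 1}", members=members, completeness="complete")
        )
    for name in names[config.n_affected:]:
        length = genome.lengths[name]
        layouts.append(
            DerivativeLayout(
                name=f"der_{name}",
                members=[(_frag(name, 0, length, length), FORWARD)],
                completeness="complete",
            )
        )
        breakpoints.setdefault(name, [])
    layouts = [canonicalize_layout(lay, genome) for lay in layouts]
    fragments = make_fragments(genome, breakpoints)
    return GroundTruth(
        genome=genome,
        mode="chromothripsis",
        layouts=layouts,
        adjacencies=_adjacencies_from_layouts(layouts, genome),
        breakpoints=breakpoints,
        fragments=fragments,
        deleted=deleted,
    )


# ---------------------------------------------------------------------------
# Coverage and caller emission
# ---------------------------------------------------------------------------

def emit_coverage(config: SimConfig) -> CoverageTrack:
    """Flat coverage at the configured mean, with the reserved high-coverage
    zone (94% mark) elevated."""
    noise = config.caller
    cov = {}
    for i in range(config.n_chroms):
        name = f"chr{i + 1}"
        length = config.chrom_length
        n_win = -(-length // noise.window_size)
        arr = np.full(n_win, noise.cov_mean)
        z0 = int(0.94 * length)
        arr[z0 // noise.window_size: z0 // noise.window_size + 5] = noise.high_cov_value
        cov[name] = arr
    return CoverageTrack(noise.window_size, cov)


def _jitter(pos: int, sd: float, length: int, rng) -> int:
    if sd <= 0:
        return pos
    return int(np.clip(round(pos + rng.normal(0, sd)), 1, length - 2))


def emit_calls(truth: GroundTruth, config: SimConfig, rng=None):
    """Noisy two-caller call sets plus a decoy cohort sample.

    Returns {'long': [...], 'short': [...], 'decoy': [...]}.  False positives
    of each filterable class are appended to the long-read set; the cohort-
    shared class also appears in the decoy sample.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    noise = config.caller
    genome = truth.genome
    support_mean = 0.5 * noise.cov_mean

    out = {"long": [], "short": [], "decoy": []}
    for adj in truth.adjacencies:
        for caller, sd in (("longread", noise.jitter_sd_long), ("shortread", noise.jitter_sd_short)):
            if rng.random() < noise.fn_rate:
                continue
            b1 = Breakend(adj.bnd1.chrom, _jitter(adj.bnd1.pos, sd, genome.lengths[adj.bnd1.chrom], rng), adj.bnd1.side)
            b2 = Breakend(adj.bnd2.chrom, _jitter(adj.bnd2.pos, sd, genome.lengths[adj.bnd2.chrom], rng), adj.bnd2.side)
            call = NovelAdjacency(
                id=f"{adj.id}.{'L' if caller == 'longread' else 'S'}",
                bnd1=b1,
                bnd2=b2,
                caller=caller,
                support=int(rng.poisson(support_mean)) + 3,
                precise=(caller == "shortread" and rng.random() < noise.precise_rate),
            )
            out["long" if caller == "longread" else "short"].append(call.canonicalized(genome))

    names = [c for c, _ in genome.chroms]
    true_bps = {c: np.asarray(v, dtype=np.int64) for c, v in truth.breakpoints.items()}

    def clean_pos(chrom, keepout: int = 2000):
        """Random position in the clean zone, away from true breakpoints so
        planted false positives stay distinct events."""
        lo, hi = _clean_zone(genome.lengths[chrom])
        bps = true_bps.get(chrom, np.array([], dtype=np.int64))
        for _ in range(1000):
            p = int(rng.integers(lo, hi))
            if bps.size == 0 or np.abs(bps - p).min() > keepout:
                return p
        raise SimulationError(f"no clean position found on {chrom}")

    def trans_pair():
        i, j = rng.choice(len(names), size=2, replace=False)
        return names[i], names[j]

    def fp(fid, b1, b2, support=None):
        return NovelAdjacency(
            id=fid,
            bnd1=b1,
            bnd2=b2,
            caller="longread",
            support=int(rng.poisson(support_mean)) + 3 if support is None else support,
        ).canonicalized(genome)

    for i in range(noise.n_fp_per_class):
        c1, c2 = trans_pair()
        out["long"].append(
            fp(f"fp_lowsupport_{i}", Breakend(c1, clean_pos(c1), TAIL),
               Breakend(c2, clean_pos(c2), HEAD), support=1)
        )
        c1, c2 = trans_pair()
        z = int(0.94 * genome.lengths[c1]) + int(rng.integers(0, 40_000))
        out["long"].append(
            fp(f"fp_highcov_{i}", Breakend(c1, z, TAIL), Breakend(c2, clean_pos(c2), HEAD))
        )
        c1, c2 = trans_pair()
        gs = genome.gaps[c1][0][0]
        out["long"].append(
            fp(f"fp_neargap_{i}", Breakend(c1, gs - 5000 - int(rng.integers(0, 4000)), TAIL),
               Breakend(c2, clean_pos(c2), HEAD))
        )
        c1, c2 = trans_pair()
        sd0 = genome.segdups[c1][0][0]
        out["long"].append(
            fp(f"fp_segdup_{i}", Breakend(c1, sd0 + int(rng.integers(0, 90_000)), TAIL),
               Breakend(c2, clean_pos(c2), HEAD))
        )
        c1, c2 = trans_pair()
        shared1 = Breakend(c1, clean_pos(c1), TAIL)
        shared2 = Breakend(c2, clean_pos(c2), HEAD)
        out["long"].append(fp(f"fp_cohort_{i}", shared1, shared2))
        out["decoy"].append(
            fp(
                f"decoy_cohort_{i}",
                Breakend(c1, shared1.pos + int(rng.integers(-300, 300)), TAIL),
                Breakend(c2, shared2.pos + int(rng.integers(-300, 300)), HEAD),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Hi-C emission
# ---------------------------------------------------------------------------

def emit_hic(truth: GroundTruth, config: SimConfig, rng=None) -> ContactMatrix:
    """Poisson-sampled overlay of the WT and derivative alleles.

    Expected counts: each allele contributes its mixture share of a power-law
    cis decay depth/(1+d)^alpha along its own chromosome order plus a small
    trans constant; the derivative allele is mapped back to reference
    coordinates through the planted layouts (deleted fragments contribute
    nothing from that allele)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    hc = config.hic
    template = ContactMatrix(hc.bin_size, truth.genome.chroms)
    B = template.n_bins
    trans_c = hc.depth * hc.trans_level

    def decay_block(n):
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        return hc.depth / (1.0 + d) ** hc.alpha

    e_wt = np.full((B, B), trans_c)
    for name, _ in truth.genome.chroms:
        off, n = template.offsets[name], template.n_bins_per_chrom[name]
        e_wt[off:off + n, off:off + n] = decay_block(n)

    vectors = [layout_bin_index(template, lay) for lay in truth.layouts]
    retained = np.concatenate([v for v in vectors if v.size]) if vectors else np.array([], int)
    e_cgr = np.zeros((B, B))
    if retained.size:
        e_cgr[np.ix_(retained, retained)] = trans_c
        for v in vectors:
            if v.size:
                e_cgr[np.ix_(v, v)] = decay_block(v.size)

    w = hc.wt_mixture
    expected = w * e_wt + (1.0 - w) * e_cgr
    iu = np.triu_indices(B)
    counts = np.zeros((B, B))
    counts[iu] = rng.poisson(expected[iu])
    counts = counts + np.triu(counts, 1).T
    return ContactMatrix(hc.bin_size, truth.genome.chroms, counts)


# ---------------------------------------------------------------------------
# Junction reads
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _mutate(seq: str, rng, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i, c in enumerate(chars):
        if rng.random() < rate:
            chars[i] = str(rng.choice(BASES[BASES != c]))
    return "".join(chars)


def plant_junction_signatures(truth: GroundTruth, config: SimConfig, rng=None):
    """Draw a (homology, indel) pair per adjacency; homology and untemplated
    insertion are exclusive mechanisms, so only homology is planted here."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    jc = config.junction
    # InDels are a property of the breakpoint coordinate (reciprocal junction
    # pairs share the clip-position offset), so adjacencies whose first
    # breakends coincide share one planted value.
    indel_at: dict[tuple[str, int], int] = {}
    for adj in truth.adjacencies:
        h = int(rng.integers(0, jc.max_homology + 1))
        coord = (adj.bnd1.chrom, adj.bnd1.pos)
        if coord not in indel_at:
            indel_at[coord] = int(rng.integers(-jc.max_indel, jc.max_indel + 1))
        truth.junction_signatures[adj.id] = (h, indel_at[coord])
    return truth.junction_signatures


def synthesize_junction_reads(genome: GenomeModel, adjacencies, signatures: dict,
                              path, rng, depth: int = 6, error_rate: float = 0.0,
                              aligned_len: int = 25, clip_len: int = 50,
                              mapq: int = 60) -> None:
    """Write a SAM file of soft-clipped reads consistent with the planted
    per-junction homology and InDel values.

    For each adjacency the first breakend is the source (reads run off it
    into target sequence; their clipped consensus carries the homology
    structure) and the second the target (its aligned consensus is the
    alignment template).  The planted InDel shifts the R group of the source
    breakend's coordinate.  Breakpoint coordinates must be far enough apart
    (> 20 kb) that fetch windows cannot mix junctions.
    """
    import pysam

    from chromoweave.signature import revcomp

    indel_at: dict[tuple[str, int], int] = {}
    for adj in adjacencies:
        _, d = signatures[adj.id]
        indel_at[(adj.bnd1.chrom, adj.bnd1.pos)] = d
    # groups[(chrom, pos, 'L'|'R')] = list of (name, pos0, cigar, seq)
    reads = []

    def emit_group(chrom, clip_pos, side, seqs, tag):
        for i, seq in enumerate(seqs):
            seq = _mutate(seq, rng, error_rate)
            if side == "L":  # right-clipped, alignment ends at clip_pos
                reads.append((chrom, clip_pos - aligned_len,
                              f"{aligned_len}M{clip_len}S", seq, f"{tag}_{i}"))
            else:  # left-clipped, alignment starts at clip_pos
                reads.append((chrom, clip_pos,
                              f"{clip_len}S{aligned_len}M", seq, f"{tag}_{i}"))

    emitted: set[tuple[str, int, str]] = set()
    for adj in adjacencies:
        h, d = signatures[adj.id]
        tc = _random_seq(rng, aligned_len)  # target consensus, junction order
        a = _random_seq(rng, aligned_len)
        if h:
            a = a[: aligned_len - h] + tc[:h]
        c = tc[h:] + _random_seq(rng, clip_len - (aligned_len - h))

        # source group at bnd1
        b1, s1 = adj.bnd1, adj.bnd1.side
        if s1 == TAIL:
            emit_group(b1.chrom, b1.pos, "L", [a + c] * depth, f"{adj.id}_src")
            emitted.add((b1.chrom, b1.pos, "L"))
        else:
            emit_group(b1.chrom, b1.pos + d, "R",
                       [revcomp(c) + revcomp(a)] * depth, f"{adj.id}_src")
            emitted.add((b1.chrom, b1.pos, "R"))

        # target group at bnd2
        b2, s2 = adj.bnd2, adj.bnd2.side
        d2 = indel_at.get((b2.chrom, b2.pos), 0)
        if s2 == HEAD:
            if (b2.chrom, b2.pos, "R") not in emitted:
                emit_group(b2.chrom, b2.pos + d2, "R",
                           [_random_seq(rng, clip_len) + tc] * depth, f"{adj.id}_tgt")
                emitted.add((b2.chrom, b2.pos, "R"))
        else:
            if (b2.chrom, b2.pos, "L") not in emitted:
                emit_group(b2.chrom, b2.pos, "L",
                           [revcomp(tc) + _random_seq(rng, clip_len)] * depth,
                           f"{adj.id}_tgt")
                emitted.add((b2.chrom, b2.pos, "L"))

    # filler groups so every source coordinate has both L and R clip groups
    for adj in adjacencies:
        _, d = signatures[adj.id]
        b1 = adj.bnd1
        if (b1.chrom, b1.pos, "L") not in emitted:
            emit_group(b1.chrom, b1.pos,
                       "L", [_random_seq(rng, aligned_len + clip_len)] * depth,
                       f"{adj.id}_fillL")
            emitted.add((b1.chrom, b1.pos, "L"))
        if (b1.chrom, b1.pos, "R") not in emitted:
            emit_group(b1.chrom, b1.pos + d, "R",
                       [_random_seq(rng, aligned_len + clip_len)] * depth,
                       f"{adj.id}_fillR")
            emitted.add((b1.chrom, b1.pos, "R"))

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome.chroms],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for chrom, pos0, cigar, seq, name in reads:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = name
            rec.reference_name = chrom
            rec.reference_start = pos0
            rec.mapping_quality = mapq
            rec.cigarstring = cigar
            rec.query_sequence = seq
            rec.flag = 0
            sam.write(rec)


def emit_junction_reads(truth: GroundTruth, config: SimConfig, path, rng=None) -> dict:
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    if not truth.junction_signatures:
        plant_junction_signatures(truth, config, np.random.default_rng(config.seed + 3))
    jc = config.junction
    synthesize_junction_reads(
        truth.genome, truth.adjacencies, truth.junction_signatures, path,
        rng=np.random.default_rng(config.seed + 4), depth=jc.depth,
        error_rate=jc.error_rate, aligned_len=jc.aligned_len, clip_len=jc.clip_len,
    )
    return truth.junction_signatures


def simulate_scaffold_permutation(seed: int, n_scaffolds: int = 5,
                                  chrom_length: int = 4_000_000,
                                  bin_size: int = 25_000, depth: float = 20.0,
                                  alpha: float = 1.0, trans_level: float = 0.02,
                                  min_bins: int = 12):
    """One derivative chromosome broken into single-fragment scaffolds with a
    hidden middle order/orientation, plus the Hi-C map it generates.

    The two telomere-bearing fragments sit at the ends (telomere outward);
    the middle fragments take a random order and orientation.  Returns
    (genome, true layout, scaffolds, matrix); the scaffolds are given in
    reference order, so the true arrangement is only recoverable from the
    map.
    """
    rng = np.random.default_rng(seed)
    genome = GenomeModel([("chr1", chrom_length)])
    n_bins = chrom_length // bin_size
    k = n_scaffolds - 1  # breakpoints
    slack = n_bins - n_scaffolds * min_bins
    if slack < 0:
        raise SimulationError("chromosome too short for the requested scaffolds")
    gaps = rng.multinomial(slack, np.ones(n_scaffolds) / n_scaffolds)
    bounds = [0]
    for i in range(k):
        bounds.append(bounds[-1] + (min_bins + int(gaps[i])))
    bounds.append(n_bins)
    frags = [
        _frag("chr1", bounds[i] * bin_size, bounds[i + 1] * bin_size, chrom_length)
        for i in range(n_scaffolds)
    ]
    middle = list(range(1, n_scaffolds - 1))
    order = [int(x) for x in rng.permutation(middle)]
    orients = [FORWARD if rng.random() < 0.5 else INVERTED for _ in order]
    members = [(frags[0], FORWARD)]
    members += [(frags[i], o) for i, o in zip(order, orients)]
    members.append((frags[-1], FORWARD))
    true_layout = DerivativeLayout(name="der_true", members=members, completeness="complete")

    scaffolds = [
        DerivativeLayout(name=f"scf_{i}", members=[(f, FORWARD)], completeness="scaffold")
        for i, f in enumerate(frags)
    ]

    template = ContactMatrix(bin_size, genome.chroms)
    vec = layout_bin_index(template, true_layout)
    B = template.n_bins
    d = np.abs(np.arange(len(vec))[:, None] - np.arange(len(vec))[None, :])
    e_cgr = depth / (1.0 + d) ** alpha
    d_wt = np.abs(np.arange(B)[:, None] - np.arange(B)[None, :])
    e_wt = depth / (1.0 + d_wt) ** alpha
    # overlay: half WT decay + half derivative decay mapped back to reference
    ix = np.ix_(vec, vec)
    exp_full = 0.5 * e_wt
    exp_full[ix] += 0.5 * e_cgr
    iu = np.triu_indices(B)
    counts = np.zeros((B, B))
    counts[iu] = rng.poisson(exp_full[iu])
    counts = counts + np.triu(counts, 1).T
    matrix = ContactMatrix(bin_size, genome.chroms, counts)
    # control individual: both alleles wild-type, independently sampled
    ctrl = np.zeros((B, B))
    ctrl[iu] = rng.poisson(e_wt[iu])
    ctrl = ctrl + np.triu(ctrl, 1).T
    control = ContactMatrix(bin_size, genome.chroms, ctrl)
    return genome, true_layout, scaffolds, matrix, control


# ---------------------------------------------------------------------------
# Tracks, genes, expression, haplotags
# ---------------------------------------------------------------------------

def _tile_blocks(length, size_range, rng):
    blocks = []
    cursor = 0
    lo, hi = size_range
    while cursor < length:
        size = int(rng.integers(lo, hi))
        blocks.append((cursor, min(cursor + size, length)))
        cursor += size
    return blocks


def emit_tracks(truth: GroundTruth, config: SimConfig, rng=None):
    """TAD partition (+boundary track), alternating A/B compartments, LADs at
    the configured genome fraction, and a sparse repeat track."""
    from chromoweave.enrichment import FeatureTrack

    rng = rng if rng is not None else np.random.default_rng(config.seed + 5)
    tc = config.tracks
    tad_iv, tad_lab = {}, {}
    bound_iv = {}
    comp_iv, comp_lab = {}, {}
    lad_iv = {}
    rep_iv, rep_lab = {}, {}
    for name, length in truth.genome.chroms:
        tads = _tile_blocks(length, tc.tad_size, rng)
        tad_iv[name] = np.array(tads)
        tad_lab[name] = [f"TAD_{i}" for i in range(len(tads))]
        bound_iv[name] = np.array(
            [(max(e - 1000, 0), min(e + 1000, length)) for _, e in tads[:-1]]
        )
        comps = _tile_blocks(length, tc.compartment_size, rng)
        comp_iv[name] = np.array(comps)
        comp_lab[name] = ["A" if i % 2 == 0 else "B" for i in range(len(comps))]
        # LAD / inter-LAD alternation sized to hit the configured fraction
        f = tc.lad_fraction
        lads = []
        cursor = 0
        while cursor < length:
            lad_len = int(rng.integers(300_000, 700_000))
            gap_len = int(lad_len * (1 - f) / f)
            if rng.random() < 0.5:
                lads.append((cursor, min(cursor + lad_len, length)))
                cursor += lad_len + gap_len
            else:
                cursor += gap_len
                if cursor < length:
                    lads.append((cursor, min(cursor + lad_len, length)))
                cursor += lad_len
        lad_iv[name] = np.array(lads)
        # repeats: short intervals at regular spacing
        spacing = int(1000 / max(tc.repeat_fraction, 1e-6))
        reps = [(p, min(p + 1000, length)) for p in range(spacing // 2, length, spacing)]
        rep_iv[name] = np.array(reps)
        classes = ["LINE", "SINE", "LTR"]
        rep_lab[name] = [classes[i % 3] for i in range(len(reps))]
    return {
        "tad": FeatureTrack("tad", tad_iv, tad_lab),
        "tad_boundary": FeatureTrack("tad_boundary", bound_iv),
        "compartment": FeatureTrack("compartment", comp_iv, comp_lab),
        "lad": FeatureTrack("lad", lad_iv),
        "repeat": FeatureTrack("repeat", rep_iv, rep_lab),
    }


def emit_genes_and_expression(truth: GroundTruth, config: SimConfig, rng=None):
    """Gene table with planted allelic-imbalance flags (probability decays
    from the near-breakpoint rate to background beyond ``near_dist``) and an
    allelic read-count table realizing those flags."""
    import pandas as pd

    from chromoweave.enrichment import _nearest_breakpoint_distance

    rng = rng if rng is not None else np.random.default_rng(config.seed + 6)
    xc = config.expression
    names = [c for c, _ in truth.genome.chroms]
    rows = []
    for i in range(xc.n_genes):
        chrom = names[int(rng.integers(0, len(names)))]
        length = truth.genome.lengths[chrom]
        while True:
            tss = int(rng.integers(0, length))
            if not truth.genome.in_gap(chrom, tss):
                break
        rows.append({"gene": f"gene_{i:04d}", "chrom": chrom, "tss": tss})
    genes = pd.DataFrame(rows)
    bps = {c: np.asarray(v, dtype=np.int64) for c, v in truth.breakpoints.items()}
    dist = _nearest_breakpoint_distance(genes, bps)
    p_aig = np.where(dist <= xc.near_dist, xc.aig_near_rate, xc.aig_background_rate)
    genes["aig"] = rng.random(len(genes)) < p_aig
    genes["distance_to_breakpoint"] = dist

    counts = []
    for rec in genes.itertuples():
        p = xc.aig_cgr_fraction if rec.aig else 0.5
        if rec.aig and rng.random() < 0.5:
            p = 1 - p  # downregulated on the rearranged allele
        for rep in range(xc.n_replicates):
            n = int(rng.poisson(xc.reads_per_replicate))
            c = int(rng.binomial(n, p)) if n else 0
            counts.append(
                {"gene": rec.gene, "replicate": f"rep{rep + 1}", "CGR": c, "WT": n - c}
            )
    return genes, pd.DataFrame(counts)


def emit_haplotags(truth: GroundTruth, config: SimConfig, rng=None):
    """Haplotagged read table consistent with the planted rearranged
    haplotype: reads at breakpoints realize WT (spanning) or CGR (one-sided
    with supplementary) alignments, mislabeled at the configured rate."""
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(config.seed + 7)
    hs = config.haplotype
    bps = [(c, p) for c, v in sorted(truth.breakpoints.items()) for p in v]
    if not bps:
        raise SimulationError("no breakpoints to anchor phase sets")
    rows = []
    for s in range(hs.n_phase_sets):
        chrom, bp = bps[s % len(bps)]
        ps = f"ps_{s:04d}"
        for r in range(hs.reads_per_set):
            hap = "H1" if rng.random() < 0.5 else "H2"
            true_class = "CGR" if hap == hs.cgr_hap else "WT"
            realized = true_class
            if rng.random() < hs.mislabel_rate:
                realized = "WT" if true_class == "CGR" else "CGR"
            if realized == "WT":
                start, end, supp = bp - 500, bp + 500, False
            else:
                start, end, supp = bp - 500, bp + int(rng.integers(0, 80)), True
            rows.append(
                {
                    "read_id": f"{ps}_r{r}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "mapq": 60,
                    "has_supplementary": supp,
                    "hap": hap,
                    "phase_set": ps,
                    "breakpoint": bp,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full emission to disk
# ---------------------------------------------------------------------------

def write_simulation(config: SimConfig, outdir) -> GroundTruth:
    """Run the full simulator and write every observable under ``outdir``."""
    import os

    from chromoweave.adjacency import write_bedpe
    from chromoweave.genome import write_bed
    from chromoweave.reconstruction import write_layout_tsv

    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "tracks"), exist_ok=True)
    truth = simulate_rearrangement(config)
    truth.genome.to_file(os.path.join(outdir, "genome.tsv"))
    write_bed(truth.genome.gaps, os.path.join(outdir, "gaps.bed"))
    write_bed(truth.genome.segdups, os.path.join(outdir, "segdups.bed"))

    calls = emit_calls(truth, config)
    write_bedpe(calls["long"], os.path.join(outdir, "calls_long.bedpe"))
    write_bedpe(calls["short"], os.path.join(outdir, "calls_short.bedpe"))
    write_bedpe(calls["decoy"], os.path.join(outdir, "calls_decoy.bedpe"))
    emit_coverage(config).to_bed(os.path.join(outdir, "coverage.bed"))

    emit_hic(truth, config).write_coo(os.path.join(outdir, "matrix.coo"))
    emit_junction_reads(truth, config, os.path.join(outdir, "junctions.sam"))

    tracks = emit_tracks(truth, config)
    for key, track in tracks.items():
        with open(os.path.join(outdir, "tracks", f"{key}.bed"), "w") as fh:
            for chrom in sorted(track.intervals):
                for i, (s, e) in enumerate(track.intervals[chrom]):
                    lab = track.labels[chrom][i] if track.labels else key
                    fh.write(f"{chrom}\t{s}\t{e}\t{lab}\n")

    genes, counts = emit_genes_and_expression(truth, config)
    genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    counts.to_csv(os.path.join(outdir, "allelic_counts.tsv"), sep="\t", index=False)
    emit_haplotags(truth, config).to_csv(
        os.path.join(outdir, "haplotags.tsv"), sep="\t", index=False
    )
    write_layout_tsv(truth.layouts, truth.deleted, os.path.join(outdir, "truth_layouts.tsv"))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(
            {
                "mode": truth.mode,
                "breakpoints": truth.breakpoints,
                "adjacencies": [
                    {
                        "id": a.id,
                        "bnd1": list(a.bnd1),
                        "bnd2": list(a.bnd2),
                    }
                    for a in truth.adjacencies
                ],
                "layouts": [
                    {"name": lay.name, "members": [[f.id, o] for f, o in lay.members]}
                    for lay in truth.layouts
                ],
                "deleted": [f.id for f in truth.deleted],
                "junction_signatures": truth.junction_signatures,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return truth
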