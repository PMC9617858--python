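"""Derivative-chromosome reconstruction from curated novel adjacencies.

Curated breakpoints cut the reference chromosomes into fragments.  Each
fragment contributes a 5' and a 3' node to a reconstruction graph (telomeric
ends contribute none); novel adjacencies add edges between fragment-end
nodes.  Once every node carries at most one adjacency edge, traversing the
maximal paths yields the ordered, oriented fragment layout of each derivative
chromosome.  Paths with telomeres at both ends are complete; others are
scaffolds; fragments with no junction evidence are singletons (candidate
deletions, classified by read coverage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx

from chromoweave.adjacency import HEAD, TAIL, Breakend, NovelAdjacency
from chromoweave.genome import GenomeModel

FORWARD = "forward"
INVERTED = "inverted"


class ReconstructionError(ValueError):
    pass


@dataclass(frozen=True)
class Fragment:
    """A reference interval between two breakpoints (or a telomere)."""

    id: str
    chrom: str
    start: int
    end: int
    telomeric_5p: bool
    telomeric_3p: bool

    def __post_init__(self):
        if self.start >= self.end:
            raise ReconstructionError(f"empty fragment {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DerivativeLayout:
    """Ordered, oriented fragments of one derivative chromosome."""

    name: str
    members: list[tuple[Fragment, str]]  # (fragment, forward|inverted)
    completeness: str  # complete | scaffold | circular
    source_adjacencies: list[str] = field(default_factory=list)

    @property
    def fragment_ids(self) -> list[str]:
        return [f.id for f, _ in self.members]

    def signature(self) -> tuple:
        return tuple((f.id, o) for f, o in self.members)

    def reversed_(self) -> "DerivativeLayout":
        flipped = [(f, FORWARD if o == INVERTED else INVERTED) for f, o in reversed(self.members)]
        return replace(self, members=flipped,
                       source_adjacencies=list(reversed(self.source_adjacencies)))

    def telomeric_ends(self) -> tuple[bool, bool]:
        """Telomere status of the layout's left and right free ends."""
        first_frag, first_orient = self.members[0]
        last_frag, last_orient = self.members[-1]
        left = first_frag.telomeric_5p if first_orient == FORWARD else first_frag.telomeric_3p
        right = last_frag.telomeric_3p if last_orient == FORWARD else last_frag.telomeric_5p
        return left, right

    @property
    def length(self) -> int:
        return sum(f.length for f, _ in self.members)


# ---------------------------------------------------------------------------
# Breakpoint simplification and fragment construction
# ---------------------------------------------------------------------------

def simplify_breakpoints(adjacencies: list[NovelAdjacency], tol: int = 50):
    """Snap near-identical breakend coordinates to a single representative.

    Single-linkage groups of per-chromosome coordinates with consecutive
    distances < ``tol`` are snapped to the leftmost coordinate of the group,
    avoiding spurious tiny fragments.  Returns (adjusted adjacencies,
    per-chromosome sorted breakpoint lists).
    """
    coords: dict[str, set[int]] = {}
    for adj in adjacencies:
        for b in adj.breakends():
            coords.setdefault(b.chrom, set()).add(b.pos)

    snap: dict[tuple[str, int], int] = {}
    breakpoints: dict[str, list[int]] = {}
    for chrom, posset in coords.items():
        poss = sorted(posset)
        reps = []
        group_start = poss[0]
        prev = poss[0]
        for p in poss[1:]:
            if p - prev < tol:
                prev = p
                continue
            reps.append(group_start)
            for q in poss:
                if group_start <= q <= prev:
                    snap[(chrom, q)] = group_start
            group_start = p
            prev = p
        reps.append(group_start)
        for q in poss:
            if group_start <= q <= prev:
                snap[(chrom, q)] = group_start
        breakpoints[chrom] = sorted(set(reps))

    adjusted = []
    for adj in adjacencies:
        b1 = Breakend(adj.bnd1.chrom, snap[(adj.bnd1.chrom, adj.bnd1.pos)], adj.bnd1.side)
        b2 = Breakend(adj.bnd2.chrom, snap[(adj.bnd2.chrom, adj.bnd2.pos)], adj.bnd2.side)
        adjusted.append(replace(adj, bnd1=b1, bnd2=b2))
    return adjusted, breakpoints


def make_fragments(genome: GenomeModel, breakpoints: dict[str, list[int]]) -> list[Fragment]:
    """Cut every chromosome at its breakpoints into tiling fragments with
    telomere flags at coordinate 0 and the chromosome end."""
    fragments = []
    for chrom, length in genome.chroms:
        bps = sorted(set(breakpoints.get(chrom, [])))
        inside = []
        for b in bps:
            if b <= 0 or b >= length:
                if b == 0:
                    warnings.warn(f"breakpoint at {chrom}:0 ignored (telomere)")
                    continue
                raise ReconstructionError(f"breakpoint {chrom}:{b} outside chromosome")
            inside.append(b)
        bounds = [0] + inside + [length]
        for s, e in zip(bounds[:-1], bounds[1:]):
            fragments.append(
                Fragment(
                    id=f"{chrom}:{s}-{e}",
                    chrom=chrom,
                    start=s,
                    end=e,
                    telomeric_5p=(s == 0),
                    telomeric_3p=(e == length),
                )
            )
    return fragments


# ---------------------------------------------------------------------------
# Graph construction, conflict resolution, traversal
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionGraph:
    genome: GenomeModel
    fragments: list[Fragment]
    graph: nx.MultiGraph  # nodes (fragment_id, '5p'|'3p'); edges keyed by adjacency id

    def conflicts(self) -> dict[tuple, list[str]]:
        """Nodes carrying more than one adjacency edge -> adjacency ids."""
        out = {}
        for node in self.graph.nodes:
            ids = [k for _, _, k in self.graph.edges(node, keys=True)]
            if len(ids) > 1:
                out[node] = sorted(ids)
        return out


def build_graph(genome: GenomeModel, fragments: list[Fragment],
                adjacencies: list[NovelAdjacency]) -> ReconstructionGraph:
    """Map each breakend to a fragment-end node and add adjacency edges.

    A ``tail`` breakend at pos attaches to the 3' node of the fragment ending
    there; a ``head`` breakend to the 5' node of the fragment starting there.
    Breakends matching no fragment boundary (or a telomeric boundary, where no
    node exists) raise.
    """
    by_end: dict[tuple[str, int], Fragment] = {}
    by_start: dict[tuple[str, int], Fragment] = {}
    for f in fragments:
        by_end[(f.chrom, f.end)] = f
        by_start[(f.chrom, f.start)] = f

    g = nx.MultiGraph()
    for f in fragments:
        if not f.telomeric_5p:
            g.add_node((f.id, "5p"))
        if not f.telomeric_3p:
            g.add_node((f.id, "3p"))

    def node_for(b: Breakend):
        if b.side == TAIL:
            frag = by_end.get((b.chrom, b.pos))
            if frag is None:
                raise ReconstructionError(
                    f"breakend {b.chrom}:{b.pos} (tail) matches no fragment 3' boundary"
                )
            if frag.telomeric_3p:
                raise ReconstructionError(
                    f"breakend {b.chrom}:{b.pos} (tail) is a telomeric boundary"
                )
            return (frag.id, "3p")
        frag = by_start.get((b.chrom, b.pos))
        if frag is None:
            raise ReconstructionError(
                f"breakend {b.chrom}:{b.pos} (head) matches no fragment 5' boundary"
            )
        if frag.telomeric_5p:
            raise ReconstructionError(
                f"breakend {b.chrom}:{b.pos} (head) is a telomeric boundary"
            )
        return (frag.id, "5p")

    for adj in adjacencies:
        n1 = node_for(adj.bnd1)
        n2 = node_for(adj.bnd2)
        g.add_edge(n1, n2, key=adj.id, adjacency=adj)
    return ReconstructionGraph(genome, fragments, g)


@dataclass(frozen=True)
class AdjacencyEvidence:
    both_tech: bool
    strand_concordant: bool
    hic_score: float


def resolve_conflicts(rg: ReconstructionGraph,
                      evidence: dict[str, AdjacencyEvidence],
                      overrides: dict[tuple, str] | None = None):
    """Keep at most one adjacency edge per node.

    At each conflicted node the edge maximal under the lexicographic key
    (both technologies, strand concordance, Hi-C support score) is kept;
    exact ties raise unless an override pins the winner for that node.
    Returns (resolved graph, list of removed adjacency ids).
    """
    overrides = overrides or {}
    g = rg.graph.copy()
    removed: list[str] = []
    changed = True
    while changed:
        changed = False
        for node in list(g.nodes):
            edges = list(g.edges(node, keys=True))
            if len(edges) <= 1:
                continue
            if node in overrides:
                winner = overrides[node]
                if winner not in {k for _, _, k in edges}:
                    raise ReconstructionError(
                        f"override for node {node} names unknown adjacency {winner}"
                    )
            else:
                def key(edge):
                    ev = evidence[edge[2]]
                    return (ev.both_tech, ev.strand_concordant, ev.hic_score)

                ranked = sorted(edges, key=key, reverse=True)
                if key(ranked[0]) == key(ranked[1]):
                    raise ReconstructionError(
                        f"evidence tie at node {node} between "
                        f"{ranked[0][2]} and {ranked[1][2]}; pin a choice via overrides"
                    )
                winner = ranked[0][2]
            for u, v, k in edges:
                if k != winner:
                    g.remove_edge(u, v, key=k)
                    removed.append(k)
                    changed = True
    return ReconstructionGraph(rg.genome, rg.fragments, g), sorted(set(removed))


def _other_end(end: str) -> str:
    return "3p" if end == "5p" else "5p"


def canonicalize_layout(layout: DerivativeLayout, genome: GenomeModel) -> DerivativeLayout:
    """Resolve the whole-layout reversal symmetry: emit the direction whose
    first fragment has the smaller (chromosome, start)."""
    first = layout.members[0][0]
    last = layout.members[-1][0]
    k_first = (genome.chrom_index(first.chrom), first.start)
    k_last = (genome.chrom_index(last.chrom), last.start)
    if k_last < k_first:
        return layout.reversed_()
    return layout


def traverse(rg: ReconstructionGraph):
    """Walk all maximal paths of the conflict-free graph.

    Returns (layouts, singletons): layouts in canonical orientation, named
    der_1, der_2, ... in order of their first fragment; fragments with no
    adjacency edge become complete single-chromosome layouts (when telomeric
    at both ends) or singletons.  Cycles are emitted as circular scaffolds
    with a warning.
    """
    g = rg.graph
    conflicts = rg.conflicts()
    if conflicts:
        raise ReconstructionError(f"graph has unresolved conflicts at {sorted(conflicts)}")
    frag_by_id = {f.id: f for f in rg.fragments}

    def adjacency_edge(fid: str, end: str):
        node = (fid, end)
        if node not in g:
            return None
        edges = list(g.edges(node, keys=True))
        return edges[0] if edges else None

    order = sorted(
        rg.fragments, key=lambda f: (rg.genome.chrom_index(f.chrom), f.start)
    )
    visited: set[str] = set()
    paths: list[DerivativeLayout] = []
    singletons: list[Fragment] = []

    def walk(start_frag: Fragment, enter_end: str) -> DerivativeLayout:
        members = []
        sources = []
        in_path: set[str] = set()
        fid, end = start_frag.id, enter_end
        while True:
            if fid in in_path:  # closed a cycle
                sources.pop()
                return DerivativeLayout("", members, "circular", sources)
            frag = frag_by_id[fid]
            visited.add(fid)
            in_path.add(fid)
            orient = FORWARD if end == "5p" else INVERTED
            members.append((frag, orient))
            exit_end = _other_end(end)
            edge = adjacency_edge(fid, exit_end)
            if edge is None:
                exit_telo = frag.telomeric_3p if exit_end == "3p" else frag.telomeric_5p
                enter_frag = members[0][0]
                enter_telo = (
                    enter_frag.telomeric_5p
                    if (members[0][1] == FORWARD)
                    else enter_frag.telomeric_3p
                )
                completeness = "complete" if (exit_telo and enter_telo) else "scaffold"
                return DerivativeLayout("", members, completeness, sources)
            u, v, key = edge
            sources.append(key)
            nxt = v if u == (fid, exit_end) else u
            fid, end = nxt[0], nxt[1]

    for frag in order:
        if frag.id in visited:
            continue
        e5 = adjacency_edge(frag.id, "5p")
        e3 = adjacency_edge(frag.id, "3p")
        if e5 is None and e3 is None:
            visited.add(frag.id)
            if frag.telomeric_5p and frag.telomeric_3p:
                paths.append(DerivativeLayout("", [(frag, FORWARD)], "complete"))
            else:
                singletons.append(frag)
            continue
        if e5 is None:
            paths.append(walk(frag, "5p"))
        elif e3 is None:
            paths.append(walk(frag, "3p"))
        # else: interior of a path (or a cycle); handled from an endpoint / below

    for frag in order:  # leftover cycles
        if frag.id in visited:
            continue
        warnings.warn(f"cycle detected at fragment {frag.id}; emitted as circular scaffold")
        layout = walk(frag, "5p")
        # trim the closing repeat if walk returned to the start
        layout = replace(layout, completeness="circular")
        paths.append(layout)

    canonical = [canonicalize_layout(p, rg.genome) for p in paths]
    canonical.sort(key=lambda p: (rg.genome.chrom_index(p.members[0][0].chrom),
                                  p.members[0][0].start))
    named = [replace(p, name=f"der_{i + 1}") for i, p in enumerate(canonical)]
    return named, singletons


def classify_singletons(singletons: list[Fragment],
                        coverage_ratio: dict[str, float],
                        lo: float = 0.6, hi: float = 0.85) -> dict[str, str]:
    """Classify leftover fragments by normalized read-coverage ratio:
    <= lo deleted, >= hi retained but unplaced, otherwise ambiguous."""
    out = {}
    for frag in singletons:
        ratio = coverage_ratio.get(frag.id)
        if ratio is None:
            out[frag.id] = "ambiguous"
        elif ratio <= lo:
            out[frag.id] = "deleted"
        elif ratio >= hi:
            out[frag.id] = "retained_unplaced"
        else:
            out[frag.id] = "ambiguous"
    return out


# ---------------------------------------------------------------------------
# Custom genomes and junction support
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).reverse_complement())


def emit_custom_genome(sequences, layouts: list[DerivativeLayout]):
    """Concatenate fragment sequences per layout (reverse-complementing
    inverted fragments).  ``sequences`` maps chromosome name to sequence (a
    dict or any indexed FASTA object).  Returns (seqs, junction table) where the
    junction table lists (derivative, junction index, position) at cumulative
    fragment boundaries."""
    seqs: dict[str, str] = {}
    junctions: list[tuple[str, int, int]] = []
    for layout in layouts:
        parts = []
        cum = 0
        for i, (frag, orient) in enumerate(layout.members):
            ref = str(sequences[frag.chrom][frag.start:frag.end])
            if frag.end > len(sequences[frag.chrom]):
                raise ReconstructionError(
                    f"fragment {frag.id} beyond sequence length of {frag.chrom}"
                )
            parts.append(_revcomp(ref) if orient == INVERTED else ref)
            cum += frag.length
            if i < len(layout.members) - 1:
                junctions.append((layout.name, i + 1, cum))
        seqs[layout.name] = "".join(parts)
    return seqs, junctions


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def junction_support(sam_path, junctions, window: int = 100) -> dict[tuple[str, int], int]:
    """Count reads whose single contiguous alignment covers
    [junction - window, junction + window] on the custom genome."""
    import pysam

    counts = {(deriv, pos): 0 for deriv, _, pos in junctions}
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for read in sam:
            if read.is_unmapped:
                continue
            chrom = read.reference_name
            for (deriv, pos), _ in list(counts.items()):
                if deriv != chrom:
                    continue
                if read.reference_start <= pos - window and read.reference_end >= pos + window:
                    counts[(deriv, pos)] += 1
    return counts


def write_layout_tsv(layouts: list[DerivativeLayout], singletons, path) -> None:
    with open(path, "w") as fh:
        fh.write("derivative\trank\tchrom\tstart\tend\torientation\tsource_adjacency\n")
        for layout in layouts:
            srcs = ["."] + list(layout.source_adjacencies)
            for rank, (frag, orient) in enumerate(layout.members):
                src = srcs[rank] if rank < len(srcs) else "."
                fh.write(
                    f"{layout.name}\t{rank}\t{frag.chrom}\t{frag.start}\t"
                    f"{frag.end}\t{orient}\t{src}\n"
                )
        for frag in singletons:
            fh.write(f"singleton\t0\t{frag.chrom}\t{frag.start}\t{frag.end}\tforward\t.\n")


def read_layout_tsv(path, genome: GenomeModel | None = None):
    """Read a layout TSV back into DerivativeLayout objects + singletons."""
    import csv

    layouts: dict[str, list] = {}
    singletons = []
    lengths = dict(genome.chroms) if genome else {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            frag = Fragment(
                id=f"{row['chrom']}:{row['start']}-{row['end']}",
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                telomeric_5p=(int(row["start"]) == 0),
                telomeric_3p=(lengths.get(row["chrom"]) == int(row["end"])),
            )
            if row["derivative"] == "singleton":
                singletons.append(frag)
            else:
                layouts.setdefault(row["derivative"], []).append((frag, row["orientation"]))
    out = [
        DerivativeLayout(name, members, "scaffold") for name, members in layouts.items()
    ]
    return out, singletons
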