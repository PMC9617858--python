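"""Breakpoint simplification, fragment graph, traversal, custom genomes."""

import numpy as np
import pytest

from chromoweave.adjacency import HEAD, TAIL, Breakend, NovelAdjacency
from chromoweave.genome import GenomeModel
from chromoweave.reconstruction import (
    FORWARD,
    INVERTED,
    AdjacencyEvidence,
    DerivativeLayout,
    Fragment,
    ReconstructionError,
    build_graph,
    classify_singletons,
    emit_custom_genome,
    junction_support,
    make_fragments,
    resolve_conflicts,
    simplify_breakpoints,
    traverse,
)


def adj(id, c1, p1, s1, c2, p2, s2):
    return NovelAdjacency(id=id, bnd1=Breakend(c1, p1, s1), bnd2=Breakend(c2, p2, s2),
                          caller="longread")


@pytest.fixture
def genome3():
    return GenomeModel([("chrA", 10_000), ("chrB", 8_000)])


class TestSimplifyBreakpoints:
    def test_near_coordinates_snap_to_leftmost(self):
        calls = [adj("a", "chrA", 1000, TAIL, "chrB", 5000, HEAD),
                 adj("b", "chrA", 1030, TAIL, "chrB", 6000, HEAD)]
        adjusted, bps = simplify_breakpoints(calls, tol=50)
        assert adjusted[0].bnd1.pos == adjusted[1].bnd1.pos == 1000
        assert bps["chrA"] == [1000]

    def test_distant_coordinates_unchanged(self):
        calls = [adj("a", "chrA", 1000, TAIL, "chrB", 5000, HEAD),
                 adj("b", "chrA", 1060, TAIL, "chrB", 6000, HEAD)]
        _, bps = simplify_breakpoints(calls, tol=50)
        assert bps["chrA"] == [1000, 1060]

    def test_single_linkage_chain_collapses(self):
        calls = [adj("a", "chrA", 1000, TAIL, "chrB", 5000, HEAD),
                 adj("b", "chrA", 1040, TAIL, "chrB", 6000, HEAD),
                 adj("c", "chrA", 1080, TAIL, "chrB", 7000, HEAD)]
        adjusted, bps = simplify_breakpoints(calls, tol=50)
        assert bps["chrA"] == [1000]
        assert {a.bnd1.pos for a in adjusted} == {1000}


class TestMakeFragments:
    def test_breakpoints_tile_chromosome(self, genome3):
        frags = make_fragments(genome3, {"chrA": [3000, 7000], "chrB": []})
        chra = [(f.start, f.end) for f in frags if f.chrom == "chrA"]
        assert chra == [(0, 3000), (3000, 7000), (7000, 10_000)]
        telo = [f for f in frags if f.chrom == "chrA"]
        assert telo[0].telomeric_5p and not telo[0].telomeric_3p
        assert telo[-1].telomeric_3p

    def test_no_breakpoints_single_telomeric_fragment(self, genome3):
        frags = make_fragments(genome3, {})
        assert all(f.telomeric_5p and f.telomeric_3p for f in frags)
        assert len(frags) == 2

    def test_breakpoint_at_zero_ignored(self, genome3):
        with pytest.warns(UserWarning):
            frags = make_fragments(genome3, {"chrA": [0, 5000]})
        assert [(f.start, f.end) for f in frags if f.chrom == "chrA"] == [
            (0, 5000), (5000, 10_000)
        ]


class TestBuildGraph:
    def test_side_to_node_mapping(self, genome3):
        frags = make_fragments(genome3, {"chrA": [3000], "chrB": [5000]})
        rg = build_graph(genome3, frags, [adj("x", "chrA", 3000, TAIL, "chrB", 5000, HEAD)])
        assert rg.graph.has_edge(("chrA:0-3000", "3p"), ("chrB:5000-8000", "5p"))

    def test_conflicting_edges_reported(self, genome3):
        frags = make_fragments(genome3, {"chrA": [3000], "chrB": [2000, 5000]})
        calls = [adj("x", "chrA", 3000, TAIL, "chrB", 2000, HEAD),
                 adj("y", "chrA", 3000, TAIL, "chrB", 5000, HEAD)]
        rg = build_graph(genome3, frags, calls)
        assert rg.conflicts() == {("chrA:0-3000", "3p"): ["x", "y"]}

    def test_unmatched_breakend_is_error(self, genome3):
        frags = make_fragments(genome3, {"chrA": [3000]})
        with pytest.raises(ReconstructionError):
            build_graph(genome3, frags, [adj("x", "chrA", 4000, TAIL, "chrB", 5000, HEAD)])

    def test_telomeric_boundary_is_error(self, genome3):
        frags = make_fragments(genome3, {"chrA": [3000], "chrB": [5000]})
        with pytest.raises(ReconstructionError):
            build_graph(genome3, frags, [adj("x", "chrA", 0, TAIL, "chrB", 5000, HEAD)])


class TestResolveConflicts:
    def _conflicted(self, genome3):
        frags = make_fragments(genome3, {"chrA": [3000], "chrB": [2000, 5000]})
        calls = [adj("x", "chrA", 3000, TAIL, "chrB", 2000, HEAD),
                 adj("y", "chrA", 3000, TAIL, "chrB", 5000, HEAD)]
        return build_graph(genome3, frags, calls)

    def test_both_technologies_beat_single(self, genome3):
        rg = self._conflicted(genome3)
        ev = {"x": AdjacencyEvidence(False, True, 9.0),
              "y": AdjacencyEvidence(True, False, 0.1)}
        resolved, removed = resolve_conflicts(rg, ev)
        assert removed == ["x"] and not resolved.conflicts()

    def test_hic_score_breaks_equal_tech(self, genome3):
        rg = self._conflicted(genome3)
        ev = {"x": AdjacencyEvidence(True, True, 5.1),
              "y": AdjacencyEvidence(True, True, 1.2)}
        resolved, removed = resolve_conflicts(rg, ev)
        assert removed == ["y"]

    def test_exact_tie_requires_override(self, genome3):
        rg = self._conflicted(genome3)
        ev = {"x": AdjacencyEvidence(True, True, 1.0),
              "y": AdjacencyEvidence(True, True, 1.0)}
        with pytest.raises(ReconstructionError):
            resolve_conflicts(rg, ev)
        resolved, removed = resolve_conflicts(
            rg, ev, overrides={("chrA:0-3000", "3p"): "y"}
        )
        assert removed == ["x"]


class TestTraverse:
    def test_wild_type_graph_yields_identity_layouts(self, genome3):
        frags = make_fragments(genome3, {})
        rg = build_graph(genome3, frags, [])
        layouts, singletons = traverse(rg)
        assert singletons == []
        assert [lay.completeness for lay in layouts] == ["complete", "complete"]
        assert all(o == FORWARD for lay in layouts for _, o in lay.members)

    def test_skipped_fragment_becomes_singleton(self, genome3):
        # A[0,b).3p -- C[c,L).5p with B[b,c) unconnected
        frags = make_fragments(genome3, {"chrA": [3000, 7000]})
        rg = build_graph(genome3, frags, [adj("x", "chrA", 3000, TAIL, "chrA", 7000, HEAD)])
        layouts, singletons = traverse(rg)
        sigs = {lay.signature() for lay in layouts}
        assert (("chrA:0-3000", FORWARD), ("chrA:7000-10000", FORWARD)) in sigs
        assert [f.id for f in singletons] == ["chrA:3000-7000"]
        (complete,) = [lay for lay in layouts if len(lay.members) == 2]
        assert complete.completeness == "complete"

    def test_tail_tail_edge_inverts_partner(self, genome3):
        frags = make_fragments(genome3, {"chrA": [3000, 7000]})
        rg = build_graph(genome3, frags, [adj("x", "chrA", 3000, TAIL, "chrA", 10_000 - 3000, TAIL)])
        layouts, singletons = traverse(rg)
        sigs = {lay.signature() for lay in layouts}
        assert (("chrA:0-3000", FORWARD), ("chrA:3000-7000", INVERTED)) in sigs

    def test_fragment_order_independence(self, genome3):
        frags = make_fragments(genome3, {"chrA": [3000, 7000], "chrB": [5000]})
        calls = [adj("x", "chrA", 3000, TAIL, "chrB", 5000, HEAD)]
        rg1 = build_graph(genome3, frags, calls)
        rg2 = build_graph(genome3, list(reversed(frags)), calls)
        lay1, s1 = traverse(rg1)
        lay2, s2 = traverse(rg2)
        assert [l.signature() for l in lay1] == [l.signature() for l in lay2]
        assert [f.id for f in s1] == [f.id for f in s2]

    def test_cycle_emitted_as_circular_scaffold(self, genome3):
        frags = make_fragments(genome3, {"chrA": [3000, 7000]})
        mid = adj("loop", "chrA", 3000, HEAD, "chrA", 7000, TAIL)
        rg = build_graph(genome3, frags, [mid])
        # the middle fragment's two ends are joined to each other -> cycle
        with pytest.warns(UserWarning, match="cycle"):
            layouts, singletons = traverse(rg)
        assert any(lay.completeness == "circular" for lay in layouts)

    def test_length_conservation(self):
        from chromoweave.simulate import SimConfig, simulate_rearrangement

        cfg = SimConfig(seed=23, mode="chromothripsis", n_breakpoints=24)
        truth = simulate_rearrangement(cfg)
        from chromoweave.reconstruction import build_graph as bg

        rg = bg(truth.genome, truth.fragments, truth.adjacencies)
        layouts, singletons = traverse(rg)
        total = sum(lay.length for lay in layouts) + sum(f.length for f in singletons)
        assert total == truth.genome.total_length()

    def test_withheld_adjacency_splits_layout(self, genome3):
        # removing an internal fragment's two junctions yields 2 scaffolds + 1 singleton
        frags = make_fragments(genome3, {"chrA": [2000, 4000, 6000, 8000]})
        # the full WT chain has an edge at every breakpoint; withholding both
        # edges of the internal fragment [4000,6000) splits the chromosome
        calls = [
            adj("e1", "chrA", 2000, TAIL, "chrA", 2000, HEAD),
            adj("e2", "chrA", 6000, TAIL, "chrA", 6000, HEAD),
            adj("e3", "chrA", 8000, TAIL, "chrA", 8000, HEAD),
        ]
        calls = [c for c in calls if c.id != "e2"]
        rg = build_graph(genome3, frags, calls)
        layouts, singletons = traverse(rg)
        chra = [lay for lay in layouts if lay.members[0][0].chrom == "chrA"]
        assert sorted(lay.completeness for lay in chra) == ["scaffold", "scaffold"]
        assert [f.id for f in singletons] == ["chrA:4000-6000"]


class TestSingletonClassification:
    def test_threshold_rules(self):
        f = Fragment(id="x", chrom="chrA", start=0, end=100, telomeric_5p=True,
                     telomeric_3p=False)
        assert classify_singletons([f], {"x": 0.5}) == {"x": "deleted"}
        assert classify_singletons([f], {"x": 1.0}) == {"x": "retained_unplaced"}
        assert classify_singletons([f], {"x": 0.7}) == {"x": "ambiguous"}
        assert classify_singletons([f], {}) == {"x": "ambiguous"}


class TestCustomGenome:
    def test_forward_concatenation_and_revcomp(self):
        seqs = {"chrA": "AAACCC", "chrB": "ACGT"}
        a = Fragment(id="a", chrom="chrA", start=0, end=6, telomeric_5p=True,
                     telomeric_3p=True)
        b = Fragment(id="b", chrom="chrB", start=0, end=4, telomeric_5p=True,
                     telomeric_3p=True)
        lay = DerivativeLayout("der", [(a, FORWARD), (b, INVERTED)], "complete")
        out, junctions = emit_custom_genome(seqs, [lay])
        assert out["der"] == "AAACCC" + "ACGT"  # revcomp of ACGT is ACGT
        lay2 = DerivativeLayout("der2", [(a, FORWARD), (b, FORWARD)], "complete")
        out2, _ = emit_custom_genome(seqs, [lay2])
        assert out2["der2"] == "AAACCCACGT"

    def test_junction_positions_are_prefix_sums(self):
        seqs = {"chrA": "A" * 100}
        parts = [
            Fragment(id=f"p{i}", chrom="chrA", start=s, end=e, telomeric_5p=False,
                     telomeric_3p=False)
            for i, (s, e) in enumerate([(0, 30), (30, 70), (70, 100)])
        ]
        lay = DerivativeLayout("der", [(p, FORWARD) for p in parts], "complete")
        _, junctions = emit_custom_genome(seqs, [lay])
        assert [(d, pos) for d, _, pos in junctions] == [("der", 30), ("der", 70)]


class TestJunctionSupport:
    def _write_sam(self, path, records):
        lines = ["@HD\tVN:1.6\tSO:unsorted", "@SQ\tSN:der\tLN:10000"]
        for name, pos, cigar in records:
            seq_len = sum(int(x) for x in __import__("re").findall(r"(\d+)[MIS=X]", cigar))
            lines.append(
                f"{name}\t0\tder\t{pos}\t60\t{cigar}\t*\t0\t0\t{'A' * seq_len}\t*"
            )
        path.write_text("\n".join(lines) + "\n")

    def test_spanning_and_nonspanning_reads(self, tmp_path):
        sam = tmp_path / "reads.sam"
        # junction at 5000 (0-based); window 100 requires covering [4900, 5100]
        self._write_sam(
            sam,
            [("spans", 4851 - 100, "400M"),  # covers 4750..5150
             ("stops_short", 4501, "490M"),  # ends at 4990
             ("split", 4801, "100M200S")],  # clipped at the junction
        )
        counts = junction_support(sam, [("der", 1, 5000)], window=100)
        assert counts[("der", 5000)] == 1


class TestSnappingProperties:
    def test_simplify_is_idempotent_and_separated(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @given(st.lists(st.integers(min_value=1, max_value=9_999), min_size=1,
                        max_size=30, unique=True))
        @settings(max_examples=100, derandomize=True, deadline=None)
        def check(positions):
            calls = [
                adj(f"a{i}", "chrA", p, TAIL, "chrB", 5000, HEAD)
                for i, p in enumerate(positions)
            ]
            adjusted, bps = simplify_breakpoints(calls, tol=50)
            # snapped breakpoints are pairwise >= tol apart
            coords = bps["chrA"]
            assert all(b - a >= 50 for a, b in zip(coords, coords[1:]))
            # idempotence: snapping again changes nothing
            again, bps2 = simplify_breakpoints(adjusted, tol=50)
            assert bps2["chrA"] == coords
            assert [a.bnd1.pos for a in again] == [a.bnd1.pos for a in adjusted]

        check()
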