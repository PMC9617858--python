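"""Novel-adjacency I/O, filter chain, and technology merge."""

import math

import numpy as np
import pytest

from chromoweave.adjacency import (
    HEAD,
    TAIL,
    Breakend,
    NovelAdjacency,
    apply_filter_chain,
    attach_small_scale,
    filter_cohort,
    filter_high_coverage,
    filter_near_gaps,
    filter_segdup,
    filter_support,
    merge_technologies,
    read_bedpe,
    select_large_scale,
)
from chromoweave.genome import CoverageTrack, GenomeError


def adj(id, c1, p1, s1, c2, p2, s2, **kw):
    return NovelAdjacency(id=id, bnd1=Breakend(c1, p1, s1), bnd2=Breakend(c2, p2, s2),
                          caller=kw.pop("caller", "longread"), **kw)


class TestReadBedpe:
    def test_strand_to_side_mapping(self, genome, tmp_path):
        p = tmp_path / "calls.bedpe"
        p.write_text("chr1\t999\t1000\tchr2\t4999\t5000\ta1\t.\t+\t-\n")
        (call,) = read_bedpe(p, genome)
        assert call.bnd1 == Breakend("chr1", 999, TAIL)
        assert call.bnd2 == Breakend("chr2", 4999, HEAD)

    def test_empty_file(self, genome, tmp_path):
        p = tmp_path / "empty.bedpe"
        p.write_text("")
        assert read_bedpe(p, genome) == []

    def test_unknown_chromosome_rejected(self, genome, tmp_path):
        p = tmp_path / "bad.bedpe"
        p.write_text("chrZ\t10\t11\tchr2\t20\t21\tx\t.\t+\t+\n")
        with pytest.raises(GenomeError):
            read_bedpe(p, genome)

    def test_extra_columns_and_canonical_order(self, genome, tmp_path):
        p = tmp_path / "calls.bedpe"
        p.write_text(
            "chr2\t100\t101\tchr1\t200\t201\tx\t.\t-\t+\t"
            "caller=shortread\tsupport=12\tprecise=true\n"
        )
        (call,) = read_bedpe(p, genome)
        # canonicalized: chr1 breakend first, sides travel with coordinates
        assert call.bnd1 == Breakend("chr1", 200, TAIL)
        assert call.bnd2 == Breakend("chr2", 100, HEAD)
        assert call.support == 12 and call.precise and call.caller == "shortread"


class TestSupportFilter:
    def test_below_five_percent_removed(self, flat_coverage):
        calls = [adj("a", "chr1", 10, TAIL, "chr2", 20, HEAD, support=1),
                 adj("b", "chr1", 30, TAIL, "chr2", 40, HEAD, support=2)]
        kept, removed = filter_support(calls, flat_coverage)
        assert [a.id for a in removed] == ["a"]  # 1 < 0.05 * 30
        assert [a.id for a in kept] == ["b"]  # 2 >= 1.5

    def test_zero_fraction_keeps_all(self, flat_coverage):
        calls = [adj("a", "chr1", 10, TAIL, "chr2", 20, HEAD, support=0)]
        kept, removed = filter_support(calls, flat_coverage, frac=0.0)
        assert removed == [] and len(kept) == 1

    def test_supportless_short_read_calls_pass(self, flat_coverage):
        calls = [adj("s", "chr1", 10, TAIL, "chr2", 20, HEAD, caller="shortread",
                     support=None)]
        kept, removed = filter_support(calls, flat_coverage)
        assert len(kept) == 1 and removed == []

    def test_zero_mean_coverage_rejected(self):
        cov = CoverageTrack(10_000, {"chr1": np.zeros(10)})
        with pytest.raises(GenomeError):
            filter_support([], cov)


class TestCoverageFilter:
    def test_high_coverage_window_removes_call(self, flat_coverage):
        flat_coverage.coverage["chr1"][5] = 100.0  # > 3 * mean
        calls = [adj("hi", "chr1", 55_000, TAIL, "chr2", 20, HEAD),
                 adj("ok", "chr1", 65_000, TAIL, "chr2", 40, HEAD)]
        kept, removed = filter_high_coverage(calls, flat_coverage)
        assert [a.id for a in removed] == ["hi"]
        assert [a.id for a in kept] == ["ok"]

    def test_infinite_factor_keeps_all(self, flat_coverage):
        flat_coverage.coverage["chr1"][5] = 1e6
        calls = [adj("hi", "chr1", 55_000, TAIL, "chr2", 20, HEAD)]
        kept, removed = filter_high_coverage(calls, flat_coverage, factor=math.inf)
        assert removed == []

    def test_breakend_outside_windows_is_error(self, flat_coverage):
        calls = [adj("x", "chr1", 999_999_999 % 10**6, TAIL, "chr2", 20, HEAD)]
        cov = CoverageTrack(10_000, {"chr1": np.full(2, 30.0), "chr2": np.full(50, 30.0)})
        with pytest.raises(GenomeError):
            filter_high_coverage(calls, cov)


class TestGapFilter:
    # gap on chr1: [100000, 200000)
    @pytest.mark.parametrize(
        "pos,removed",
        [(195_000, True),  # inside the gap
         (209_999, True),  # 9999 bp right of the gap end
         (210_000, False),  # exactly 10 kb: strict < keeps it
         (90_001, True), (90_000, False)],  # left side mirror
    )
    def test_distance_convention(self, genome, pos, removed):
        calls = [adj("g", "chr1", pos, TAIL, "chr2", 20, HEAD)]
        kept, rem = filter_near_gaps(calls, genome)
        assert (len(rem) == 1) == removed


class TestSegdupFilter:
    def test_inside_removed_halfopen_end_kept(self, genome):
        calls = [adj("in", "chr1", 600, TAIL, "chr2", 20, HEAD),
                 adj("edge", "chr1", 900, TAIL, "chr2", 40, HEAD)]
        kept, removed = filter_segdup(calls, genome)
        assert [a.id for a in removed] == ["in"]
        assert [a.id for a in kept] == ["edge"]

    def test_no_segdups_no_removal(self, genome):
        calls = [adj("x", "chr2", 100, TAIL, "chr2", 400_000, HEAD)]
        assert filter_segdup(calls, genome)[1] == []


class TestCohortFilter:
    def test_shared_adjacency_removed_in_both_samples(self):
        a = adj("a", "chr1", 10_000, TAIL, "chr2", 20_000, HEAD)
        b = adj("b", "chr1", 10_300, TAIL, "chr2", 19_700, HEAD)
        out = filter_cohort({"A": [a], "B": [b]})
        assert out["A"][0] == [] and out["B"][0] == []
        assert [x.id for x in out["A"][1]] == ["a"]

    def test_unique_adjacency_kept(self):
        a = adj("a", "chr1", 10_000, TAIL, "chr2", 20_000, HEAD)
        b = adj("b", "chr1", 300_000, TAIL, "chr2", 20_000, HEAD)
        out = filter_cohort({"A": [a], "B": [b]})
        assert [x.id for x in out["A"][0]] == ["a"]
        assert [x.id for x in out["B"][0]] == ["b"]

    def test_single_sample_cluster_survives(self):
        # two same-sample calls 500 bp apart form one cluster -> not shared
        a1 = adj("a1", "chr1", 10_000, TAIL, "chr2", 20_000, HEAD)
        a2 = adj("a2", "chr1", 10_500, TAIL, "chr2", 20_500, HEAD)
        b = adj("b", "chr1", 300_000, TAIL, "chr2", 20_000, HEAD)
        out = filter_cohort({"A": [a1, a2], "B": [b]})
        assert {x.id for x in out["A"][0]} == {"a1", "a2"}

    def test_transitive_linkage_spans_samples(self):
        # A-call links to B-call only through a second A-call (single linkage)
        a1 = adj("a1", "chr1", 10_000, TAIL, "chr2", 20_000, HEAD)
        a2 = adj("a2", "chr1", 10_900, TAIL, "chr2", 20_000, HEAD)
        b = adj("b", "chr1", 11_700, TAIL, "chr2", 20_000, HEAD)
        out = filter_cohort({"A": [a1, a2], "B": [b]})
        assert out["A"][0] == [] and out["B"][0] == []

    def test_side_mismatch_does_not_cluster(self):
        a = adj("a", "chr1", 10_000, TAIL, "chr2", 20_000, HEAD)
        b = adj("b", "chr1", 10_000, HEAD, "chr2", 20_000, HEAD)
        out = filter_cohort({"A": [a], "B": [b]})
        assert len(out["A"][0]) == 1 and len(out["B"][0]) == 1

    def test_one_sample_noop(self):
        a = adj("a", "chr1", 10_000, TAIL, "chr2", 20_000, HEAD)
        out = filter_cohort({"A": [a]})
        assert [x.id for x in out["A"][0]] == ["a"]


class TestMergeTechnologies:
    def make_pair(self, precise):
        long = adj("L", "chr1", 10_000, TAIL, "chr2", 20_000, HEAD, support=12)
        short = adj("S", "chr1", 10_050, TAIL, "chr2", 19_980, HEAD,
                    caller="shortread", precise=precise)
        return long, short

    def test_precise_short_call_wins(self):
        long, short = self.make_pair(precise=True)
        (rep,) = merge_technologies([long], [short])
        assert rep.bnd1.pos == 10_050 and rep.techs == {"longread", "shortread"}

    def test_imprecise_short_call_defers_to_long(self):
        long, short = self.make_pair(precise=False)
        (rep,) = merge_technologies([long], [short])
        assert rep.bnd1.pos == 10_000 and rep.techs == {"longread", "shortread"}

    def test_unmatched_calls_pass_through(self):
        long = adj("L", "chr1", 10_000, TAIL, "chr2", 20_000, HEAD)
        short = adj("S", "chr1", 400_000, TAIL, "chr2", 20_000, HEAD, caller="shortread")
        out = merge_technologies([long], [short])
        assert {a.id for a in out} == {"L", "S"}

    def test_output_size_identity(self, rng):
        # |merged| = |pairs| + |unmatched long| + |unmatched short|
        longs = [adj(f"L{i}", "chr1", 100_000 * (i + 1), TAIL, "chr2", 50_000, HEAD)
                 for i in range(6)]
        shorts = [adj(f"S{i}", "chr1", 100_000 * (i + 1) + 200, TAIL, "chr2", 50_100,
                      HEAD, caller="shortread") for i in range(3)]
        shorts.append(adj("S9", "chr2", 10_000, TAIL, "chr2", 490_000, HEAD,
                          caller="shortread"))
        out = merge_technologies(longs, shorts)
        assert len(out) == 3 + 3 + 1


class TestSpanSelection:
    @pytest.mark.parametrize(
        "c2,p2,large",
        [("chr2", 50_000, True),  # trans
         ("chr1", 110_000, False),  # span exactly 100 kb
         ("chr1", 110_001, True)],  # strictly greater
    )
    def test_span_rule(self, c2, p2, large):
        call = adj("x", "chr1", 10_000, TAIL, c2, p2, HEAD)
        big, small = select_large_scale([call])
        assert (len(big) == 1) == large

    def test_attach_small_scale_by_anchor_distance(self):
        curated = [adj("big", "chr1", 10_000, TAIL, "chr2", 400_000, HEAD, curated=True)]
        near = adj("near", "chr1", 10_020, TAIL, "chr1", 60_020, HEAD)
        far = adj("far", "chr1", 15_000, TAIL, "chr1", 65_000, HEAD)
        out = attach_small_scale(curated, [near, far], tol=50)
        assert {a.id for a in out} == {"big", "near"}

    def test_attach_tol_zero_requires_exact(self):
        curated = [adj("big", "chr1", 10_000, TAIL, "chr2", 400_000, HEAD, curated=True)]
        exact = adj("ex", "chr1", 10_000, TAIL, "chr1", 60_000, HEAD)
        off = adj("off", "chr1", 10_001, TAIL, "chr1", 60_001, HEAD)
        out = attach_small_scale(curated, [exact, off], tol=0)
        assert {a.id for a in out} == {"big", "ex"}


class TestFilterProperties:
    def _random_calls(self, genome, rng, n=40):
        names = [c for c, _ in genome.chroms]
        calls = []
        for i in range(n):
            c1, c2 = rng.choice(names, 2)
            calls.append(
                adj(f"r{i}", c1, int(rng.integers(0, genome.lengths[c1])), TAIL,
                    c2, int(rng.integers(0, genome.lengths[c2])), HEAD,
                    support=int(rng.integers(0, 20))).canonicalized(genome)
            )
        return calls

    def test_each_filter_partitions_input(self, genome, flat_coverage, rng):
        calls = self._random_calls(genome, rng)
        for kept, removed in (
            filter_support(calls, flat_coverage),
            filter_high_coverage(calls, flat_coverage),
            filter_near_gaps(calls, genome),
            filter_segdup(calls, genome),
        ):
            assert len(kept) + len(removed) == len(calls)
            assert {a.id for a in kept}.isdisjoint({a.id for a in removed})

    def test_filters_commute_as_predicates(self, genome, flat_coverage, rng):
        calls = self._random_calls(genome, rng)
        k1, _ = filter_near_gaps(filter_segdup(calls, genome)[0], genome)
        k2, _ = filter_segdup(filter_near_gaps(calls, genome)[0], genome)
        assert {a.id for a in k1} == {a.id for a in k2}
        k3, _ = filter_support(filter_high_coverage(calls, flat_coverage)[0], flat_coverage)
        k4, _ = filter_high_coverage(filter_support(calls, flat_coverage)[0], flat_coverage)
        assert {a.id for a in k3} == {a.id for a in k4}


class TestFilterChainOnSimulation:
    def test_planted_false_positives_removed_exactly(self):
        from chromoweave.simulate import (
            SimConfig,
            emit_calls,
            emit_coverage,
            simulate_rearrangement,
        )

        cfg = SimConfig(seed=17, mode="chromothripsis", n_breakpoints=20)
        truth = simulate_rearrangement(cfg)
        calls = emit_calls(truth, cfg)
        cov = emit_coverage(cfg)
        kept, removed = apply_filter_chain(
            calls["long"], cov, truth.genome,
            cohort={"decoy": calls["decoy"]}, sample="case",
        )
        planted_fp = {a.id for a in calls["long"] if a.id.startswith("fp_")}
        assert {a.id for a in removed} == planted_fp
        assert {a.id for a in kept} == {a.id for a in calls["long"]} - planted_fp
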