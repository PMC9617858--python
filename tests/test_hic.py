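"""Contact-matrix model: I/O, bin rounding, tiles, decay, recomposition,
control subtraction."""

import dataclasses

import numpy as np
import pytest

from chromoweave.hic import (
    ContactMatrix,
    MatrixError,
    SubBinFragment,
    extract_tile,
    fit_decay,
    inverse_layouts,
    layout_bin_index,
    make_bin_fragment,
    recompose,
    subtract_control,
)
from chromoweave.reconstruction import FORWARD, INVERTED, DerivativeLayout, Fragment


def frag(chrom, start, end, length):
    return Fragment(id=f"{chrom}:{start}-{end}", chrom=chrom, start=start, end=end,
                    telomeric_5p=(start == 0), telomeric_3p=(end == length))


def random_matrix(rng, bin_size=10_000, chroms=(("chr1", 100_000), ("chr2", 60_000))):
    m = ContactMatrix(bin_size, list(chroms))
    upper = np.triu(rng.poisson(3.0, size=(m.n_bins, m.n_bins)).astype(float))
    m._m = upper + np.triu(upper, 1).T
    return m


class TestCooIO:
    def test_round_trip_identity(self, rng, tmp_path):
        m = random_matrix(rng)
        path = tmp_path / "m.coo"
        m.write_coo(path)
        assert ContactMatrix.read_coo(path) == m

    def test_lower_triangle_entry_normalized(self, tmp_path):
        path = tmp_path / "m.coo"
        path.write_text('#{"bin_size": 10000, "chroms": [["chr1", 60000]]}\n5\t2\t3.0\n')
        with pytest.warns(UserWarning):
            m = ContactMatrix.read_coo(path)
        assert m.get(2, 5) == 3.0 and m.get(5, 2) == 3.0

    def test_missing_header_is_error(self, tmp_path):
        path = tmp_path / "m.coo"
        path.write_text("0\t0\t1.0\n")
        with pytest.raises(MatrixError):
            ContactMatrix.read_coo(path)

    def test_negative_count_is_error(self, tmp_path):
        path = tmp_path / "m.coo"
        path.write_text('#{"bin_size": 10000, "chroms": [["chr1", 60000]]}\n0\t1\t-2\n')
        with pytest.raises(MatrixError):
            ContactMatrix.read_coo(path)


class TestBinRounding:
    def test_start_up_end_down(self):
        m = ContactMatrix(25_000, [("chr1", 200_000)])
        assert m.fragment_bins("chr1", 30_000, 120_000) == (2, 4, False)

    def test_aligned_fragment(self):
        m = ContactMatrix(25_000, [("chr1", 200_000)])
        assert m.fragment_bins("chr1", 0, 25_000) == (0, 1, False)

    def test_sub_bin_flag(self):
        m = ContactMatrix(25_000, [("chr1", 200_000)])
        b0, b1, sub = m.fragment_bins("chr1", 30_000, 40_000)
        assert sub


class TestExtractTile:
    def test_matches_dense_slicing(self, rng):
        m = random_matrix(rng)
        bf1 = make_bin_fragment(m, "chr1", 20_000, 40_000)
        bf2 = make_bin_fragment(m, "chr2", 0, 30_000)
        tile = extract_tile(m, bf1, bf2)
        np.testing.assert_array_equal(
            tile, m.dense()[bf1.start_bin:bf1.end_bin, bf2.start_bin:bf2.end_bin]
        )

    def test_double_inversion_is_identity(self, rng):
        m = random_matrix(rng)
        bf1 = make_bin_fragment(m, "chr1", 0, 50_000)
        bf2 = make_bin_fragment(m, "chr1", 50_000, 100_000)
        once = extract_tile(m, bf1, bf2, invert_rows=True, invert_cols=True)
        np.testing.assert_array_equal(once[::-1, ::-1], extract_tile(m, bf1, bf2))

    def test_sub_bin_fragment_is_error(self, rng):
        m = random_matrix(rng)
        sub = make_bin_fragment(m, "chr1", 1_000, 9_000)
        with pytest.raises(SubBinFragment):
            extract_tile(m, sub, sub)


class TestDecay:
    def test_constant_matrix_gives_constant_expectation(self):
        m = ContactMatrix(10_000, [("chr1", 100_000)])
        m._m = np.full((10, 10), 4.0)
        decay = fit_decay(m)
        np.testing.assert_allclose(decay.expected, 4.0)

    def test_trans_free_matrix_has_zero_trans_expectation(self, rng):
        m = random_matrix(rng)
        # zero the trans block
        off = m.offsets["chr2"]
        m._m[:off, off:] = 0
        m._m[off:, :off] = 0
        assert fit_decay(m).trans_expectation == 0.0

    def test_planted_powerlaw_recovered(self, rng):
        n = 400
        m = ContactMatrix(10_000, [("chr1", n * 10_000)])
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        expected = 50.0 / (1.0 + d)
        upper = np.triu(rng.poisson(expected).astype(float))
        m._m = upper + np.triu(upper, 1).T
        decay = fit_decay(m)
        truth = 50.0 / (1.0 + np.arange(51))
        np.testing.assert_allclose(decay.expected[:51], truth, rtol=0.10)

    def test_nonincreasing(self, rng):
        m = random_matrix(rng)
        decay = fit_decay(m)
        assert (np.diff(decay.expected) <= 1e-12).all()

    def test_empty_matrix_is_error(self):
        m = ContactMatrix(10_000, [])
        with pytest.raises(MatrixError):
            fit_decay(m)


class TestRecompose:
    def test_identity_layout_reproduces_input(self, rng):
        m = random_matrix(rng)
        layouts = [
            DerivativeLayout(n + "_id", [(frag(n, 0, L, L), FORWARD)], "complete")
            for n, L in m.chroms
        ]
        out = recompose(m, layouts)
        np.testing.assert_array_equal(out.dense(), m.dense())

    def test_single_inverted_fragment_antitransposes_block(self, rng):
        m = random_matrix(rng, chroms=(("chr1", 100_000),))
        lay = DerivativeLayout(
            "d", [(frag("chr1", 0, 100_000, 100_000), INVERTED)], "complete"
        )
        out = recompose(m, [lay])
        np.testing.assert_array_equal(out.dense(), m.dense()[::-1, ::-1])

    def test_two_fragment_swap_remaps_every_entry(self, rng):
        m = random_matrix(rng, chroms=(("chr1", 100_000),))
        a = frag("chr1", 0, 50_000, 100_000)
        b = frag("chr1", 50_000, 100_000, 100_000)
        out = recompose(m, [DerivativeLayout("d", [(b, FORWARD), (a, FORWARD)], "complete")])
        # brute-force index remap oracle
        src = m.dense()
        perm = list(range(5, 10)) + list(range(0, 5))
        expected = src[np.ix_(perm, perm)]
        np.testing.assert_array_equal(out.dense(), expected)

    def test_total_signal_conserved_on_loss_free_layout(self, rng):
        m = random_matrix(rng, chroms=(("chr1", 100_000),))
        a = frag("chr1", 0, 30_000, 100_000)
        b = frag("chr1", 30_000, 100_000, 100_000)
        out = recompose(m, [DerivativeLayout("d", [(b, INVERTED), (a, FORWARD)], "complete")])
        assert out.total_signal() == m.total_signal()

    def test_overlapping_fragments_rejected(self, rng):
        m = random_matrix(rng, chroms=(("chr1", 100_000),))
        a = frag("chr1", 0, 60_000, 100_000)
        b = frag("chr1", 40_000, 100_000, 100_000)
        with pytest.raises(MatrixError):
            recompose(m, [DerivativeLayout("d", [(a, FORWARD), (b, FORWARD)], "complete")])

    def test_involution_recovers_source(self):
        from chromoweave.simulate import SimConfig, emit_hic, simulate_rearrangement

        cfg = SimConfig(seed=5, mode="chromothripsis", n_breakpoints=12, n_chroms=3)
        truth = simulate_rearrangement(cfg)
        m = emit_hic(truth, cfg)
        fwd = recompose(m, truth.layouts)
        inv = inverse_layouts(m, truth.layouts, fwd)
        back = recompose(fwd, inv)
        idx = np.sort(np.concatenate([layout_bin_index(m, lay) for lay in truth.layouts]))
        np.testing.assert_array_equal(back.dense(), m.dense()[np.ix_(idx, idx)])


class TestSubtractControl:
    def test_self_subtraction_halves_off_diagonal(self, rng):
        m = random_matrix(rng)
        out = subtract_control(m, m)
        off = ~np.eye(m.n_bins, dtype=bool)
        np.testing.assert_allclose(out.dense()[off], 0.5 * m.dense()[off])

    def test_zero_control_is_error(self, rng):
        m = random_matrix(rng)
        zero = ContactMatrix(m.bin_size, m.chroms)
        with pytest.raises(MatrixError):
            subtract_control(m, zero)

    def test_first_subdiagonal_exclusion_variant(self, rng):
        m = random_matrix(rng)
        ctrl = random_matrix(np.random.default_rng(99))
        out = subtract_control(m, ctrl, exclude="main_and_first")
        n = m.n_bins
        mask = np.ones((n, n), dtype=bool)
        np.fill_diagonal(mask, False)
        i = np.arange(n - 1)
        mask[i, i + 1] = mask[i + 1, i] = False
        f = 0.5 * m.dense()[mask].sum() / ctrl.dense()[mask].sum()
        np.testing.assert_allclose(
            out.dense(), np.maximum(m.dense() - f * ctrl.dense(), 0)
        )

    def test_clipping_keeps_counts_nonnegative(self, rng):
        m = random_matrix(rng)
        ctrl = random_matrix(np.random.default_rng(1))
        out = subtract_control(m, ctrl)
        assert (out.dense() >= 0).all()


class TestEctopicDetection:
    def test_junction_tiles_flagged_null_tiles_not(self):
        from chromoweave.hic import ectopic_score
        from chromoweave.simulate import SimConfig, emit_hic, simulate_rearrangement

        cfg = SimConfig(seed=5, mode="chromothripsis", n_breakpoints=12, n_chroms=3)
        truth = simulate_rearrangement(cfg)
        m = emit_hic(truth, cfg)
        decay = fit_decay(m)

        junction_pairs = set()
        for lay in truth.layouts:
            for (fa, _), (fb, _) in zip(lay.members[:-1], lay.members[1:]):
                junction_pairs.add(frozenset((fa.id, fb.id)))

        flags = {}
        frags = [f for f in truth.fragments
                 if not make_bin_fragment(m, f.chrom, f.start, f.end).sub_bin]
        for i, fa in enumerate(frags):
            for fb in frags[i + 1:]:
                if fa.chrom == fb.chrom and (fa.end == fb.start or fb.end == fa.start):
                    continue  # reference neighbours are not ectopic
                bfa = make_bin_fragment(m, fa.chrom, fa.start, fa.end)
                bfb = make_bin_fragment(m, fb.chrom, fb.start, fb.end)
                _, flagged = ectopic_score(m, decay, bfa, bfb)
                flags[frozenset((fa.id, fb.id))] = flagged

        for pair in junction_pairs:
            if pair in flags:
                assert flags[pair], f"true junction tile {pair} not flagged"
        null_tiles = [v for k, v in flags.items() if k not in junction_pairs]
        assert sum(null_tiles) / len(null_tiles) < 0.05
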