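"""Debye intensities, weighted-bin histograms and partial-histogram scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emsaxs import (
    DensityMap,
    FormFactorParams,
    build_shells,
    cross_histogram,
    debye_exact,
    debye_intensity,
    form_factor,
    pair_histogram,
    scan_histograms,
)

Q = np.linspace(0.01, 0.5, 40)


class TestFormFactor:
    @pytest.mark.parametrize(
        "q,sigma,expected",
        [(0.0, 1.0, 1.0), (1.0, 1.0, np.exp(-0.5)), (2.0, 1.0, np.exp(-2.0)),
         (0.5, 2.0, np.exp(-0.5))],
    )
    def test_closed_form(self, q, sigma, expected):
        assert form_factor(q, FormFactorParams(sigma)) == pytest.approx(expected)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            FormFactorParams(0.0)


class TestPairHistogram:
    def test_two_unit_points(self):
        h = pair_histogram(np.array([[0, 0, 0], [5, 0, 0.0]]), np.ones(2), 0.1)
        assert h.self_weight == 2.0
        np.testing.assert_allclose(h.bin_weights, [2.0])
        np.testing.assert_allclose(h.bin_centers, [5.0])

    def test_weighted_bin_center_of_mass(self):
        # two far-apart pairs whose distances (1.0, w=2) and (1.5, w=6)
        # share one 1-Angstrom bin -> centre (2*1.0 + 6*1.5) / 8 = 1.375
        positions = np.array(
            [[0, 0, 0], [1.0, 0, 0], [100, 0, 0], [101.5, 0, 0.0]]
        )
        weights = np.array([1.0, 1.0, 1.0, 3.0])
        h = pair_histogram(positions, weights, bin_width=1.0)
        k = int(1.0 / 1.0)  # the [1, 2) bin
        center = h.wr_per_bin[k] / h.weight_per_bin[k]
        assert h.weight_per_bin[k] == pytest.approx(8.0)
        assert center == pytest.approx(1.375)

    def test_centred_bins_use_midpoint(self):
        h = pair_histogram(
            np.array([[0, 0, 0], [1.2, 0, 0.0]]), np.ones(2), 1.0,
            weighted_bins=False,
        )
        np.testing.assert_allclose(h.bin_centers, [1.5])

    def test_empty_input(self):
        h = pair_histogram(np.empty((0, 3)), np.empty(0), 0.1)
        assert h.self_weight == 0.0 and h.total_weight == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 40),
        seed=st.integers(0, 10_000),
        bin_width=st.floats(0.05, 1.0),
    )
    def test_conservation_property(self, n, seed, bin_width):
        """self_weight + sum(bin_weights) == (sum w)^2 for any point set."""
        rng = np.random.default_rng(seed)
        positions = rng.uniform(0, 15, (n, 3))
        weights = rng.uniform(0.1, 3.0, n)
        h = pair_histogram(positions, weights, bin_width)
        assert h.total_weight == pytest.approx(weights.sum() ** 2, rel=1e-9)


class TestCrossHistogram:
    def test_single_pair(self):
        h = cross_histogram(
            np.array([[0, 0, 0.0]]), np.ones(1),
            np.array([[3, 0, 0.0]]), np.ones(1), 0.1,
        )
        assert h.self_weight == 0.0
        np.testing.assert_allclose(h.bin_weights, [2.0])
        np.testing.assert_allclose(h.bin_centers, [3.0])

    def test_total_identity_random_sets(self, rng):
        pa, pb = rng.uniform(0, 10, (30, 3)), rng.uniform(0, 10, (20, 3))
        wa, wb = rng.uniform(0.1, 2, 30), rng.uniform(0.1, 2, 20)
        h = cross_histogram(pa, wa, pb, wb, 0.1)
        assert h.total_weight == pytest.approx(2 * wa.sum() * wb.sum(), rel=1e-12)

    def test_self_cross_consistent_with_pair(self, rng):
        positions = rng.uniform(0, 10, (25, 3))
        weights = rng.uniform(0.1, 2, 25)
        total_cross = cross_histogram(
            positions, weights, positions, weights, 0.1
        ).total_weight
        pair = pair_histogram(positions, weights, 0.1)
        # cross(A, A) counts every ordered pair incl. i=j at distance 0:
        # 2 * [(sum w)^2] ... while pair stores (sum w)^2 split self/pairs
        assert total_cross == pytest.approx(2 * weights.sum() ** 2, rel=1e-12)
        assert pair.total_weight == pytest.approx(weights.sum() ** 2, rel=1e-12)

    def test_empty_side(self):
        h = cross_histogram(np.empty((0, 3)), np.empty(0),
                            np.array([[0, 0, 0.0]]), np.ones(1), 0.1)
        assert h.total_weight == 0.0


class TestDebye:
    def test_single_point_is_form_factor_squared(self):
        h = pair_histogram(np.zeros((1, 3)), np.ones(1), 0.1)
        np.testing.assert_allclose(debye_intensity(h, Q), form_factor(Q) ** 2)

    def test_two_point_closed_form(self):
        r = 4.0
        h = pair_histogram(np.array([[0, 0, 0], [r, 0, 0.0]]), np.ones(2), 1e-6)
        expected = 2 * form_factor(Q) ** 2 * (1 + np.sin(Q * r) / (Q * r))
        np.testing.assert_allclose(debye_intensity(h, Q), expected, rtol=1e-10)

    def test_q_zero_gives_total_weight(self, rng):
        positions = rng.uniform(0, 10, (20, 3))
        weights = rng.uniform(0.5, 2, 20)
        h = pair_histogram(positions, weights, 0.1)
        I = debye_intensity(h, np.array([0.0]))
        assert I[0] == pytest.approx(weights.sum() ** 2, rel=1e-6)

    def test_binned_matches_exact_oracle(self, rng):
        positions = rng.uniform(0, 20, (300, 3))
        weights = rng.uniform(0.5, 2, 300)
        h = pair_histogram(positions, weights, 0.1)
        binned = debye_intensity(h, Q)
        exact = debye_exact(positions, weights, Q)
        assert np.max(np.abs(binned / exact - 1)) < 1e-3

    def test_tiny_bins_converge_to_exact(self, rng):
        positions = rng.uniform(0, 8, (20, 3))
        weights = rng.uniform(0.5, 2, 20)
        h = pair_histogram(positions, weights, 1e-5)
        np.testing.assert_allclose(
            debye_intensity(h, Q), debye_exact(positions, weights, Q), rtol=1e-9
        )

    def test_exact_permutation_invariant(self, rng):
        positions = rng.uniform(0, 10, (15, 3))
        weights = rng.uniform(0.5, 2, 15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(
            debye_exact(positions, weights, Q),
            debye_exact(positions[perm], weights[perm], Q),
            rtol=1e-12,
        )

    def test_exact_bilinear_in_weights(self, rng):
        positions = rng.uniform(0, 10, (15, 3))
        weights = rng.uniform(0.5, 2, 15)
        np.testing.assert_allclose(
            debye_exact(positions, 3.0 * weights, Q),
            9.0 * debye_exact(positions, weights, Q),
            rtol=1e-12,
        )


class TestWeightedBinSuperiority:
    def test_cubic_lattice(self):
        """On an ordered lattice, centre-of-mass bins beat midpoint bins."""
        side = 6
        grid = np.indices((side, side, side)).reshape(3, -1).T * 2.0
        weights = np.ones(len(grid))
        exact = debye_exact(grid, weights, Q)
        err = {}
        for weighted in (True, False):
            h = pair_histogram(grid, weights, 0.5, weighted_bins=weighted)
            err[weighted] = np.max(np.abs(debye_intensity(h, Q) / exact - 1))
        assert err[True] < err[False]


class TestScanHistograms:
    def _random_shells(self, rng, n_voxels=200, n_levels=12):
        dens = rng.uniform(size=(10, 10, 10))
        flat = np.argsort(dens.reshape(-1))[::-1][:n_voxels]
        mask = np.zeros(1000, dtype=bool)
        mask[flat] = True
        dens_map = np.where(mask.reshape(10, 10, 10), dens, -1.0)
        dmap = DensityMap(dens_map, np.ones(3), np.zeros(3))
        levels = np.linspace(dens_map.max(), dens_map[dens_map > 0].min(), n_levels)
        return dmap, build_shells(dmap, levels)

    def test_incremental_equals_from_scratch(self, rng):
        dmap, shells = self._random_shells(rng)
        per_level = scan_histograms(shells, bin_width=0.1)
        for k, entry in enumerate(per_level):
            union_p = np.concatenate(shells.shell_positions[: k + 1])
            union_w = np.concatenate(shells.shell_weights[: k + 1])
            scratch = pair_histogram(union_p, union_w, 0.1)
            inc = entry.pp
            assert inc.self_weight == pytest.approx(scratch.self_weight, rel=1e-9)
            n = max(len(inc.weight_per_bin), len(scratch.weight_per_bin))
            a = np.pad(inc.weight_per_bin, (0, n - len(inc.weight_per_bin)))
            b = np.pad(scratch.weight_per_bin, (0, n - len(scratch.weight_per_bin)))
            np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)
            awr = np.pad(inc.wr_per_bin, (0, n - len(inc.wr_per_bin)))
            bwr = np.pad(scratch.wr_per_bin, (0, n - len(scratch.wr_per_bin)))
            np.testing.assert_allclose(awr, bwr, rtol=1e-9, atol=1e-12)

    def test_empty_shell_keeps_histogram(self):
        dmap = DensityMap(
            np.array([0.9, 0.5, 0.1]).reshape(-1, 1, 1), np.ones(3), np.zeros(3)
        )
        shells = build_shells(dmap, np.array([0.8, 0.7, 0.05]))
        per_level = scan_histograms(shells, bin_width=0.1)
        # level 1 adds nothing (no density in [0.7, 0.8))
        np.testing.assert_array_equal(
            per_level[0].pp.weight_per_bin, per_level[1].pp.weight_per_bin
        )
        assert per_level[0].pp.self_weight == per_level[1].pp.self_weight

    def test_three_single_point_shells(self):
        dmap = DensityMap(
            np.array([0.9, 0.5, 0.2]).reshape(-1, 1, 1), np.ones(3), np.zeros(3)
        )
        shells = build_shells(dmap, np.array([0.8, 0.4, 0.1]))
        final = scan_histograms(shells, bin_width=0.1)[-1].pp
        scratch = pair_histogram(
            np.concatenate(shells.shell_positions),
            np.concatenate(shells.shell_weights), 0.1,
        )
        assert final.total_weight == pytest.approx(scratch.total_weight, rel=1e-12)

    def test_waters_components_present(self, rng):
        dmap, shells = self._random_shells(rng, n_voxels=50, n_levels=4)
        waters = [rng.uniform(0, 10, (10, 3)) for _ in range(4)]
        per_level = scan_histograms(shells, waters, bin_width=0.1)
        entry = per_level[-1]
        assert entry.pw is not None and entry.ww is not None
        total_w = shells.cumulative_size(3)
        assert entry.pw.total_weight == pytest.approx(2 * total_w * 10, rel=1e-9)
        assert entry.ww.total_weight == pytest.approx(100.0, rel=1e-9)
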