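"""Rg/Ree, block-averaged errors, KDE distributions and the shape factor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confens import (
    AtomRecord,
    ConformationalEnsemble,
    InputError,
    ScalarSeries,
    Topology,
    autocorrelation,
    block_average_error,
    end_to_end_distance,
    inter_residue_distance,
    kde_distribution,
    radius_of_gyration,
    shape_factor,
    shape_factor_from_ensemble,
)
from confens._geometry import random_rotation_matrices
from confens.synthetic import ChainSpec, generate_rigid_rod


def _beads(positions, masses=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    masses = masses if masses is not None else [1.0] * n
    atoms = [
        AtomRecord("CA", "C", m, i, "GLY") for i, m in zip(range(n), masses)
    ]
    return ConformationalEnsemble(Topology(atoms), positions[np.newaxis])


def _series(values):
    values = np.asarray(values, dtype=float)
    return ScalarSeries(values, np.zeros(len(values), dtype=int), "x")


class TestRadiusOfGyration:
    def test_point_mass_is_zero(self):
        assert radius_of_gyration(_beads([[1.0, 2.0, 3.0]])).values[0] == 0.0

    def test_two_equal_masses_give_half_separation(self):
        d = 0.8
        ens = _beads([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        assert radius_of_gyration(ens).values[0] == pytest.approx(d / 2)

    def test_mass_weighting_shifts_com(self):
        ens = _beads([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]], masses=[3.0, 1.0])
        # com at 0.25; Rg^2 = (3*0.0625 + 1*0.5625)/4
        assert radius_of_gyration(ens).values[0] == pytest.approx(
            np.sqrt(0.1875)
        )

    def test_fjc_mean_square_matches_closed_form(self, fjc_ensemble):
        rg2 = radius_of_gyration(fjc_ensemble).values ** 2
        n, b = 100, 0.38
        expected = b**2 * n * (n + 2) / (6 * (n + 1))
        assert np.mean(rg2) == pytest.approx(expected, rel=0.03)

    def test_zero_total_mass_rejected(self):
        ens = _beads([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.raises(InputError):
            radius_of_gyration(ens, weights=np.zeros(2))


class TestDistances:
    def test_collinear_beads(self):
        ens = _beads([[0, 0, 0], [0.38, 0, 0], [0.76, 0, 0]])
        assert end_to_end_distance(ens).values[0] == pytest.approx(0.76)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-1, 1, size=(6, 3))
        ens = _beads(pos)
        rot = random_rotation_matrices(1, rng)[0]
        moved = _beads(pos @ rot.T + rng.uniform(-5, 5, size=3))
        assert end_to_end_distance(moved).values[0] == pytest.approx(
            end_to_end_distance(ens).values[0]
        )
        assert radius_of_gyration(moved).values[0] == pytest.approx(
            radius_of_gyration(ens).values[0]
        )

    def test_inter_residue_same_index_zero(self):
        ens = generate_rigid_rod(ChainSpec(12, 0.38, 1, seed=0))
        assert inter_residue_distance(ens, 3, 3).values[0] == 0.0

    def test_rod_separation_scales_with_index_gap(self):
        ens = generate_rigid_rod(ChainSpec(12, 0.38, 1, seed=0))
        assert inter_residue_distance(ens, 1, 9).values[0] == pytest.approx(
            8 * 0.38
        )

    def test_terminal_pair_equals_end_to_end(self):
        ens = generate_rigid_rod(ChainSpec(12, 0.38, 4, seed=1))
        np.testing.assert_allclose(
            inter_residue_distance(ens, 0, 11, atom="CA").values,
            end_to_end_distance(ens, atom="CA").values,
        )


class TestBlockAveraging:
    def test_constant_series_zero_error(self):
        res = block_average_error(_series(np.full(256, 3.14)))
        assert res.mean == pytest.approx(3.14)
        assert res.error == 0.0

    def test_mean_equals_plain_average(self, rng):
        x = rng.normal(size=4096)
        res = block_average_error(_series(x))
        assert res.mean == pytest.approx(float(x.mean()), abs=1e-12)

    def test_iid_error_matches_closed_form(self):
        rng = np.random.default_rng(2024)
        n = 2**14
        res = block_average_error(_series(rng.normal(size=n)))
        assert res.error == pytest.approx(1 / np.sqrt(n), rel=0.20)

    def test_ar1_error_matches_effective_sample_size(self):
        rng = np.random.default_rng(99)
        phi, n = 0.9, 2**16
        eps = rng.normal(size=n) * np.sqrt(1 - phi**2)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        true_se = np.sqrt((1 + phi) / (1 - phi)) / np.sqrt(n)
        res = block_average_error(_series(x))
        assert res.converged
        assert res.error == pytest.approx(true_se, rel=0.25)

    def test_short_series_warns_and_flags_unconverged(self):
        with pytest.warns(UserWarning, match="too short"):
            res = block_average_error(_series(np.arange(10.0)))
        assert not res.converged


class TestAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        acf = autocorrelation(_series(rng.normal(size=512)), 10)
        assert acf[0] == pytest.approx(1.0)

    def test_white_noise_correlations_small(self):
        rng = np.random.default_rng(7)
        n = 2**14
        acf = autocorrelation(_series(rng.normal(size=n)), 20)
        assert np.abs(acf[1:]).max() < 4 / np.sqrt(n)

    def test_ar1_decay(self):
        rng = np.random.default_rng(8)
        phi, n = 0.8, 2**16
        eps = rng.normal(size=n) * np.sqrt(1 - phi**2)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        acf = autocorrelation(_series(x), 5)
        np.testing.assert_allclose(acf[1:], phi ** np.arange(1, 6), atol=0.03)


class TestKDE:
    def test_density_integrates_to_one(self, rng):
        est = kde_distribution(_series(rng.normal(size=2000)))
        assert np.trapezoid(est.density, est.grid) == pytest.approx(1.0, abs=1e-3)

    def test_standard_normal_peak_density(self):
        rng = np.random.default_rng(3)
        est = kde_distribution(_series(rng.normal(size=100_000)))
        at_zero = np.interp(0.0, est.grid, est.density)
        assert at_zero == pytest.approx(0.3989, rel=0.05)

    def test_bimodal_sample_has_two_maxima(self):
        rng = np.random.default_rng(4)
        x = np.concatenate(
            [rng.normal(-4, 0.5, size=3000), rng.normal(4, 0.5, size=3000)]
        )
        est = kde_distribution(_series(x))
        d = est.density
        interior = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])
        assert interior.sum() == 2

    def test_degenerate_sample_rejected(self):
        with pytest.raises(InputError):
            kde_distribution(_series(np.full(100, 1.0)))


class TestShapeFactor:
    def test_identical_frames_exact_ratio_zero_error(self):
        rod = generate_rigid_rod(ChainSpec(10, 0.38, 1, seed=0))
        coords = np.repeat(rod.coordinates, 40, axis=0)
        ens = ConformationalEnsemble(rod.topology, coords)
        sf = shape_factor_from_ensemble(ens)
        single = shape_factor_from_ensemble(rod)
        assert sf.rs == pytest.approx(single.rs, abs=1e-12)
        assert sf.error == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_coil_limit(self, fjc_ensemble):
        sf = shape_factor_from_ensemble(fjc_ensemble)
        assert sf.rs == pytest.approx(6 * 101 / 102, abs=0.15)

    def test_rod_limit_exact(self):
        rod = generate_rigid_rod(ChainSpec(1001, 0.38, 1, seed=0))
        sf = shape_factor_from_ensemble(rod)
        assert sf.rs == pytest.approx(12 * 1000 / 1002, abs=1e-6)

    def test_square_of_mean_convention_differs_and_is_labelled(self, fjc_ensemble):
        ms = shape_factor_from_ensemble(fjc_ensemble, convention="mean-square")
        sm = shape_factor_from_ensemble(fjc_ensemble, convention="square-of-mean")
        assert sm.convention == "square-of-mean"
        # Ree fluctuates far more than Rg, so the square-of-mean convention
        # loses more in the numerator than in the denominator
        assert sm.rs < ms.rs

    def test_nonpositive_rg_rejected(self):
        from confens.dimensions import BlockAverageResult

        bad = BlockAverageResult(0.0, 0.0, [(1, 0.0, 0.0)])
        good = BlockAverageResult(1.0, 0.1, [(1, 0.1, 0.0)])
        with pytest.raises(InputError):
            shape_factor(bad, good)
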