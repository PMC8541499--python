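"""Medoid fitting, shared PCA, free-energy surfaces and basin recovery."""

import numpy as np
import pytest

from confens import ConformationalEnsemble, InputError
from confens._geometry import random_rotation_matrices, superpose_frames
from confens.landscape import (
    find_basins,
    free_energy_surface,
    medoid_fit,
    representative_frame,
    shared_pca,
)
from confens.synthetic import generate_multistate_ensemble


def _backbone_indices(ens):
    return np.flatnonzero(np.isin(ens.topology.atom_names, ("N", "CA", "C", "O")))


def _pairwise_rmsd(ens, i, j):
    idx = _backbone_indices(ens)
    sup = superpose_frames(ens.coordinates[[i]], ens.coordinates[j], idx)
    return float(
        np.sqrt(np.mean(np.sum((sup[0, idx] - ens.coordinates[j, idx]) ** 2, axis=1)))
    )


class TestMedoidFit:
    def test_rigid_copies_collapse_to_zero_rmsd(self, helix_peptide, rng):
        rots = random_rotation_matrices(8, rng)
        base = helix_peptide.coordinates[0]
        center = base.mean(axis=0)
        coords = np.einsum("fij,aj->fai", rots, base - center) + rng.uniform(
            -3, 3, size=(8, 1, 3)
        )
        ens = ConformationalEnsemble(helix_peptide.topology, coords)
        aligned, _ = medoid_fit(ens)
        spread = aligned.coordinates - aligned.coordinates[0]
        assert np.sqrt(np.mean(spread**2)) < 1e-6  # nm

    def test_medoid_matches_exhaustive_search(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        toy = ens.frames(np.arange(7))
        _, medoid = medoid_fit(toy)
        sums = [
            sum(_pairwise_rmsd(toy, i, j) for j in range(7)) for i in range(7)
        ]
        assert medoid == int(np.argmin(sums))

    def test_fit_is_idempotent(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        toy = ens.frames(np.arange(30))
        once, _ = medoid_fit(toy)
        twice, _ = medoid_fit(once)
        assert np.abs(twice.coordinates - once.coordinates).max() < 1e-9


class TestSharedPCA:
    def test_repeated_conformation_has_no_variance(self, helix_peptide):
        coords = np.repeat(helix_peptide.coordinates, 20, axis=0)
        ens = ConformationalEnsemble(helix_peptide.topology, coords)
        basis, proj, _ = shared_pca(ens)
        assert basis.explained_variance.max() < 1e-12
        assert np.abs(proj).max() < 1e-6

    def test_components_orthonormal_and_reconstruction(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        sub = ens.frames(np.arange(0, 400))
        basis, proj, _ = shared_pca(sub, n_components=10**9)  # keep all
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)
        aligned, _ = medoid_fit(sub)
        idx = _backbone_indices(sub)
        flat = aligned.coordinates[:, idx].reshape(400, -1)
        recon = basis.mean_structure + basis.project(flat) @ basis.components
        np.testing.assert_allclose(recon, flat, atol=1e-8)

    def test_pc1_sign_recovers_generation_labels(self, two_state_conformers):
        ens, labels = generate_multistate_ensemble(
            list(two_state_conformers),
            (0.5, 0.5),
            noise_sd=0.02,
            n_frames=2000,
            seed=3,
            return_labels=True,
        )
        _, proj, _ = shared_pca(ens)
        cluster = (proj[:, 0] > 0).astype(int)
        agreement = max((cluster == labels).mean(), (cluster != labels).mean())
        assert agreement >= 0.99

    def test_identical_inputs_give_identical_projections(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        sub = ens.frames(np.arange(300))
        basis, proj_a, proj_b = shared_pca(sub, sub)
        np.testing.assert_allclose(proj_a, proj_b, atol=1e-10)
        _, proj_single, _ = shared_pca(sub)
        # same landscape up to a global sign per component
        for d in range(proj_single.shape[1]):
            assert np.allclose(proj_a[:, d], proj_single[:, d], atol=1e-8) or np.allclose(
                proj_a[:, d], -proj_single[:, d], atol=1e-8
            )

    def test_atom_count_mismatch_rejected(self, two_state_ensemble, helix_peptide):
        from confens import StructuralError
        from confens.synthetic import BackboneGeometry, build_backbone

        small = build_backbone("AAAA", BackboneGeometry.extended(4))
        ens, _ = two_state_ensemble
        with pytest.raises(StructuralError):
            shared_pca(ens.frames(np.arange(120)), small)


class TestFreeEnergySurface:
    def test_minimum_near_centroid_and_shifted_to_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20_000, 2))
        surf = free_energy_surface(pts)
        assert surf.free_energy.min() == 0.0
        i, j = np.unravel_index(np.argmin(surf.free_energy), surf.free_energy.shape)
        cell = surf.pc1_grid[1] - surf.pc1_grid[0]
        assert abs(surf.pc1_grid[i] - pts[:, 0].mean()) < 10 * cell
        assert abs(surf.pc2_grid[j] - pts[:, 1].mean()) < 10 * cell

    def test_two_sigma_ring_is_about_two_rt(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30_000, 2))
        surf = free_energy_surface(pts)
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (surf.pc1_grid, surf.pc2_grid), surf.free_energy
        )
        ang = np.linspace(0, 2 * np.pi, 73)[:-1]
        ring = np.column_stack([2 * np.cos(ang), 2 * np.sin(ang)])
        assert float(interp(ring).mean()) == pytest.approx(2.0, abs=0.15)

    def test_degenerate_projections_rejected(self):
        pts = np.zeros((500, 2))
        pts[:, 0] = np.random.default_rng(0).normal(size=500)
        with pytest.raises(InputError):
            free_energy_surface(pts)


class TestBasins:
    def test_two_state_populations_and_free_energy_gap(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        _, proj, _ = shared_pca(ens)
        surf = free_energy_surface(proj)
        basins = find_basins(surf)
        assert len(basins) == 2
        assert basins[0].population == pytest.approx(0.7, abs=0.05)
        assert basins[1].population == pytest.approx(0.3, abs=0.05)
        gap = basins[1].minimum_energy - basins[0].minimum_energy
        assert gap == pytest.approx(np.log(7 / 3), abs=0.2)

    def test_unimodal_cloud_single_low_basin(self):
        rng = np.random.default_rng(2)
        surf = free_energy_surface(rng.normal(size=(5000, 2)))
        basins = find_basins(surf)
        assert len(basins) == 1
        assert basins[0].energy_class == "<=1RT"

    def test_populations_sum_to_one_when_level_unbounded(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        _, proj, _ = shared_pca(ens)
        surf = free_energy_surface(proj)
        basins = find_basins(surf, max_level=1e9)
        assert sum(b.population for b in basins) == pytest.approx(1.0, abs=0.01)

    def test_populations_never_exceed_one(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        _, proj, _ = shared_pca(ens)
        basins = find_basins(free_energy_surface(proj), max_level=3.0)
        assert sum(b.population for b in basins) <= 1.0

    def test_representative_of_majority_basin_has_majority_label(
        self, two_state_ensemble
    ):
        ens, labels = two_state_ensemble
        _, proj, _ = shared_pca(ens)
        surf = free_energy_surface(proj)
        basins = find_basins(surf)
        assert labels[basins[0].representative_frame] == 0

    def test_representative_projection_inside_basin_cells(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        _, proj, _ = shared_pca(ens)
        surf = free_energy_surface(proj)
        for basin in find_basins(surf):
            rep = representative_frame(basin, surf)
            from confens.landscape import _nearest_cell

            i = _nearest_cell(np.array([surf.projections[rep, 0]]), surf.pc1_grid)[0]
            j = _nearest_cell(np.array([surf.projections[rep, 1]]), surf.pc2_grid)[0]
            assert basin.cells[i, j]

    def test_landscape_invariant_under_global_rigid_motion(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        sub = ens.frames(np.arange(500))
        rng = np.random.default_rng(9)
        rot = random_rotation_matrices(1, rng)[0]
        moved = sub.with_coordinates(sub.coordinates @ rot.T + np.array([5.0, 1.0, -2.0]))
        _, proj_a, _ = shared_pca(sub)
        _, proj_b, _ = shared_pca(moved)
        np.testing.assert_allclose(proj_a, proj_b, atol=1e-8)

    def test_majority_population_recovery_over_seeds(self, two_state_conformers):
        """Mean recovered majority-basin population over 10 seeds of the
        70/30 two-state generator stays in [0.65, 0.75]."""
        majors = []
        for seed in range(10):
            ens = generate_multistate_ensemble(
                list(two_state_conformers),
                (0.7, 0.3),
                noise_sd=0.03,
                n_frames=1500,
                seed=seed,
            )
            _, proj, _ = shared_pca(ens)
            basins = find_basins(free_energy_surface(proj, grid_size=150))
            majors.append(basins[0].population)
        assert 0.65 <= float(np.mean(majors)) <= 0.75
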