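"""Contact maps, hydrogen-bond criterion, salt bridges and cation-pi."""

import numpy as np
import pytest

from confens import (
    AtomRecord,
    ConformationalEnsemble,
    CriterionError,
    InputError,
    Topology,
)
from confens.interactions import (
    cation_pi_table,
    contact_delta,
    contact_map,
    hydrogen_bonds,
    salt_bridge_table,
)
from confens.synthetic import build_interaction_fixture


def _random_residue_ensemble(rng, n_res=5, atoms_per_res=3, n_frames=20, scale=0.6):
    atoms = []
    for r in range(n_res):
        for k in range(atoms_per_res):
            atoms.append(AtomRecord(f"C{k}", "C", 12.011, r, "ALA"))
    coords = rng.uniform(0, scale, size=(n_frames, len(atoms), 3))
    return ConformationalEnsemble(Topology(atoms), coords)


def _brute_force_map(ens, cutoff):
    n_res = ens.n_residues
    res = ens.topology.residue_index
    prob = np.zeros((n_res, n_res))
    for f in range(ens.n_frames):
        frame = ens.coordinates[f]
        for i in range(n_res):
            for j in range(n_res):
                if i == j:
                    continue
                hit = any(
                    np.linalg.norm(frame[a] - frame[b]) < cutoff
                    for a in np.flatnonzero(res == i)
                    for b in np.flatnonzero(res == j)
                )
                prob[i, j] += hit
    prob /= ens.n_frames
    np.fill_diagonal(prob, 1.0)
    return prob


class TestContactMap:
    def test_fixture_below_cutoff_always_in_contact(self):
        cm = contact_map(build_interaction_fixture("contact", 0.35))
        assert cm.probability[0, 1] == 1.0

    def test_fixture_above_cutoff_never_in_contact(self):
        cm = contact_map(build_interaction_fixture("contact", 0.45))
        assert cm.probability[0, 1] == 0.0

    def test_matches_brute_force_oracle_exactly(self, rng):
        ens = _random_residue_ensemble(rng)
        cm = contact_map(ens, cutoff=0.4)
        np.testing.assert_array_equal(cm.probability, _brute_force_map(ens, 0.4))

    def test_hydrogens_excluded_by_default(self):
        atoms = [
            AtomRecord("CB", "C", 12.011, 0, "ALA"),
            AtomRecord("HB", "H", 1.008, 0, "ALA"),
            AtomRecord("CB", "C", 12.011, 1, "ALA"),
        ]
        # hydrogen of residue 0 is within the cutoff, its heavy atom is not
        coords = np.array([[[0.0, 0, 0], [0.45, 0, 0], [0.7, 0, 0]]])
        ens = ConformationalEnsemble(Topology(atoms), coords)
        assert contact_map(ens).probability[0, 1] == 0.0
        assert contact_map(ens, heavy_only=False).probability[0, 1] == 1.0

    def test_probabilities_invariant_under_frame_reordering(self, rng):
        ens = _random_residue_ensemble(rng, n_frames=30)
        perm = rng.permutation(30)
        shuffled = ens.frames(perm)
        np.testing.assert_array_equal(
            contact_map(ens).probability, contact_map(shuffled).probability
        )


class TestContactDelta:
    def test_self_delta_zero(self, rng):
        cm = contact_map(_random_residue_ensemble(rng))
        np.testing.assert_array_equal(contact_delta(cm, cm), 0.0)

    def test_bounds_and_antisymmetry(self, rng):
        a = contact_map(_random_residue_ensemble(rng))
        b = contact_map(_random_residue_ensemble(np.random.default_rng(5)))
        d = contact_delta(a, b)
        assert d.min() >= -1.0 and d.max() <= 1.0
        np.testing.assert_array_equal(d, -contact_delta(b, a))

    def test_cutoff_mismatch_rejected(self, rng):
        ens = _random_residue_ensemble(rng)
        with pytest.raises(InputError):
            contact_delta(contact_map(ens, 0.4), contact_map(ens, 0.5))


def _hbond_triple(r_da, theta_deg):
    """Donor at origin, H on +x, acceptor at distance r_da with the
    requested H-donor-acceptor angle."""
    atoms = [
        AtomRecord("N", "N", 14.007, 0, "ALA"),
        AtomRecord("H", "H", 1.008, 0, "ALA"),
        AtomRecord("O", "O", 15.999, 1, "ALA"),
    ]
    th = np.radians(theta_deg)
    coords = np.array(
        [[[0.0, 0, 0], [0.1, 0, 0], [r_da * np.cos(th), r_da * np.sin(th), 0]]]
    )
    return ConformationalEnsemble(Topology(atoms), coords)


class TestHydrogenBondCriterion:
    @pytest.mark.parametrize(
        "r_da,theta,expected",
        [
            (0.28, 10.0, True),  # bound 0.33 - 0.00044*100 = 0.286 nm
            (0.40, 0.0, False),  # exceeds the zero-angle bound 0.33 nm
            (0.30, 30.0, False),  # bound 0.33 - 0.396 < 0: impossible
        ],
    )
    def test_angle_dependent_distance_rule(self, r_da, theta, expected):
        ens = _hbond_triple(r_da, theta)
        bonded = hydrogen_bonds(ens, donors=[(0, 1)], acceptors=[2])
        assert bool(bonded[0, 0, 0]) is expected

    def test_no_donors_raises_criterion_error(self):
        ens = _hbond_triple(0.28, 10.0)
        with pytest.raises(CriterionError, match="hydrogens"):
            hydrogen_bonds(ens, donors=[], acceptors=[2])


class TestSaltBridges:
    def test_fixture_bridged_every_frame(self):
        table = salt_bridge_table(build_interaction_fixture("salt_bridge", 0.28))
        row = table.table.iloc[0]
        assert row.donor == "ARG1" and row.acceptor == "SEP2"
        assert row.probability_pct == 100.0

    def test_pair_out_of_range_never_bridged(self):
        table = salt_bridge_table(build_interaction_fixture("salt_bridge", 0.50))
        assert table.table.probability_pct.iloc[0] == 0.0

    def test_bridge_implies_contact_at_standard_cutoff(self):
        fixture = build_interaction_fixture("salt_bridge", 0.28)
        assert salt_bridge_table(fixture).table.probability_pct.iloc[0] == 100.0
        assert contact_map(fixture).probability[0, 1] == 1.0

    def test_no_phospho_residues_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            table = salt_bridge_table(build_interaction_fixture("contact", 0.3))
        assert len(table.table) == 0

    def test_replicate_error_is_standard_error_of_replicate_means(self):
        # five replicates of 10 frames with bridged fractions .4/.5/.5/.6/.5
        base = build_interaction_fixture("salt_bridge", 0.28)
        far = base.coordinates[0].copy()
        res1 = base.topology.residue_index == 1
        far[res1] += 10.0  # move the acceptor residue out of range
        fracs = [0.4, 0.5, 0.5, 0.6, 0.5]
        frames, rep = [], []
        for r, f in enumerate(fracs):
            n_on = int(round(10 * f))
            for k in range(10):
                frames.append(base.coordinates[0] if k < n_on else far)
                rep.append(r)
        ens = ConformationalEnsemble(
            base.topology, np.array(frames), np.array(rep)
        )
        row = salt_bridge_table(ens).table.iloc[0]
        assert row.probability_pct == pytest.approx(50.0)
        expected_err = 100 * np.std(fracs, ddof=1) / np.sqrt(5)
        assert row.error_pct == pytest.approx(expected_err)

    def test_errors_invariant_under_replicate_relabelling(self):
        base = build_interaction_fixture("salt_bridge", 0.28)
        far = base.coordinates[0].copy()
        far[base.topology.residue_index == 1] += 10.0
        frames = [base.coordinates[0]] * 6 + [far] * 6
        rep_a = [0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1]
        rep_b = [1, 1, 1, 0, 0, 0, 1, 1, 1, 0, 0, 0]
        t_a = salt_bridge_table(
            ConformationalEnsemble(base.topology, np.array(frames), np.array(rep_a))
        )
        t_b = salt_bridge_table(
            ConformationalEnsemble(base.topology, np.array(frames), np.array(rep_b))
        )
        assert t_a.table.error_pct.iloc[0] == pytest.approx(
            t_b.table.error_pct.iloc[0]
        )


class TestCationPi:
    @pytest.mark.parametrize(
        "sep,expected", [(0.55, 100.0), (0.60, 100.0), (0.65, 0.0)]
    )
    def test_two_distance_criterion_inclusive(self, sep, expected):
        table = cation_pi_table(build_interaction_fixture("cation_pi", sep))
        assert table.table.probability_pct.iloc[0] == expected

    def test_both_distances_required(self):
        ens = build_interaction_fixture("cation_pi", 0.55)
        coords = ens.coordinates.copy()
        topo = ens.topology
        tyr_cz = topo.atom_indices(residue=1, name="CZ")[0]
        arg_cz = topo.atom_indices(residue=0, name="CZ")[0]
        # push the tyrosine CZ out to 0.65 nm while CG stays at 0.55 nm
        v = coords[0, tyr_cz] - coords[0, arg_cz]
        coords[0, tyr_cz] = coords[0, arg_cz] + v / np.linalg.norm(v) * 0.65
        moved = ConformationalEnsemble(topo, coords)
        assert cation_pi_table(moved).table.probability_pct.iloc[0] == 0.0

    def test_no_pairs_gives_empty_table(self):
        table = cation_pi_table(build_interaction_fixture("contact", 0.3))
        assert len(table.table) == 0

    def test_alternative_cation_atom_selectable(self):
        ens = build_interaction_fixture("cation_pi", 0.55)
        table = cation_pi_table(ens, cation_atom="NE")
        assert table.parameters["cation_atom"] == "NE"
        assert len(table.table) == 1
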