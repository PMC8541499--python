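"""Synthetic ensembles and geometric fixtures with known ground truth.

Every analysis stage in this package is validated against inputs whose
statistics or geometry are known exactly, so the whole pipeline can be
exercised without molecular-dynamics trajectories:

* freely-jointed (ideal Gaussian-coil) chains and rigid rods with closed-form
  polymer statistics, the two reference shapes of the shape factor;
* full-backbone peptides built at prescribed (phi, psi) dihedrals — ideal
  alpha-helix, 3_10-helix, polyproline II, extended strand — for testing the
  secondary-structure assignment;
* minimal two-residue fixtures with salt-bridge, cation-pi or plain-contact
  geometry at controlled distances;
* multi-state, multi-replicate ensembles with known state populations for
  free-energy-landscape basin recovery.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._errors import InputError, StructuralError
from ._geometry import _unit, place_atom, random_rotation_matrices
from .io import AtomRecord, ConformationalEnsemble, Topology, mass_of_element

__all__ = [
    "ChainSpec",
    "BackboneGeometry",
    "generate_gaussian_chain",
    "generate_rigid_rod",
    "build_backbone",
    "build_interaction_fixture",
    "build_two_strand_sheet",
    "generate_multistate_ensemble",
]


@dataclass(frozen=True)
class ChainSpec:
    """Bead-chain specification: ``n_residues`` beads joined by bonds of
    fixed length ``bond_length`` (nm), ``n_frames`` independent frames."""

    n_residues: int
    bond_length: float = 0.38
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise InputError("n_residues must be >= 2")
        if self.bond_length <= 0:
            raise InputError("bond_length must be positive")
        if self.n_frames < 1:
            raise InputError("n_frames must be >= 1")


def _bead_topology(n: int) -> Topology:
    # one pseudo-atom per residue; named CA so the default Ree endpoints apply
    return Topology(
        [
            AtomRecord(
                name="CA",
                element="C",
                mass=1.0,
                residue_index=i,
                residue_name="GLY",
            )
            for i in range(n)
        ]
    )


def generate_gaussian_chain(spec: ChainSpec) -> ConformationalEnsemble:
    """Freely-jointed chain of point beads with unit equal masses.

    Each bond is an independent uniformly random direction of length
    ``bond_length``, so the closed forms of the ideal Gaussian coil hold:
    <Ree^2> = N b^2 and <Rg^2> = b^2 N(N+2) / (6(N+1)) for N bonds.
    """
    rng = np.random.default_rng(spec.seed)
    n_bonds = spec.n_residues - 1
    directions = rng.normal(size=(spec.n_frames, n_bonds, 3))
    directions /= np.linalg.norm(directions, axis=2, keepdims=True)
    bonds = directions * spec.bond_length
    coords = np.zeros((spec.n_frames, spec.n_residues, 3))
    coords[:, 1:] = np.cumsum(bonds, axis=1)
    return ConformationalEnsemble(_bead_topology(spec.n_residues), coords)


def generate_rigid_rod(spec: ChainSpec) -> ConformationalEnsemble:
    """Collinear equally spaced beads; frames differ only by a rigid
    rotation and translation drawn from the seed."""
    rng = np.random.default_rng(spec.seed)
    axis_coords = np.zeros((spec.n_residues, 3))
    axis_coords[:, 0] = np.arange(spec.n_residues) * spec.bond_length
    rots = random_rotation_matrices(spec.n_frames, rng)
    shifts = rng.normal(scale=1.0, size=(spec.n_frames, 1, 3))
    coords = np.einsum("fij,aj->fai", rots, axis_coords) + shifts
    return ConformationalEnsemble(_bead_topology(spec.n_residues), coords)


# ---------------------------------------------------------------------------
# Full-backbone peptide construction
# ---------------------------------------------------------------------------

# ideal backbone internal coordinates (nm / degrees)
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1229
BOND_N_H = 0.1010
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_KNOWN_RESIDUES = set(_THREE_LETTER.values()) | {"SEP", "TPO", "PTR"}


@dataclass(frozen=True)
class BackboneGeometry:
    """Per-residue backbone dihedrals (degrees); bond lengths/angles fixed
    at the ideal values above, omega fixed at 180 degrees."""

    phi: tuple[float, ...]
    psi: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.phi) != len(self.psi):
            raise InputError("phi and psi must have the same length")
        for ang in (*self.phi, *self.psi):
            if not (-180.0 < ang <= 180.0):
                raise InputError(f"dihedral {ang} outside (-180, 180]")

    @classmethod
    def uniform(cls, phi: float, psi: float, n_residues: int) -> "BackboneGeometry":
        return cls(phi=(phi,) * n_residues, psi=(psi,) * n_residues)

    @classmethod
    def alpha_helix(cls, n_residues: int) -> "BackboneGeometry":
        return cls.uniform(-57.0, -47.0, n_residues)

    @classmethod
    def three_ten_helix(cls, n_residues: int) -> "BackboneGeometry":
        return cls.uniform(-49.0, -26.0, n_residues)

    @classmethod
    def ppii(cls, n_residues: int) -> "BackboneGeometry":
        return cls.uniform(-75.0, 145.0, n_residues)

    @classmethod
    def extended(cls, n_residues: int) -> "BackboneGeometry":
        return cls.uniform(-139.0, 135.0, n_residues)


def _normalize_sequence(sequence: Sequence[str] | str) -> list[str]:
    out = []
    for code in sequence:
        code = code.upper()
        if len(code) == 1:
            if code not in _THREE_LETTER:
                raise InputError(f"unknown residue code {code!r}")
            code = _THREE_LETTER[code]
        if code not in _KNOWN_RESIDUES:
            raise InputError(f"unknown residue code {code!r}")
        out.append(code)
    return out


def build_backbone(
    sequence: Sequence[str] | str,
    geometry: BackboneGeometry,
    chain_id: str = "A",
    residue_offset: int = 0,
) -> ConformationalEnsemble:
    """Single-frame full-backbone peptide at the requested dihedrals.

    Atoms per residue: N, H, CA, C, O (no amide H on proline or on the
    first residue, whose amine is not part of a peptide plane).  The amide H
    is placed on the N-H vector antiparallel to the preceding carbonyl C=O.
    Dihedrals recomputed from the coordinates match the request to well
    under 0.5 degrees.
    """
    residues = _normalize_sequence(sequence)
    n = len(residues)
    if len(geometry.phi) != n:
        raise InputError(
            f"geometry covers {len(geometry.phi)} residues, sequence has {n}"
        )
    # chain construction on N, CA, C; O and H hang off afterwards
    n_pos = np.empty((n, 3))
    ca_pos = np.empty((n, 3))
    c_pos = np.empty((n, 3))
    n_pos[0] = (0.0, 0.0, 0.0)
    ca_pos[0] = (BOND_N_CA, 0.0, 0.0)
    theta = np.radians(ANGLE_N_CA_C)
    c_pos[0] = ca_pos[0] + BOND_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for i in range(1, n):
        n_pos[i] = place_atom(
            n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
            BOND_C_N, ANGLE_CA_C_N, geometry.psi[i - 1],
        )
        ca_pos[i] = place_atom(
            ca_pos[i - 1], c_pos[i - 1], n_pos[i],
            BOND_N_CA, ANGLE_C_N_CA, OMEGA,
        )
        c_pos[i] = place_atom(
            c_pos[i - 1], n_pos[i], ca_pos[i],
            BOND_CA_C, ANGLE_N_CA_C, geometry.phi[i],
        )
    o_pos = np.empty((n, 3))
    for i in range(n):
        # carbonyl O trans to the next amide N across the peptide plane
        o_pos[i] = place_atom(
            n_pos[i], ca_pos[i], c_pos[i],
            BOND_C_O, ANGLE_CA_C_O, geometry.psi[i] + 180.0,
        )
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []

    def _add(name: str, element: str, res_i: int, pos: np.ndarray) -> None:
        atoms.append(
            AtomRecord(
                name=name,
                element=element,
                mass=mass_of_element(element, name),
                residue_index=res_i + residue_offset,
                residue_name=residues[res_i],
                chain_id=chain_id,
            )
        )
        coords.append(pos)

    for i in range(n):
        _add("N", "N", i, n_pos[i])
        if i > 0 and residues[i] != "PRO":
            h_dir = _unit(c_pos[i - 1] - o_pos[i - 1])
            _add("H", "H", i, n_pos[i] + BOND_N_H * h_dir)
        _add("CA", "C", i, ca_pos[i])
        _add("C", "C", i, c_pos[i])
        _add("O", "O", i, o_pos[i])
    return ConformationalEnsemble(Topology(atoms), np.array(coords)[np.newaxis])


# ---------------------------------------------------------------------------
# Interaction fixtures
# ---------------------------------------------------------------------------


def build_interaction_fixture(
    kind: str,
    separation: float,
    dha_angle: float = 170.0,
) -> ConformationalEnsemble:
    """Minimal two-residue system whose governing interaction distance
    equals ``separation`` (nm).

    ``kind``:

    * ``"salt_bridge"`` — arginine NH1 donor (with hydrogen HH11) and
      phosphoserine phosphate oxygen O1P acceptor, donor-acceptor distance
      ``separation`` with a donor-H-acceptor angle of ``dha_angle`` degrees.
    * ``"cation_pi"`` — arginine guanidinium (CZ cation centre, NE/NH1/NH2
      present) and tyrosine CG/CZ, both criterion distances equal to
      ``separation``.
    * ``"contact"`` — two single-heavy-atom residues at ``separation``.
    """
    if separation <= 0:
        raise InputError("separation must be positive")
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []

    def _add(name, element, res_i, res_name, pos, chain="A"):
        atoms.append(
            AtomRecord(
                name=name,
                element=element,
                mass=mass_of_element(element, name),
                residue_index=res_i,
                residue_name=res_name,
                chain_id=chain,
            )
        )
        coords.append(np.asarray(pos, dtype=float))

    far = 4.0  # nm; parks backbone dummies away from the interaction site
    if kind == "salt_bridge":
        donor = np.zeros(3)
        h = np.array([BOND_N_H, 0.0, 0.0])
        # acceptor in the xy-plane at the requested D-H-A angle
        alpha = np.radians(180.0 - dha_angle)
        u = np.array([np.cos(alpha), np.sin(alpha), 0.0])
        c = np.cos(alpha)
        t = -BOND_N_H * c + np.sqrt(
            BOND_N_H**2 * c**2 - BOND_N_H**2 + separation**2
        )
        acceptor = h + t * u
        for name, pos in [
            ("N", donor + (-far, 0.0, 0.0)),
            ("CA", donor + (-far + 0.15, 0.0, 0.0)),
            ("C", donor + (-far + 0.3, 0.0, 0.0)),
            ("O", donor + (-far + 0.3, 0.12, 0.0)),
            ("CZ", donor + (-0.133, 0.0, 0.0)),
            ("NH1", donor),
            ("HH11", h),
        ]:
            element = "O" if name == "O" else name[0]
            _add(name, element, 0, "ARG", pos)
        p = acceptor + _unit(acceptor - donor) * 0.16
        for name, pos in [
            ("N", acceptor + (far, 0.0, 0.0)),
            ("CA", acceptor + (far - 0.15, 0.0, 0.0)),
            ("C", acceptor + (far - 0.3, 0.0, 0.0)),
            ("O", acceptor + (far - 0.3, 0.12, 0.0)),
            ("OG", p + (0.0, 0.16, 0.0)),
            ("P", p),
            ("O1P", acceptor),
            ("O2P", p + (0.0, -0.10, 0.12)),
            ("O3P", p + (0.0, -0.10, -0.12)),
        ]:
            element = {"P": "P"}.get(name, "O" if name[0] == "O" else name[0])
            _add(name, element, 1, "SEP", pos)
    elif kind == "cation_pi":
        half_ring = 0.139  # half the tyrosine CG-CZ (para) distance
        if separation <= half_ring:
            raise InputError(
                f"cation_pi separation must exceed {half_ring} nm "
                "(half the CG-CZ ring diagonal)"
            )
        cation = np.zeros(3)
        x = np.sqrt(separation**2 - half_ring**2)
        cg = np.array([x, half_ring, 0.0])
        cz_tyr = np.array([x, -half_ring, 0.0])
        for name, pos in [
            ("N", cation + (-far, 0.0, 0.0)),
            ("CA", cation + (-far + 0.15, 0.0, 0.0)),
            ("C", cation + (-far + 0.3, 0.0, 0.0)),
            ("O", cation + (-far + 0.3, 0.12, 0.0)),
            ("NE", cation + (-0.133, 0.0, 0.0)),
            ("CZ", cation),
            ("NH1", cation + (0.066, 0.115, 0.0)),
            ("NH2", cation + (0.066, -0.115, 0.0)),
        ]:
            element = "O" if name == "O" else name[0]
            _add(name, element, 0, "ARG", pos)
        for name, pos in [
            ("N", cg + (far, 0.0, 0.0)),
            ("CA", cg + (far - 0.15, 0.0, 0.0)),
            ("C", cg + (far - 0.3, 0.0, 0.0)),
            ("O", cg + (far - 0.3, 0.12, 0.0)),
            ("CB", cg + (0.05, 0.145, 0.0)),
            ("CG", cg),
            ("CZ", cz_tyr),
        ]:
            element = "O" if name == "O" else name[0]
            _add(name, element, 1, "TYR", pos)
    elif kind == "contact":
        _add("CB", "C", 0, "ALA", (0.0, 0.0, 0.0))
        _add("CB", "C", 1, "ALA", (separation, 0.0, 0.0))
    else:
        raise InputError(f"unknown fixture kind {kind!r}")
    return ConformationalEnsemble(Topology(atoms), np.array(coords)[np.newaxis])


def build_two_strand_sheet(
    n_residues: int = 6,
    antiparallel: bool = True,
) -> ConformationalEnsemble:
    """Two extended strands packed as a (anti)parallel beta-sheet.

    The second strand is generated by a two-fold rotation (antiparallel) or
    a pure translation (parallel) of the first, and the inter-strand offset
    is chosen by a grid search maximising the number of backbone hydrogen
    bonds under the Kabsch-Sander energy criterion.  Strands are separate
    chains, so there is no covalent connection between them.
    """
    from .secondary import _frame_backbone_arrays, _hbond_energy_matrix

    strand_a = build_backbone(
        "A" * n_residues, BackboneGeometry.extended(n_residues), chain_id="A"
    )
    coords_a = strand_a.coordinates[0]
    names = strand_a.topology.atom_names
    ca = coords_a[names == "CA"]
    c = coords_a[names == "C"]
    o = coords_a[names == "O"]
    # strand frame: e1 along the chain, e2 along the in-plane C=O (hydrogen
    # bond) direction, e3 normal to the sheet plane
    e1 = _unit(ca[-1] - ca[0])
    co = _unit(o[0] - c[0])
    e2 = _unit(co - np.dot(co, e1) * e1)
    e3 = np.cross(e1, e2)
    center = ca.mean(axis=0)
    rel = coords_a - center
    if antiparallel:
        # 2-fold rotation about the sheet normal reverses the chain direction
        coords_flip = center + 2.0 * np.outer(rel @ e3, e3) - rel
    else:
        coords_flip = coords_a.copy()
    best = None
    for sign in (1.0, -1.0):
        for sep in np.arange(0.38, 0.60, 0.02):
            for shift in np.arange(-0.8, 0.81, 0.05):
                coords_b = coords_flip + sign * sep * e2 + shift * e1
                cand = _combine_strands(strand_a, coords_b, n_residues)
                arrays = _frame_backbone_arrays(
                    cand.topology, cand.coordinates[0]
                )
                energy = _hbond_energy_matrix(arrays)
                inter = int(np.sum(energy[:n_residues, n_residues:] < -0.5)) + int(
                    np.sum(energy[n_residues:, :n_residues] < -0.5)
                )
                if best is None or inter > best[0]:
                    best = (inter, cand)
    return best[1]


def _combine_strands(strand_a, coords_b, n_residues):
    from dataclasses import replace as _replace

    atoms_b = [
        _replace(a, chain_id="B", residue_index=a.residue_index + n_residues)
        for a in strand_a.topology.atoms
    ]
    topo = Topology(list(strand_a.topology.atoms) + atoms_b)
    coords = np.concatenate([strand_a.coordinates[0], coords_b], axis=0)
    return ConformationalEnsemble(topo, coords[np.newaxis])


# ---------------------------------------------------------------------------
# Multi-state ensembles
# ---------------------------------------------------------------------------


def generate_multistate_ensemble(
    conformers: Sequence[ConformationalEnsemble],
    weights: Sequence[float],
    noise_sd: float,
    n_frames: int,
    n_replicates: int = 1,
    seed: int = 0,
    rotate: bool = True,
    return_labels: bool = False,
) -> ConformationalEnsemble | tuple[ConformationalEnsemble, np.ndarray]:
    """Mixture ensemble: each frame is a randomly rotated copy of a
    conformer drawn with probability ``weights``, plus isotropic Gaussian
    coordinate noise of scale ``noise_sd`` (nm).

    Replicate labels are assigned evenly over frames in order.  With
    ``return_labels=True`` the ground-truth conformer index of every frame
    is returned alongside the ensemble.
    """
    if len(conformers) == 0:
        raise InputError("need at least one conformer")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(conformers),):
        raise InputError("one weight per conformer required")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-8:
        raise InputError("weights must be non-negative and sum to 1")
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    topo = conformers[0].topology
    base = []
    for k, conf in enumerate(conformers):
        if conf.topology != topo:
            raise StructuralError(f"conformer {k} topology differs from conformer 0")
        if conf.n_frames != 1:
            raise InputError("conformers must be single-frame ensembles")
        base.append(conf.coordinates[0])
    base = np.array(base)
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(conformers), size=n_frames, p=weights)
    coords = base[labels].copy()
    if rotate:
        centroids = coords.mean(axis=1, keepdims=True)
        rots = random_rotation_matrices(n_frames, rng)
        coords = np.einsum("fij,faj->fai", rots, coords - centroids) + centroids
    if noise_sd > 0:
        coords = coords + rng.normal(scale=noise_sd, size=coords.shape)
    replicate_id = (np.arange(n_frames, dtype=np.intp) * n_replicates) // n_frames
    ens = ConformationalEnsemble(topo, coords, replicate_id)
    if return_labels:
        return ens, labels
    return ens
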