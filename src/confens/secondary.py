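"""Secondary-structure assignment: DSSP hydrogen-bond patterns + PPII.

The assignment follows the classic Kabsch-Sander algorithm: a backbone
hydrogen bond between the carbonyl of residue i and the amide of residue j
is declared when the electrostatic interaction energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

(distances in Angstrom between the O/C of the acceptor and the N/H of the
donor) is below -0.5 kcal/mol.  Repeating n -> n+4 bonds define alpha-helix
(H), n -> n+3 the 3_10-helix (G), n -> n+5 the pi-helix (I); isolated and
laddered inter-strand bridges give B and E; hydrogen-bonded turns give T
and strong backbone curvature gives the bend S.

Classic DSSP leaves the polyproline-II helix — the dominant local structure
of many disordered peptides — in the irregular class, so the assignment is
extended afterwards: coil residues whose (phi, psi) fall in the PPII window
(default -75 +/- 29, +145 +/- 29 degrees) in runs of at least two
consecutive residues are relabelled P.

Amide hydrogens are used when present in the topology; otherwise they are
placed on the N-H vector antiparallel to the preceding carbonyl, the
standard DSSP construction.  Prolines and chain-initial residues are never
hydrogen-bond donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import InputError, SelectionError
from ._geometry import angle_deg, dihedral_deg
from .io import ConformationalEnsemble, Topology

__all__ = [
    "SecondaryStructureAssignment",
    "SSProfile",
    "PPIIWindow",
    "backbone_dihedrals",
    "dssp_assign",
    "ppii_extend",
    "assign_with_ppii",
    "ss_profile",
]

#: DSSP codes plus P (polyproline II) and C (coil/irregular).
SS_CODES = ("H", "G", "I", "E", "B", "T", "S", "P", "C")

#: Grouping used for propensity profiles (pi-helix counts as irregular).
SS_GROUPS = {
    "helix": ("H", "G"),
    "strand": ("E", "B"),
    "turn": ("T",),
    "bend": ("S",),
    "ppii": ("P",),
    "irregular": ("C", "I"),
}

_HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_HB_PREFACTOR = 0.084 * 332.0  # kcal/mol * Angstrom
_BEND_ANGLE = 70.0  # degrees
_NH_BOND = 0.1010  # nm, for placed amide hydrogens


@dataclass
class SecondaryStructureAssignment:
    """Per-frame, per-residue structure codes (frames x residues)."""

    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="U1")
        if self.codes.ndim != 2:
            raise InputError("codes must be a frames x residues matrix")
        bad = set(np.unique(self.codes)) - set(SS_CODES)
        if bad:
            raise InputError(f"unknown structure codes {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    @property
    def n_residues(self) -> int:
        return self.codes.shape[1]


@dataclass
class SSProfile:
    """Per-residue grouped-class fractions and peptide-level mean content."""

    per_residue: pd.DataFrame  # one row per residue, one column per group
    content: pd.Series  # mean over residues, per group


@dataclass(frozen=True)
class PPIIWindow:
    """Dihedral window and run-length rule of the PPII extension."""

    phi_center: float = -75.0
    psi_center: float = 145.0
    tolerance: float = 29.0
    min_run: int = 2

    def contains(self, phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
        ok = np.isfinite(phi) & np.isfinite(psi)
        return (
            ok
            & (np.abs(phi - self.phi_center) <= self.tolerance)
            & (np.abs(psi - self.psi_center) <= self.tolerance)
        )


# ---------------------------------------------------------------------------
# Backbone bookkeeping
# ---------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=16)
def _backbone_indices(topology: Topology) -> dict:
    """Per-residue indices of N, CA, C, O (+H if present), chain labels,
    proline mask and same-chain contiguity flags."""
    n_res = topology.n_residues
    idx = {name: np.full(n_res, -1, dtype=np.intp) for name in ("N", "CA", "C", "O", "H")}
    for name in ("N", "CA", "C", "O", "H"):
        for r in range(n_res):
            hits = topology.atom_indices(residue=r, name=name)
            if len(hits):
                idx[name][r] = hits[0]
    for name in ("N", "CA", "C", "O"):
        if np.any(idx[name] < 0):
            missing = np.flatnonzero(idx[name] < 0)
            raise SelectionError(
                f"residues {missing.tolist()} lack backbone atom {name!r}"
            )
    chain_of_res = np.empty(n_res, dtype=object)
    for r in range(n_res):
        chain_of_res[r] = topology.atoms[topology.atom_indices(residue=r)[0]].chain_id
    res_names = np.array(topology.residue_names)
    # residue i is peptide-bonded to i+1 iff they share a chain
    connected = np.array(
        [chain_of_res[i] == chain_of_res[i + 1] for i in range(n_res - 1)], dtype=bool
    )
    return {
        "idx": idx,
        "connected": connected,
        "proline": res_names == "PRO",
        "chain": chain_of_res,
    }


def _frame_backbone_arrays(topology: Topology, frame: np.ndarray) -> dict:
    """Coordinates of N, CA, C, O and (real or placed) H per residue for one
    frame; H is NaN where the residue cannot donate."""
    info = _backbone_indices(topology)
    idx = info["idx"]
    out = {name: frame[idx[name]] for name in ("N", "CA", "C", "O")}
    n_res = topology.n_residues
    h = np.full((n_res, 3), np.nan)
    for r in range(n_res):
        if info["proline"][r]:
            continue
        if idx["H"][r] >= 0:
            h[r] = frame[idx["H"][r]]
        elif r > 0 and info["connected"][r - 1]:
            co = out["C"][r - 1] - out["O"][r - 1]
            co /= np.linalg.norm(co)
            h[r] = out["N"][r] + _NH_BOND * co
    out["H"] = h
    out["connected"] = info["connected"]
    out["proline"] = info["proline"]
    return out


def _hbond_energy_matrix(arrays: dict) -> np.ndarray:
    """Kabsch-Sander energies E[i, j]: carbonyl of residue i accepting the
    amide hydrogen of residue j.  Invalid pairs get +inf."""
    c = arrays["C"] * 10.0  # nm -> Angstrom
    o = arrays["O"] * 10.0
    n = arrays["N"] * 10.0
    h = arrays["H"] * 10.0
    n_res = len(c)

    def _dist(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        energy = _HB_PREFACTOR * (
            1.0 / _dist(o, n) + 1.0 / _dist(c, h) - 1.0 / _dist(o, h) - 1.0 / _dist(c, n)
        )
    energy = np.where(np.isfinite(energy), energy, np.inf)
    # donors without an amide hydrogen cannot bond
    energy[:, np.any(np.isnan(arrays["H"]), axis=1)] = np.inf
    ii = np.arange(n_res)
    energy[ii, ii] = np.inf
    # the amide directly following the carbonyl shares its peptide bond
    conn = arrays["connected"]
    for i in range(n_res - 1):
        if conn[i]:
            energy[i, i + 1] = np.inf
    return energy


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------


def backbone_dihedrals(
    ensemble: ConformationalEnsemble,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame, per-residue (phi, psi) in degrees; NaN where undefined.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    The first residue of a chain has no phi, the last no psi.
    """
    info = _backbone_indices(ensemble.topology)
    idx = info["idx"]
    conn = info["connected"]
    n_res = ensemble.n_residues
    coords = ensemble.coordinates
    phi = np.full((ensemble.n_frames, n_res), np.nan)
    psi = np.full((ensemble.n_frames, n_res), np.nan)
    for r in range(n_res):
        if r > 0 and conn[r - 1]:
            phi[:, r] = dihedral_deg(
                coords[:, idx["C"][r - 1]],
                coords[:, idx["N"][r]],
                coords[:, idx["CA"][r]],
                coords[:, idx["C"][r]],
            )
        if r < n_res - 1 and conn[r]:
            psi[:, r] = dihedral_deg(
                coords[:, idx["N"][r]],
                coords[:, idx["CA"][r]],
                coords[:, idx["C"][r]],
                coords[:, idx["N"][r + 1]],
            )
    return phi, psi


# ---------------------------------------------------------------------------
# DSSP assignment
# ---------------------------------------------------------------------------


def _assign_frame(topology: Topology, frame: np.ndarray) -> np.ndarray:
    arrays = _frame_backbone_arrays(topology, frame)
    n_res = len(arrays["CA"])
    conn = arrays["connected"]
    hb = _hbond_energy_matrix(arrays) < _HB_ENERGY_CUTOFF

    def _contiguous(i: int, j: int) -> bool:
        lo, hi = min(i, j), max(i, j)
        return bool(np.all(conn[lo:hi]))

    # n-turns: CO(i) ... HN(i+n) within one chain
    turns = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if hb[i, i + n] and _contiguous(i, i + n):
                turns[n][i] = True

    helix = {code: np.zeros(n_res, dtype=bool) for code in "GHI"}
    for n, code, length in ((4, "H", 4), (3, "G", 3), (5, "I", 5)):
        for i in range(1, n_res - n):
            if turns[n][i - 1] and turns[n][i]:
                helix[code][i : i + length] = True

    # beta bridges: parallel / antiparallel Kabsch-Sander patterns
    def _hb(a: int, b: int) -> bool:
        return 0 <= a < n_res and 0 <= b < n_res and hb[a, b]

    bridges: list[tuple[int, int, str]] = []
    for i in range(n_res):
        for j in range(i + 3, n_res):
            para = (_hb(i - 1, j) and _hb(j, i + 1)) or (
                _hb(j - 1, i) and _hb(i, j + 1)
            )
            anti = (_hb(i, j) and _hb(j, i)) or (
                _hb(i - 1, j + 1) and _hb(j - 1, i + 1)
            )
            if para:
                bridges.append((i, j, "P"))
            if anti:
                bridges.append((i, j, "A"))
    bridge_set = set(bridges)
    strand = np.zeros(n_res, dtype=bool)
    lone_bridge = np.zeros(n_res, dtype=bool)
    for i, j, kind in bridges:
        if kind == "P":
            laddered = (
                (i + 1, j + 1, "P") in bridge_set
                or (i - 1, j - 1, "P") in bridge_set
            )
        else:
            laddered = (
                (i + 1, j - 1, "A") in bridge_set
                or (i - 1, j + 1, "A") in bridge_set
            )
        if laddered:
            strand[i] = strand[j] = True
        else:
            lone_bridge[i] = lone_bridge[j] = True

    turn_t = np.zeros(n_res, dtype=bool)
    for n in (3, 4, 5):
        for i in np.flatnonzero(turns[n]):
            turn_t[i + 1 : i + n] = True

    bend = np.zeros(n_res, dtype=bool)
    ca = arrays["CA"]
    for i in range(2, n_res - 2):
        if _contiguous(i - 2, i + 2):
            # curvature: angle between chain directions before and after i
            u = ca[i] - ca[i - 2]
            v = ca[i + 2] - ca[i]
            kink = angle_deg(ca[i] + u, ca[i], ca[i] + v)
            if kink > _BEND_ANGLE:
                bend[i] = True

    codes = np.full(n_res, "C", dtype="U1")
    # priority: H > E > B > G > I > T > S
    for mask, code in (
        (bend, "S"),
        (turn_t, "T"),
        (helix["I"], "I"),
        (helix["G"], "G"),
        (lone_bridge, "B"),
        (strand, "E"),
        (helix["H"], "H"),
    ):
        codes[mask] = code
    return codes


def dssp_assign(ensemble: ConformationalEnsemble) -> SecondaryStructureAssignment:
    """Kabsch-Sander DSSP codes for every frame and residue.

    Chains shorter than 3 residues come out all-coil (no hydrogen-bond
    pattern can form).  Side chains are ignored, so phosphoserine and
    phosphothreonine are treated exactly like their parent residues.
    """
    codes = np.stack(
        [
            _assign_frame(ensemble.topology, ensemble.coordinates[f])
            for f in range(ensemble.n_frames)
        ]
    )
    return SecondaryStructureAssignment(codes)


def ppii_extend(
    assignment: SecondaryStructureAssignment,
    dihedrals: tuple[np.ndarray, np.ndarray],
    window: PPIIWindow = PPIIWindow(),
) -> SecondaryStructureAssignment:
    """Relabel coil residues in the PPII dihedral window as P.

    Only residues currently assigned C are eligible, so P never overwrites
    a hydrogen-bond-derived DSSP class, and only runs of at least
    ``window.min_run`` consecutive eligible residues are relabelled.
    """
    phi, psi = dihedrals
    codes = assignment.codes.copy()
    if phi.shape != codes.shape or psi.shape != codes.shape:
        raise InputError("dihedral arrays must match the assignment shape")
    eligible = (codes == "C") & window.contains(phi, psi)
    n_frames, n_res = codes.shape
    for f in range(n_frames):
        run_start = None
        row = eligible[f]
        for r in range(n_res + 1):
            if r < n_res and row[r]:
                if run_start is None:
                    run_start = r
            else:
                if run_start is not None and r - run_start >= window.min_run:
                    codes[f, run_start:r] = "P"
                run_start = None
    return SecondaryStructureAssignment(codes)


def assign_with_ppii(
    ensemble: ConformationalEnsemble, window: PPIIWindow = PPIIWindow()
) -> SecondaryStructureAssignment:
    """DSSP assignment followed by the PPII extension."""
    assignment = dssp_assign(ensemble)
    return ppii_extend(assignment, backbone_dihedrals(ensemble), window)


def ss_profile(assignment: SecondaryStructureAssignment) -> SSProfile:
    """Per-residue fractions of the grouped classes and mean content.

    Groups: helix = H+G, strand = E+B, turn = T, bend = S, PPII = P,
    irregular = C+I.  The grouped fractions at every residue sum to 1.
    """
    if assignment.n_frames < 1:
        raise InputError("assignment has no frames")
    data = {}
    for group, members in SS_GROUPS.items():
        mask = np.isin(assignment.codes, members)
        data[group] = mask.mean(axis=0)
    per_residue = pd.DataFrame(data)
    per_residue.index.name = "residue"
    return SSProfile(per_residue=per_residue, content=per_residue.mean(axis=0))
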