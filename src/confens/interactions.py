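"""Residue-residue interactions: contacts, salt bridges, cation-pi.

Three geometric criteria, each reported as a probability over frames with
an across-replicate error bar:

* **contact** — two residues are in contact in a frame when any pair of
  their (by default heavy) atoms is closer than 0.4 nm;
* **salt bridge** — a basic donor group (arginine NE/NH1/NH2, lysine NZ, or
  the N-terminal amine) is hydrogen-bonded to a phosphate oxygen, using the
  angle-dependent Wernet-Nilsson distance criterion
  r_DA < 0.33 nm - 0.00044 nm/deg^2 * theta^2, with theta the H-donor-
  acceptor angle;
* **cation-pi** — the arginine guanidinium carbon CZ (configurable) is
  within 0.6 nm (inclusive) of *both* the CG and CZ atoms of a tyrosine
  ring.

The tables mirror how interaction statistics are reported for
phosphorylated peptides: one row per residue pair, probability in %, error
as the standard error of per-replicate probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import CriterionError, InputError, SelectionError
from ._geometry import angle_deg
from .io import ConformationalEnsemble

__all__ = [
    "ContactMap",
    "InteractionTable",
    "contact_map",
    "contact_delta",
    "hydrogen_bonds",
    "salt_bridge_table",
    "cation_pi_table",
]

DEFAULT_CONTACT_CUTOFF = 0.4  # nm
CATION_PI_CUTOFF = 0.6  # nm, inclusive on both distances
HB_R0 = 0.33  # nm, zero-angle donor-acceptor bound
HB_K = 0.00044  # nm / deg^2

#: Basic donor side-chain atoms per residue type.
BASIC_DONOR_ATOMS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}

#: Phosphate oxygens plus the phospho-ester oxygen, per phospho residue type.
PHOSPHO_ACCEPTOR_ATOMS = {
    "SEP": ("O1P", "O2P", "O3P", "OG"),
    "TPO": ("O1P", "O2P", "O3P", "OG1"),
    "PTR": ("O1P", "O2P", "O3P", "OH"),
}

CARBOXYLATE_ACCEPTOR_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass
class ContactMap:
    """Symmetric residue-residue contact probability matrix in [0, 1]."""

    probability: np.ndarray
    cutoff: float
    atom_scope: str = "heavy"

    def __post_init__(self) -> None:
        p = np.asarray(self.probability, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise InputError("contact probability must be a square matrix")
        if not np.allclose(p, p.T):
            raise InputError("contact probability must be symmetric")
        if p.min() < 0 or p.max() > 1:
            raise InputError("contact probabilities must lie in [0, 1]")
        self.probability = p

    @property
    def n_residues(self) -> int:
        return self.probability.shape[0]


@dataclass
class InteractionTable:
    """Tidy per-pair probability table (one row per residue pair).

    Columns: donor, acceptor, donor_residue, acceptor_residue,
    probability_pct, error_pct.  ``error_pct`` is the standard error of the
    per-replicate probabilities (NaN with a single replicate).
    """

    table: pd.DataFrame
    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.table):
            p = self.table["probability_pct"].to_numpy()
            if p.min() < 0 or p.max() > 100:
                raise InputError("probabilities must lie in [0, 100]")


def _residue_label(ensemble: ConformationalEnsemble, residue: int) -> str:
    return f"{ensemble.topology.residue_name(residue)}{residue + 1}"


def _replicate_stats(
    bonded: np.ndarray, replicate_id: np.ndarray
) -> tuple[float, float]:
    """Overall probability (%) and across-replicate standard error (%)."""
    prob = 100.0 * float(bonded.mean())
    reps = np.unique(replicate_id)
    if len(reps) < 2:
        return prob, float("nan")
    per_rep = np.array([bonded[replicate_id == r].mean() for r in reps])
    err = 100.0 * float(np.std(per_rep, ddof=1) / np.sqrt(len(reps)))
    return prob, err


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------


def contact_map(
    ensemble: ConformationalEnsemble,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    heavy_only: bool = True,
) -> ContactMap:
    """P(i, j) = fraction of frames with any atom of residue i closer than
    ``cutoff`` to any atom of residue j.  Diagonal is 1 by convention.

    Hydrogens are excluded by default so the map does not depend on whether
    the trajectory stored them.  Sequence-adjacent pairs are included
    (bonded neighbours are trivially in contact at 0.4 nm).
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    topo = ensemble.topology
    scope = topo.heavy_mask() if heavy_only else np.ones(topo.n_atoms, dtype=bool)
    atom_idx = np.flatnonzero(scope)
    res_of = topo.residue_index[atom_idx]
    order = np.argsort(res_of, kind="stable")
    atom_idx = atom_idx[order]
    res_of = res_of[order]
    present = np.unique(res_of)
    starts = np.searchsorted(res_of, present)
    n_res = topo.n_residues
    counts = np.zeros((n_res, n_res), dtype=np.int64)
    coords = ensemble.coordinates[:, atom_idx]
    for f in range(ensemble.n_frames):
        x = coords[f]
        d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
        # residue-block minimum in both directions
        d = np.minimum.reduceat(d, starts, axis=0)
        d = np.minimum.reduceat(d, starts, axis=1)
        hit = d < cutoff
        counts[np.ix_(present, present)] += hit
    prob = counts / ensemble.n_frames
    np.fill_diagonal(prob, 1.0)
    prob = np.maximum(prob, prob.T)  # guard symmetry against fp noise
    return ContactMap(prob, cutoff, "heavy" if heavy_only else "all")


def contact_delta(map_a: ContactMap, map_b: ContactMap) -> np.ndarray:
    """Signed change in contact probability, ``map_a - map_b`` element-wise
    (conventionally phosphorylated minus non-phosphorylated)."""
    if map_a.n_residues != map_b.n_residues:
        raise InputError("contact maps have different residue counts")
    if not np.isclose(map_a.cutoff, map_b.cutoff):
        raise InputError("contact maps were computed with different cutoffs")
    return map_a.probability - map_b.probability


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


def attached_hydrogens(
    ensemble: ConformationalEnsemble, donor_atom: int, max_bond: float = 0.125
) -> list[int]:
    """Hydrogen atoms covalently attached to ``donor_atom`` (same residue,
    within ``max_bond`` nm in the first frame)."""
    topo = ensemble.topology
    res = topo.residue_index[donor_atom]
    frame0 = ensemble.coordinates[0]
    out = []
    for a in topo.atom_indices(residue=int(res)):
        if topo.elements[a].upper() in ("H", "D") and a != donor_atom:
            if np.linalg.norm(frame0[a] - frame0[donor_atom]) <= max_bond:
                out.append(int(a))
    return out


def hydrogen_bonds(
    ensemble: ConformationalEnsemble,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    r0: float = HB_R0,
    k: float = HB_K,
) -> np.ndarray:
    """Evaluate the angle-dependent hydrogen-bond criterion.

    ``donors`` are (donor_heavy_atom, hydrogen_atom) index pairs,
    ``acceptors`` acceptor heavy-atom indices.  A triple is bonded in a
    frame when r_DA < r0 - k * theta^2 with theta the H-donor-acceptor
    angle in degrees.  Returns a boolean array of shape
    (n_frames, n_donors, n_acceptors).
    """
    if not donors:
        raise CriterionError(
            "no donor hydrogens available; supply or place hydrogens before "
            "evaluating the hydrogen-bond criterion"
        )
    coords = ensemble.coordinates
    out = np.zeros((ensemble.n_frames, len(donors), len(acceptors)), dtype=bool)
    for di, (d, h) in enumerate(donors):
        for ai, a in enumerate(acceptors):
            r_da = np.linalg.norm(coords[:, a] - coords[:, d], axis=1)
            theta = angle_deg(coords[:, h], coords[:, d], coords[:, a])
            out[:, di, ai] = r_da < (r0 - k * theta**2)
    return out


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------


def _donor_groups(
    ensemble: ConformationalEnsemble,
) -> list[tuple[str, int | None, list[tuple[int, int]]]]:
    """(label, residue_index_or_None_for_NT, [(donor, hydrogen), ...])."""
    topo = ensemble.topology
    groups: list[tuple[str, int | None, list[tuple[int, int]]]] = []
    # N-terminal amine of each chain, reported as its own "NT" row
    seen_chains: set[str] = set()
    for r in range(topo.n_residues):
        chain = topo.atoms[topo.atom_indices(residue=r)[0]].chain_id
        if chain in seen_chains:
            continue
        seen_chains.add(chain)
        n_idx = topo.atom_indices(residue=r, name="N")
        if len(n_idx):
            pairs = [
                (int(n_idx[0]), h) for h in attached_hydrogens(ensemble, int(n_idx[0]))
            ]
            if pairs:
                label = "NT" if len(seen_chains) == 1 else f"NT({chain})"
                groups.append((label, None, pairs))
    for r in range(topo.n_residues):
        res_name = topo.residue_name(r).upper()
        donor_names = BASIC_DONOR_ATOMS.get(res_name)
        if not donor_names:
            continue
        pairs = []
        for name in donor_names:
            for d in topo.atom_indices(residue=r, name=name):
                pairs.extend(
                    (int(d), h) for h in attached_hydrogens(ensemble, int(d))
                )
        if pairs:
            groups.append((_residue_label(ensemble, r), r, pairs))
    return groups


def salt_bridge_table(
    ensemble: ConformationalEnsemble,
    include_carboxylates: bool = False,
    r0: float = HB_R0,
    k: float = HB_K,
) -> InteractionTable:
    """Salt-bridge probabilities between basic donors and phosphate (and
    optionally carboxylate) acceptors.

    A pair counts as bridged in a frame when at least one hydrogen bond
    (angle-dependent criterion) connects any donor N-H of the basic group
    to any acceptor oxygen.  Donors lacking explicit hydrogens are skipped.
    """
    import warnings

    topo = ensemble.topology
    acceptor_groups: list[tuple[str, list[int]]] = []
    for r in sorted(topo.phospho_residues):
        names = PHOSPHO_ACCEPTOR_ATOMS.get(topo.residue_name(r).upper(), ())
        idx = [int(i) for name in names for i in topo.atom_indices(residue=r, name=name)]
        if idx:
            acceptor_groups.append((_residue_label(ensemble, r), idx))
    if include_carboxylates:
        for r in range(topo.n_residues):
            names = CARBOXYLATE_ACCEPTOR_ATOMS.get(topo.residue_name(r).upper(), ())
            idx = [
                int(i) for name in names for i in topo.atom_indices(residue=r, name=name)
            ]
            if idx:
                acceptor_groups.append((_residue_label(ensemble, r), idx))
    params = {"criterion": "r_DA < r0 - k*theta^2", "r0_nm": r0, "k_nm_per_deg2": k}
    if not acceptor_groups:
        if topo.phospho_residues:
            warnings.warn(
                "phosphorylated residues carry no phosphate oxygen atoms: "
                "salt-bridge table is empty"
            )
        else:
            warnings.warn("no phosphorylated residues: salt-bridge table is empty")
        return InteractionTable(_empty_table(), "salt_bridge", params)
    donor_groups = _donor_groups(ensemble)
    rows = []
    for donor_label, _, donor_pairs in donor_groups:
        for acceptor_label, acceptor_idx in acceptor_groups:
            bonded = hydrogen_bonds(ensemble, donor_pairs, acceptor_idx, r0=r0, k=k)
            any_bond = bonded.any(axis=(1, 2))
            prob, err = _replicate_stats(any_bond, ensemble.replicate_id)
            rows.append(
                {
                    "donor": donor_label,
                    "acceptor": acceptor_label,
                    "probability_pct": prob,
                    "error_pct": err,
                }
            )
    return InteractionTable(pd.DataFrame(rows), "salt_bridge", params)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["donor", "acceptor", "probability_pct", "error_pct"]
    )


# ---------------------------------------------------------------------------
# Cation-pi
# ---------------------------------------------------------------------------


def cation_pi_table(
    ensemble: ConformationalEnsemble,
    cation_atom: str = "CZ",
    cutoff: float = CATION_PI_CUTOFF,
) -> InteractionTable:
    """Arginine-tyrosine cation-pi probabilities.

    Interaction in a frame requires BOTH distances from the arginine cation
    reference atom (guanidinium CZ by default, NE/NH1/NH2 selectable) to
    tyrosine CG and to tyrosine CZ to be <= ``cutoff`` (inclusive).
    """
    topo = ensemble.topology
    res_names = [topo.residue_name(r).upper() for r in range(topo.n_residues)]
    arg_residues = [r for r, n in enumerate(res_names) if n == "ARG"]
    tyr_residues = [r for r, n in enumerate(res_names) if n in ("TYR", "PTR")]
    params = {"cation_atom": cation_atom, "cutoff_nm": cutoff}
    if not arg_residues or not tyr_residues:
        return InteractionTable(_empty_table(), "cation_pi", params)
    rows = []
    for ra in arg_residues:
        cation_idx = topo.atom_indices(residue=ra, name=cation_atom)
        if len(cation_idx) == 0:
            raise SelectionError(
                f"arginine {ra} lacks cation reference atom {cation_atom!r}"
            )
        for rt in tyr_residues:
            ring = {}
            for name in ("CG", "CZ"):
                idx = topo.atom_indices(residue=rt, name=name)
                if len(idx) == 0:
                    raise SelectionError(f"tyrosine {rt} lacks ring atom {name!r}")
                ring[name] = int(idx[0])
            c = ensemble.coordinates[:, int(cation_idx[0])]
            d_cg = np.linalg.norm(ensemble.coordinates[:, ring["CG"]] - c, axis=1)
            d_cz = np.linalg.norm(ensemble.coordinates[:, ring["CZ"]] - c, axis=1)
            interacting = (d_cg <= cutoff) & (d_cz <= cutoff)
            prob, err = _replicate_stats(interacting, ensemble.replicate_id)
            rows.append(
                {
                    "donor": _residue_label(ensemble, ra),
                    "acceptor": _residue_label(ensemble, rt),
                    "probability_pct": prob,
                    "error_pct": err,
                }
            )
    return InteractionTable(pd.DataFrame(rows), "cation_pi", params)
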