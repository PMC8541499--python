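"""Ensemble container and I/O.

The universal input of every analysis in this package is a
:class:`ConformationalEnsemble`: an (n_frames, n_atoms, 3) coordinate array
in nanometres plus a :class:`Topology` describing atom names, elements,
masses, residues and chains.  Multi-model PDB (one ``MODEL`` per frame) is
the primary interchange format; a plain-text frames format with a key-value
topology sidecar is provided for synthetic data.

Phosphorylated residues are recognised by their PDB chemical-component
codes (SEP = phosphoserine, TPO = phosphothreonine, PTR = phosphotyrosine)
plus any user-supplied aliases, and their indices are carried on the
topology so interaction analyses can find them without re-deriving naming
conventions.

All coordinates are stored in nm internally; PDB I/O converts from/to
Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from ._errors import InputError, ParseError, SelectionError, StructuralError

__all__ = [
    "AtomRecord",
    "Topology",
    "ConformationalEnsemble",
    "PHOSPHO_RESIDUE_CODES",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_frames_text",
    "write_frames_text",
    "select_atoms",
    "backbone_selector",
    "concatenate_replicates",
    "subsample_frames",
    "to_mdtraj",
]

#: PDB chemical-component codes recognised as phosphorylated residues.
PHOSPHO_RESIDUE_CODES = frozenset({"SEP", "TPO", "PTR"})

#: Backbone atom names used by the convenience backbone selector.
BACKBONE_ATOM_NAMES = ("N", "CA", "C", "O")

# Standard atomic masses (u), keyed on element symbol.
_ELEMENT_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "FE": 55.845,
    "ZN": 65.38,
}


def mass_of_element(element: str, atom_name: str = "") -> float:
    """Standard atomic mass for ``element``, falling back to the first
    character of ``atom_name`` when the element symbol is empty/unknown."""
    key = element.strip().upper()
    if key in _ELEMENT_MASSES:
        return _ELEMENT_MASSES[key]
    if atom_name:
        first = atom_name.strip()[:1].upper()
        if first in _ELEMENT_MASSES:
            return _ELEMENT_MASSES[first]
    raise InputError(
        f"cannot assign a mass to atom {atom_name!r} with element {element!r}"
    )


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    ``residue_index`` is the 0-based residue ordinal within the whole
    topology (not the PDB residue number, which is written 1-based).
    """

    name: str
    element: str
    mass: float
    residue_index: int
    residue_name: str
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not self.name:
            raise InputError("atom name must be non-empty")
        if self.mass <= 0:
            raise InputError(f"atom {self.name!r}: mass must be positive")
        if self.residue_index < 0:
            raise InputError(f"atom {self.name!r}: residue_index must be >= 0")


class Topology:
    """Ordered atom list plus the set of phosphorylated residue indices.

    Exposes column-wise numpy views (``atom_names``, ``masses``, ...) used by
    the vectorised analyses.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        phospho_aliases: Iterable[str] = (),
    ) -> None:
        if len(atoms) == 0:
            raise InputError("topology must contain at least one atom")
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self.atom_names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.residue_index = np.array(
            [a.residue_index for a in self.atoms], dtype=np.intp
        )
        self.residue_names_per_atom = np.array([a.residue_name for a in self.atoms])
        self.chain_ids = np.array([a.chain_id for a in self.atoms])
        # residue ordinals must not decrease within a chain
        for cid in np.unique(self.chain_ids):
            idx = self.residue_index[self.chain_ids == cid]
            if np.any(np.diff(idx) < 0):
                raise StructuralError(
                    f"residue indices decrease within chain {cid!r}"
                )
        self._residue_ids = np.unique(self.residue_index)
        if not np.array_equal(self._residue_ids, np.arange(len(self._residue_ids))):
            raise StructuralError("residue indices must be contiguous from 0")
        codes = PHOSPHO_RESIDUE_CODES | {a.upper() for a in phospho_aliases}
        self.phospho_residues: frozenset[int] = frozenset(
            int(i)
            for i in self._residue_ids
            if self.residue_name(int(i)).upper() in codes
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self._residue_ids)

    def residue_name(self, residue: int) -> str:
        mask = self.residue_index == residue
        if not mask.any():
            raise SelectionError(f"no residue with index {residue}")
        return str(self.residue_names_per_atom[mask][0])

    @property
    def residue_names(self) -> list[str]:
        return [self.residue_name(i) for i in range(self.n_residues)]

    def atom_indices(
        self, residue: int | None = None, name: str | None = None
    ) -> np.ndarray:
        """Indices of atoms matching residue and/or atom name."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue is not None:
            mask &= self.residue_index == residue
        if name is not None:
            mask &= self.atom_names == name
        return np.flatnonzero(mask)

    def heavy_mask(self) -> np.ndarray:
        """Boolean mask of non-hydrogen atoms."""
        return ~np.isin(self.elements, ("H", "D"))

    def __len__(self) -> int:
        return self.n_atoms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self.atoms == other.atoms

    def __hash__(self) -> int:
        return hash(self.atoms)


@dataclass
class ConformationalEnsemble:
    """Frames x atoms x 3 coordinates (nm) with topology and replicate labels.

    ``replicate_id`` labels the independent trajectory each frame came from
    (contiguous integers from 0); across-replicate dispersion is the basis of
    every error bar in the interaction tables.  ``frame_stride`` optionally
    records the time between saved frames in ps.
    """

    topology: Topology
    coordinates: np.ndarray
    replicate_id: np.ndarray | None = None
    frame_stride: float | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim == 2:
            self.coordinates = self.coordinates[np.newaxis]
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise StructuralError(
                f"coordinates must have shape (frames, atoms, 3); "
                f"got {self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise StructuralError(
                f"coordinate atom count {self.coordinates.shape[1]} does not "
                f"match topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise StructuralError("coordinates contain non-finite values")
        if self.replicate_id is None:
            self.replicate_id = np.zeros(self.n_frames, dtype=np.intp)
        else:
            self.replicate_id = np.asarray(self.replicate_id, dtype=np.intp)
            if self.replicate_id.shape != (self.n_frames,):
                raise StructuralError("replicate_id must have one label per frame")
            uniq = np.unique(self.replicate_id)
            if not np.array_equal(uniq, np.arange(len(uniq))):
                raise StructuralError("replicate_id values must be contiguous from 0")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_residues(self) -> int:
        return self.topology.n_residues

    @property
    def n_replicates(self) -> int:
        return int(self.replicate_id.max()) + 1

    def with_coordinates(self, coords: np.ndarray) -> "ConformationalEnsemble":
        return ConformationalEnsemble(
            self.topology, coords, self.replicate_id.copy(), self.frame_stride
        )

    def frames(self, indices: np.ndarray | Sequence[int]) -> "ConformationalEnsemble":
        """Sub-ensemble of the given frame indices (replicate labels re-packed)."""
        indices = np.asarray(indices, dtype=np.intp)
        rep = self.replicate_id[indices]
        # re-pack to contiguous labels while preserving ordering of originals
        uniq = np.unique(rep)
        remap = {int(u): k for k, u in enumerate(uniq)}
        rep = np.array([remap[int(r)] for r in rep], dtype=np.intp)
        return ConformationalEnsemble(
            self.topology, self.coordinates[indices], rep, self.frame_stride
        )

    def replicate(self, label: int) -> "ConformationalEnsemble":
        return self.frames(np.flatnonzero(self.replicate_id == label))


def backbone_selector(atom: AtomRecord) -> bool:
    """Predicate selecting the protein backbone atoms N, CA, C, O."""
    return atom.name in BACKBONE_ATOM_NAMES


def select_atoms(
    ensemble: ConformationalEnsemble,
    selector: Callable[[AtomRecord], bool],
) -> ConformationalEnsemble:
    """Sub-ensemble of the atoms for which ``selector(atom)`` is true.

    Frame count and order are preserved.  Residue indices are renumbered to
    stay contiguous; the phospho-residue set is remapped accordingly.
    """
    keep = np.array([bool(selector(a)) for a in ensemble.topology.atoms])
    if not keep.any():
        raise SelectionError("selector matched no atoms")
    old_atoms = [a for a, k in zip(ensemble.topology.atoms, keep) if k]
    old_res = sorted({a.residue_index for a in old_atoms})
    res_remap = {r: k for k, r in enumerate(old_res)}
    new_atoms = [replace(a, residue_index=res_remap[a.residue_index]) for a in old_atoms]
    topo = Topology(new_atoms)
    return ConformationalEnsemble(
        topo,
        ensemble.coordinates[:, keep],
        ensemble.replicate_id.copy(),
        ensemble.frame_stride,
    )


def concatenate_replicates(
    ensembles: Sequence[ConformationalEnsemble],
) -> ConformationalEnsemble:
    """Concatenate ensembles frame-wise; replicate_id is set to list position.

    All inputs must share an identical topology.
    """
    if len(ensembles) == 0:
        raise InputError("need at least one ensemble")
    topo = ensembles[0].topology
    for k, ens in enumerate(ensembles[1:], start=1):
        if ens.topology != topo:
            raise StructuralError(f"topology of ensemble {k} differs from ensemble 0")
    coords = np.concatenate([e.coordinates for e in ensembles], axis=0)
    rep = np.concatenate(
        [np.full(e.n_frames, k, dtype=np.intp) for k, e in enumerate(ensembles)]
    )
    stride = ensembles[0].frame_stride
    return ConformationalEnsemble(topo, coords, rep, stride)


def subsample_frames(
    ensemble: ConformationalEnsemble, n_frames: int
) -> ConformationalEnsemble:
    """Equally spaced subsample of ``n_frames`` frames, first frame retained.

    With total T and target n, the stride is floor(T / n) and frames
    0, s, 2s, ... are kept.  Used to mimic taking a fixed number of equally
    spaced frames from a combined trajectory.
    """
    total = ensemble.n_frames
    if n_frames < 1:
        raise InputError("n_frames must be >= 1")
    if n_frames >= total:
        return ensemble.frames(np.arange(total))
    stride = total // n_frames
    indices = np.arange(n_frames, dtype=np.intp) * stride
    return ensemble.frames(indices)


# ---------------------------------------------------------------------------
# Multi-model PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _stack_to_ensemble(
    stack, phospho_aliases: Iterable[str]
) -> ConformationalEnsemble:
    import biotite.structure as bst

    if isinstance(stack, bst.AtomArray):
        stack = bst.stack([stack])
    n_atoms = stack.array_length()
    # contiguous 0-based residue ordinals in order of appearance
    res_key = list(zip(stack.chain_id, stack.res_id, stack.ins_code))
    seen: dict[tuple, int] = {}
    res_ordinal = np.empty(n_atoms, dtype=np.intp)
    for i, key in enumerate(res_key):
        if key not in seen:
            seen[key] = len(seen)
        res_ordinal[i] = seen[key]
    atoms = []
    for i in range(n_atoms):
        element = str(stack.element[i]).strip()
        name = str(stack.atom_name[i]).strip()
        atoms.append(
            AtomRecord(
                name=name,
                element=element or name[:1],
                mass=mass_of_element(element, name),
                residue_index=int(res_ordinal[i]),
                residue_name=str(stack.res_name[i]).strip(),
                chain_id=str(stack.chain_id[i]).strip() or "A",
            )
        )
    topo = Topology(atoms, phospho_aliases=phospho_aliases)
    coords_nm = np.asarray(stack.coord, dtype=float) / 10.0
    return ConformationalEnsemble(topo, coords_nm)


def read_multimodel_pdb(
    path: str | Path, phospho_aliases: Iterable[str] = ()
) -> ConformationalEnsemble:
    """Read a (multi-)model PDB file into an ensemble, one frame per MODEL.

    Coordinates are converted Angstrom -> nm.  Residues named SEP/TPO/PTR
    (or any of ``phospho_aliases``) are registered in
    ``topology.phospho_residues``.  All frames start in replicate 0.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        pdb_file = PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises plain ValueError/InvalidFileError
        msg = str(exc)
        if "number of atoms" in msg.lower() or "models" in msg.lower():
            raise StructuralError(f"{path}: inconsistent models ({msg})") from exc
        raise ParseError(f"{path}: {msg}") from exc
    if stack.array_length() == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return _stack_to_ensemble(stack, phospho_aliases)


def write_multimodel_pdb(
    ensemble: ConformationalEnsemble, path: str | Path
) -> None:
    """Write the ensemble as a multi-model PDB (one MODEL/ENDMDL per frame)."""
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    topo = ensemble.topology
    n_atoms = topo.n_atoms
    arrays = []
    # PDB residue numbers are written 1-based per chain
    res_id = topo.residue_index + 1
    for f in range(ensemble.n_frames):
        arr = bst.AtomArray(n_atoms)
        arr.coord = ensemble.coordinates[f] * 10.0  # nm -> Angstrom
        arr.chain_id = topo.chain_ids
        arr.res_id = res_id
        arr.res_name = topo.residue_names_per_atom
        arr.atom_name = topo.atom_names
        arr.element = topo.elements
        arr.hetero = np.isin(
            topo.residue_names_per_atom, sorted(PHOSPHO_RESIDUE_CODES)
        )
        arrays.append(arr)
    stack = bst.stack(arrays)
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    # a 1-frame stack is serialised without MODEL records; add them so the
    # output is always a well-formed multi-model file
    if not any(line.startswith("MODEL") for line in pdb_file.lines):
        body = [ln for ln in pdb_file.lines if ln.strip()]
        pdb_file.lines = ["MODEL        1", *body, "ENDMDL"]
    try:
        pdb_file.write(str(path))
    except OSError as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Auxiliary plain-text frames format
# ---------------------------------------------------------------------------


def write_frames_text(
    ensemble: ConformationalEnsemble, frames_path: str | Path, topology_path: str | Path
) -> None:
    """Write the auxiliary plain-text representation.

    ``frames_path``: one row per atom per frame: ``frame x y z`` (nm).
    ``topology_path``: key-value sidecar, one ``atom`` line per atom plus
    per-frame ``replicate`` labels and the frame stride.
    """
    with open(topology_path, "w") as fh:
        fh.write("format: confens-topology-v1\n")
        if ensemble.frame_stride is not None:
            fh.write(f"frame_stride_ps: {ensemble.frame_stride!r}\n")
        fh.write(
            "replicate_id: " + ",".join(str(int(r)) for r in ensemble.replicate_id) + "\n"
        )
        for a in ensemble.topology.atoms:
            fh.write(
                f"atom: name={a.name} element={a.element} mass={a.mass!r} "
                f"residue_index={a.residue_index} residue_name={a.residue_name} "
                f"chain={a.chain_id}\n"
            )
    with open(frames_path, "w") as fh:
        fh.write("# frame x_nm y_nm z_nm\n")
        for f in range(ensemble.n_frames):
            for xyz in ensemble.coordinates[f]:
                fh.write(
                    f"{f} {float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r}\n"
                )


def read_frames_text(
    frames_path: str | Path,
    topology_path: str | Path,
    phospho_aliases: Iterable[str] = (),
) -> ConformationalEnsemble:
    """Read the auxiliary plain-text format written by :func:`write_frames_text`."""
    atoms: list[AtomRecord] = []
    replicate_id = None
    frame_stride = None
    for lineno, line in enumerate(Path(topology_path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "frame_stride_ps":
            frame_stride = float(value)
        elif key == "replicate_id":
            replicate_id = np.array([int(v) for v in value.split(",")], dtype=np.intp)
        elif key == "atom":
            fields = dict(tok.split("=", 1) for tok in value.split())
            try:
                atoms.append(
                    AtomRecord(
                        name=fields["name"],
                        element=fields["element"],
                        mass=float(fields["mass"]),
                        residue_index=int(fields["residue_index"]),
                        residue_name=fields["residue_name"],
                        chain_id=fields.get("chain", "A"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{topology_path}:{lineno}: bad atom line ({exc})")
    if not atoms:
        raise ParseError(f"{topology_path}: no atom records")
    topo = Topology(atoms, phospho_aliases=phospho_aliases)
    rows = []
    frame_col = []
    for lineno, line in enumerate(Path(frames_path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"{frames_path}:{lineno}: expected 'frame x y z'")
        frame_col.append(int(parts[0]))
        rows.append([float(p) for p in parts[1:]])
    coords = np.array(rows, dtype=float)
    n_frames = max(frame_col) + 1 if frame_col else 0
    if coords.shape[0] != n_frames * topo.n_atoms:
        raise StructuralError(
            f"{frames_path}: row count {coords.shape[0]} is not "
            f"n_frames*n_atoms = {n_frames}*{topo.n_atoms}"
        )
    coords = coords.reshape(n_frames, topo.n_atoms, 3)
    return ConformationalEnsemble(topo, coords, replicate_id, frame_stride)


# ---------------------------------------------------------------------------
# mdtraj bridge (used for RMSD fitting and as an independent DSSP oracle)
# ---------------------------------------------------------------------------


def to_mdtraj(ensemble: ConformationalEnsemble):
    """Convert to an :class:`mdtraj.Trajectory` (coordinates stay in nm)."""
    import mdtraj as md
    import mdtraj.core.element as mdelem

    top = md.Topology()
    chains: dict[str, object] = {}
    residues: dict[int, object] = {}
    for a in ensemble.topology.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = top.add_chain()
        if a.residue_index not in residues:
            residues[a.residue_index] = top.add_residue(
                a.residue_name, chains[a.chain_id], resSeq=a.residue_index + 1
            )
        try:
            element = mdelem.get_by_symbol(a.element.capitalize())
        except KeyError:
            element = mdelem.virtual
        top.add_atom(a.name, element, residues[a.residue_index])
    return md.Trajectory(
        ensemble.coordinates.astype(np.float32), top
    )
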