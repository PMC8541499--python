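"""Conditional free-energy landscapes from backbone-coordinate PCA.

The procedure mirrors standard ensemble-landscape analysis of disordered
peptides:

1. all frames are least-squares fitted (translation + rotation) onto the
   *central structure* — the medoid under backbone RMSD;
2. principal component analysis of the fitted backbone Cartesian
   coordinates; when two ensemble variants (e.g. non-phosphorylated and
   phosphorylated) are compared, the PCA basis is fitted on their pooled
   frames so both project into the same space and the landscapes are
   directly comparable;
3. the probability density over the first two principal components is
   estimated by Gaussian kernel density estimation and converted to a
   conditional free energy F = -ln(p / p_max) in units of RT, so the global
   minimum sits at 0;
4. basins are the attraction regions of grid local minima under steepest
   descent, each with its population (fraction of frames), its minimum
   energy class (<=1, <=2, <=3 RT) and a representative frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._errors import InputError, StructuralError
from ._geometry import superpose_frames
from .io import ConformationalEnsemble, backbone_selector, select_atoms

__all__ = [
    "PCBasis",
    "EnergyLandscape",
    "Basin",
    "medoid_fit",
    "shared_pca",
    "free_energy_surface",
    "find_basins",
    "representative_frame",
]

MEDOID_MAX_EXACT = 5000  # frames; above this the medoid search subsamples


@dataclass
class PCBasis:
    """Shared PCA basis: mean coordinate vector and orthonormal components."""

    mean_structure: np.ndarray  # (3N,)
    components: np.ndarray  # (k, 3N), rows orthonormal
    explained_variance: np.ndarray  # (k,), non-increasing, nm^2

    def project(self, flat_coords: np.ndarray) -> np.ndarray:
        return (flat_coords - self.mean_structure) @ self.components.T


@dataclass
class EnergyLandscape:
    """Gridded conditional free energy over (PC1, PC2), in RT units."""

    pc1_grid: np.ndarray  # (n1,) cell-centre coordinates
    pc2_grid: np.ndarray  # (n2,)
    free_energy: np.ndarray  # (n1, n2); min exactly 0
    density_bandwidth: tuple[float, float]
    projections: np.ndarray  # (n_frames, 2)
    replicate_id: np.ndarray | None = None


@dataclass
class Basin:
    """One attraction basin of the landscape."""

    cells: np.ndarray  # boolean (n1, n2) membership mask
    minimum: tuple[float, float]  # (PC1, PC2) of the minimum cell centre
    minimum_energy: float  # RT
    population: float  # fraction of all frames
    energy_class: str | None  # "<=1RT" | "<=2RT" | "<=3RT" | None
    representative_frame: int | None = None


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _backbone_atom_indices(ensemble: ConformationalEnsemble) -> np.ndarray:
    names = ensemble.topology.atom_names
    idx = np.flatnonzero(np.isin(names, ("N", "CA", "C", "O")))
    if len(idx) == 0:
        raise StructuralError("ensemble has no backbone atoms to fit on")
    return idx


def medoid_fit(
    ensemble: ConformationalEnsemble, max_exact: int = MEDOID_MAX_EXACT
) -> tuple[ConformationalEnsemble, int]:
    """Superpose every frame onto the central structure of the ensemble.

    The central structure is the medoid under backbone RMSD: the frame
    minimising the sum of backbone RMSDs to all frames.  The search is
    exact up to ``max_exact`` frames and runs on an evenly spaced
    ``max_exact``-frame subsample beyond that; the fit itself always covers
    every frame.  Returns (aligned ensemble, medoid frame index).
    """
    import mdtraj as md

    from .io import subsample_frames, to_mdtraj

    fit_idx = _backbone_atom_indices(ensemble)
    bb = select_atoms(ensemble, lambda a: a.name in ("N", "CA", "C", "O"))
    if ensemble.n_frames > max_exact:
        stride = ensemble.n_frames // max_exact
        search_frames = np.arange(max_exact, dtype=np.intp) * stride
    else:
        search_frames = np.arange(ensemble.n_frames, dtype=np.intp)
    traj = to_mdtraj(bb.frames(search_frames))
    best_sum, best_k = np.inf, 0
    for k in range(len(search_frames)):
        total = md.rmsd(traj, traj, k).sum()
        if total < best_sum:
            best_sum, best_k = total, k
    medoid = int(search_frames[best_k])
    aligned = superpose_frames(
        ensemble.coordinates, ensemble.coordinates[medoid], fit_idx
    )
    return ensemble.with_coordinates(aligned), medoid


def _flat_backbone(ensemble: ConformationalEnsemble) -> np.ndarray:
    idx = _backbone_atom_indices(ensemble)
    return ensemble.coordinates[:, idx].reshape(ensemble.n_frames, -1)


def shared_pca(
    ensemble_a: ConformationalEnsemble,
    ensemble_b: ConformationalEnsemble | None = None,
    n_components: int = 2,
    mode: str = "pooled",
) -> tuple[PCBasis, np.ndarray, np.ndarray | None]:
    """PCA of fitted backbone coordinates, with a basis shared across two
    ensembles so their landscapes are directly comparable.

    ``mode="pooled"`` (default) fits the basis on the pooled frames of both
    ensembles with equal weight per frame; ``mode="fit-first"`` fits on
    ensemble_a only and projects ensemble_b onto that basis.  In either
    mode both ensembles are first superposed onto the medoid of the pooled
    frames.  Returns (basis, projections_a, projections_b_or_None).
    """
    from sklearn.decomposition import PCA

    idx_a = _backbone_atom_indices(ensemble_a)
    if ensemble_b is None:
        aligned, _ = medoid_fit(ensemble_a)
        flat = _flat_backbone(aligned)
        pca = PCA(
            n_components=min(n_components, flat.shape[1], len(flat)),
            svd_solver="full",
        )
        proj = pca.fit_transform(flat)
        basis = PCBasis(pca.mean_, pca.components_, pca.explained_variance_)
        return basis, proj, None
    idx_b = _backbone_atom_indices(ensemble_b)
    if len(idx_a) != len(idx_b):
        raise StructuralError(
            f"backbone atom counts differ: {len(idx_a)} vs {len(idx_b)}"
        )
    pooled = ConformationalEnsemble(
        select_atoms(ensemble_a, backbone_selector).topology,
        np.concatenate(
            [ensemble_a.coordinates[:, idx_a], ensemble_b.coordinates[:, idx_b]]
        ),
    )
    aligned, _ = medoid_fit(pooled)
    flat = aligned.coordinates.reshape(aligned.n_frames, -1)
    n_a = ensemble_a.n_frames
    pca = PCA(
        n_components=min(n_components, flat.shape[1], len(flat)),
        svd_solver="full",
    )
    if mode == "pooled":
        proj = pca.fit_transform(flat)
        proj_a, proj_b = proj[:n_a], proj[n_a:]
    elif mode == "fit-first":
        pca.fit(flat[:n_a])
        proj_a = pca.transform(flat[:n_a])
        proj_b = pca.transform(flat[n_a:])
    else:
        raise InputError(f"unknown shared-PCA mode {mode!r}")
    basis = PCBasis(pca.mean_, pca.components_, pca.explained_variance_)
    return basis, proj_a, proj_b


# ---------------------------------------------------------------------------
# Free-energy surface
# ---------------------------------------------------------------------------


def free_energy_surface(
    projections: np.ndarray,
    grid_size: int = 200,
    replicate_id: np.ndarray | None = None,
) -> EnergyLandscape:
    """Conditional free energy F = -ln(p / p_max) on a (PC1, PC2) grid.

    The density is a 2-D Gaussian KDE with Scott's-rule bandwidth; the grid
    spans the occupied range extended by 3 bandwidths per axis.
    """
    from scipy.stats import gaussian_kde

    proj = np.asarray(projections, dtype=float)
    if proj.ndim != 2 or proj.shape[1] < 2:
        raise InputError("projections must be (n_frames, >=2)")
    proj = proj[:, :2]
    if len(proj) < 100:
        raise InputError("need at least 100 frames for a landscape")
    std = proj.std(axis=0, ddof=1)
    if np.any(std <= 0):
        raise InputError("degenerate projections: zero variance along a PC")
    kde = gaussian_kde(proj.T, bw_method="scott")
    bw = tuple(float(kde.factor * s) for s in std)
    grids = [
        np.linspace(proj[:, d].min() - 3 * bw[d], proj[:, d].max() + 3 * bw[d], grid_size)
        for d in (0, 1)
    ]
    mesh = np.meshgrid(grids[0], grids[1], indexing="ij")
    density = kde(np.vstack([m.ravel() for m in mesh])).reshape(grid_size, grid_size)
    p_max = density.max()
    with np.errstate(divide="ignore"):
        free = -np.log(density / p_max)
    free = free + 0.0  # normalise -0.0 at the global minimum
    return EnergyLandscape(
        pc1_grid=grids[0],
        pc2_grid=grids[1],
        free_energy=free,
        density_bandwidth=bw,
        projections=proj,
        replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# Basins
# ---------------------------------------------------------------------------


def _descent_pointers(free: np.ndarray) -> np.ndarray:
    """For every grid cell, the flat index of its steepest-descent neighbour
    (8-neighbourhood; itself when it is a local minimum).  Plateau ties go
    to the lowest flat index because candidates are scanned in that order."""
    n1, n2 = free.shape
    padded = np.pad(free, 1, constant_values=np.inf)
    shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    stacked = np.stack(
        [padded[1 + di : 1 + di + n1, 1 + dj : 1 + dj + n2] for di, dj in shifts]
    )
    best = np.argmin(stacked, axis=0)  # first minimum wins -> lowest flat index
    di = np.array([s[0] for s in shifts])[best]
    dj = np.array([s[1] for s in shifts])[best]
    ii, jj = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    return ((ii + di) * n2 + (jj + dj)).ravel()


def find_basins(
    landscape: EnergyLandscape, max_level: float = 5.0
) -> list[Basin]:
    """Basins of attraction of the landscape's local minima below
    ``max_level`` RT, ordered by population (descending).

    Every grid cell with F <= max_level drains along steepest descent to a
    local minimum; the frames whose projections fall into a basin's cells
    define its population.  Frames above the level (or outside the grid)
    stay unassigned, so populations sum to at most 1.
    """
    import warnings

    free = landscape.free_energy
    n1, n2 = free.shape
    ptr = _descent_pointers(free)
    # unoccupied (infinite-F) cells are their own sinks and never assigned
    own = np.arange(n1 * n2)
    ptr = np.where(np.isfinite(free.ravel()), ptr, own)
    # path-double until every pointer reaches its fixed point
    for _ in range(64):
        nxt = ptr[ptr]
        if np.array_equal(nxt, ptr):
            break
        ptr = nxt
    roots = np.unique(ptr)
    flat_free = free.ravel()
    minima = [r for r in roots if flat_free[r] <= max_level]
    if not minima:
        warnings.warn(f"no free-energy minima below {max_level} RT")
        return []
    # frame -> cell
    proj = landscape.projections
    i_idx = _nearest_cell(proj[:, 0], landscape.pc1_grid)
    j_idx = _nearest_cell(proj[:, 1], landscape.pc2_grid)
    frame_cell = i_idx * n2 + j_idx
    assigned_mask = flat_free <= max_level
    basins = []
    for root in minima:
        cells_flat = (ptr == root) & assigned_mask
        cells = cells_flat.reshape(n1, n2)
        member_frames = np.flatnonzero(cells_flat[frame_cell])
        population = len(member_frames) / len(proj)
        mi, mj = divmod(int(root), n2)
        min_energy = float(free[mi, mj])
        basin = Basin(
            cells=cells,
            minimum=(float(landscape.pc1_grid[mi]), float(landscape.pc2_grid[mj])),
            minimum_energy=min_energy,
            population=population,
            energy_class=_energy_class(min_energy),
        )
        basin.representative_frame = representative_frame(basin, landscape)
        basins.append(basin)
    basins.sort(key=lambda b: b.population, reverse=True)
    return basins


def _energy_class(min_energy: float) -> str | None:
    for level in (1, 2, 3):
        if min_energy <= level:
            return f"<={level}RT"
    return None


def _nearest_cell(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(grid, values)
    idx = np.clip(idx, 1, len(grid) - 1)
    left = np.abs(values - grid[idx - 1]) <= np.abs(values - grid[idx])
    return np.where(left, idx - 1, idx)


def representative_frame(
    basin: Basin, landscape: EnergyLandscape
) -> int | None:
    """Frame whose projection is nearest (Euclidean in PC space) to the
    basin minimum, among the frames inside the basin's cells."""
    proj = landscape.projections
    n2 = basin.cells.shape[1]
    i_idx = _nearest_cell(proj[:, 0], landscape.pc1_grid)
    j_idx = _nearest_cell(proj[:, 1], landscape.pc2_grid)
    inside = basin.cells[i_idx, j_idx]
    if not inside.any():
        return None
    candidates = np.flatnonzero(inside)
    d2 = np.sum((proj[candidates] - np.asarray(basin.minimum)) ** 2, axis=1)
    return int(candidates[np.argmin(d2)])
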