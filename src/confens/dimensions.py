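"""Global dimensions of an ensemble: Rg, Ree, distances, errors, shapes.

The quantities here summarise how large and how elongated a disordered
peptide is: the mass-weighted radius of gyration Rg, the end-to-end distance
Ree between the terminal CA atoms, and the dimensionless shape factor

    rs = <Ree^2> / <Rg^2>,

which is ~6 for an ideal Gaussian coil and ~12 for a stiff rod, so it
diagnoses compaction or stiffening of the chain (e.g. upon multisite
phosphorylation).  Because trajectory frames are strongly autocorrelated,
statistical errors of time averages are obtained by Flyvbjerg-Petersen
block averaging, and full distributions by Gaussian kernel density
estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._errors import InputError, SelectionError
from .io import ConformationalEnsemble

__all__ = [
    "ScalarSeries",
    "BlockAverageResult",
    "DistributionEstimate",
    "ShapeFactor",
    "radius_of_gyration",
    "end_to_end_distance",
    "inter_residue_distance",
    "block_average_error",
    "autocorrelation",
    "kde_distribution",
    "shape_factor",
    "shape_factor_from_ensemble",
]


@dataclass
class ScalarSeries:
    """A per-frame scalar observable with replicate grouping."""

    values: np.ndarray
    replicate_id: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.replicate_id = np.asarray(self.replicate_id, dtype=np.intp)
        if self.values.ndim != 1:
            raise InputError("series values must be 1-D")
        if self.replicate_id.shape != self.values.shape:
            raise InputError("replicate_id must match values in length")
        if not np.all(np.isfinite(self.values)):
            raise InputError("series contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def __pow__(self, exponent: float) -> "ScalarSeries":
        return ScalarSeries(
            self.values**exponent, self.replicate_id, f"{self.name}^{exponent:g}"
        )


@dataclass
class BlockAverageResult:
    """Mean and blocked standard error of a correlated series.

    ``block_curve`` records (block_size, error_estimate, error_uncertainty)
    per blocking level; ``converged`` is False when no plateau was found.
    """

    mean: float
    error: float
    block_curve: list[tuple[int, float, float]]
    converged: bool = True


@dataclass
class DistributionEstimate:
    """Gaussian-KDE density on a regular grid; integrates to 1."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


@dataclass
class ShapeFactor:
    """Shape factor rs with the ingredients it was computed from.

    ``convention`` is ``"mean-square"`` (rs = <Ree^2>/<Rg^2>; the Gaussian
    coil gives exactly 6 and the rod 12 in the long-chain limit) or
    ``"square-of-mean"`` (rs = <Ree>^2/<Rg>^2).
    """

    rs: float
    rg_used: float
    ree_used: float
    error: float
    convention: str = "mean-square"


def radius_of_gyration(
    ensemble: ConformationalEnsemble, weights: np.ndarray | None = None
) -> ScalarSeries:
    """Per-frame mass-weighted radius of gyration (nm) over all atoms.

    Rg = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i ), the convention of
    standard MD analysis tools.  ``weights`` overrides the topology masses.
    """
    masses = ensemble.topology.masses if weights is None else np.asarray(weights, float)
    total = masses.sum()
    if total <= 0:
        raise InputError("total mass must be positive")
    w = masses / total
    com = np.einsum("a,fai->fi", w, ensemble.coordinates)
    delta = ensemble.coordinates - com[:, np.newaxis]
    rg2 = np.einsum("a,fa->f", w, np.sum(delta**2, axis=2))
    return ScalarSeries(np.sqrt(rg2), ensemble.replicate_id, "Rg")


def _endpoint_index(ensemble: ConformationalEnsemble, residue: int, atom: str) -> int:
    idx = ensemble.topology.atom_indices(residue=residue, name=atom)
    if len(idx) == 0:
        raise SelectionError(
            f"residue {residue} has no atom named {atom!r}"
        )
    return int(idx[0])


def end_to_end_distance(
    ensemble: ConformationalEnsemble, atom: str = "CA"
) -> ScalarSeries:
    """Per-frame distance (nm) between ``atom`` of the first and last
    residues (CA by default; bead chains use their single CA pseudo-atom)."""
    i = _endpoint_index(ensemble, 0, atom)
    j = _endpoint_index(ensemble, ensemble.n_residues - 1, atom)
    d = np.linalg.norm(
        ensemble.coordinates[:, j] - ensemble.coordinates[:, i], axis=1
    )
    return ScalarSeries(d, ensemble.replicate_id, "Ree")


def inter_residue_distance(
    ensemble: ConformationalEnsemble, i: int, j: int, atom: str = "CA"
) -> ScalarSeries:
    """Per-frame distance (nm) between the named atom of residues i and j."""
    ai = _endpoint_index(ensemble, i, atom)
    aj = _endpoint_index(ensemble, j, atom)
    d = np.linalg.norm(
        ensemble.coordinates[:, aj] - ensemble.coordinates[:, ai], axis=1
    )
    return ScalarSeries(d, ensemble.replicate_id, f"d({i},{j},{atom})")


# ---------------------------------------------------------------------------
# Error estimation for correlated series
# ---------------------------------------------------------------------------

_MIN_BLOCKS_FOR_PLATEAU = 16


def block_average_error(series: ScalarSeries | np.ndarray) -> BlockAverageResult:
    """Flyvbjerg-Petersen blocking analysis of a correlated series.

    The series is repeatedly pair-averaged; at each level the naive standard
    error of the mean, sqrt(var / n_blocks), is recorded together with its
    own statistical uncertainty err/sqrt(2(n_blocks-1)).  The reported error
    is the plateau of this curve: starting from the first level whose
    increase to the next level is within its uncertainty band, errors over
    the remaining usable levels (>= 16 blocks) are averaged.  If the curve
    is still rising at the last usable level, the maximum estimate is
    returned and the result is flagged unconverged.

    Fewer than 32 frames (5 blocking levels) triggers a warning and returns
    the naive i.i.d. standard error, flagged unconverged.
    """
    x = series.values if isinstance(series, ScalarSeries) else np.asarray(series, float)
    n = len(x)
    mean = float(x.mean())
    if n < 2:
        raise InputError("need at least 2 frames for an error estimate")
    naive = float(np.std(x, ddof=1) / np.sqrt(n))
    if n < 32:
        warnings.warn(
            f"series of length {n} too short for blocking (need >= 32 frames); "
            "returning naive standard error",
            stacklevel=2,
        )
        return BlockAverageResult(mean, naive, [(1, naive, 0.0)], converged=False)
    curve: list[tuple[int, float, float]] = []
    y = x.astype(float)
    block_size = 1
    while len(y) >= 2:
        m = len(y)
        err = float(np.std(y, ddof=1) / np.sqrt(m))
        unc = err / np.sqrt(2.0 * (m - 1))
        curve.append((block_size, err, unc))
        if m % 2 == 1:
            y = y[:-1]
        y = 0.5 * (y[0::2] + y[1::2])
        block_size *= 2
    usable = [
        k
        for k, (bs, _, _) in enumerate(curve)
        if n // bs >= _MIN_BLOCKS_FOR_PLATEAU
    ]
    if len(usable) < 2:
        return BlockAverageResult(mean, naive, curve, converged=False)
    last = usable[-1]
    onset = None
    for k in usable[:-1]:
        # plateau onset: the next level no longer rises beyond this level's band
        if curve[k + 1][1] - curve[k][1] <= curve[k][2]:
            onset = k
            break
    if onset is None:
        err = max(curve[k][1] for k in usable)
        return BlockAverageResult(mean, float(err), curve, converged=False)
    plateau_errors = [curve[k][1] for k in usable if k >= onset]
    return BlockAverageResult(mean, float(np.mean(plateau_errors)), curve)


def autocorrelation(
    series: ScalarSeries | np.ndarray, max_lag: int
) -> np.ndarray:
    """Normalised autocorrelation function for lags 0..max_lag (ACF(0)=1)."""
    from statsmodels.tsa.stattools import acf

    x = series.values if isinstance(series, ScalarSeries) else np.asarray(series, float)
    if max_lag >= len(x):
        raise InputError("max_lag must be smaller than the series length")
    return acf(x, nlags=max_lag, fft=True)


def kde_distribution(
    series: ScalarSeries | np.ndarray,
    bandwidth: float | None = None,
    n_grid: int = 512,
) -> DistributionEstimate:
    """Gaussian kernel density estimate of the observable's distribution.

    Bandwidth defaults to Scott's factor n^(-1/5) times the sample standard
    deviation; the grid spans the data range extended by 3 bandwidths.
    """
    x = series.values if isinstance(series, ScalarSeries) else np.asarray(series, float)
    if len(np.unique(x)) < 2:
        raise InputError("all values identical: distribution is degenerate")
    if bandwidth is None:
        kde = stats.gaussian_kde(x, bw_method="scott")
    else:
        if bandwidth <= 0:
            raise InputError("bandwidth must be positive")
        kde = stats.gaussian_kde(x, bw_method=bandwidth / np.std(x, ddof=1))
    h = float(kde.factor * np.std(x, ddof=1))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, n_grid)
    density = kde(grid)
    return DistributionEstimate(grid=grid, density=density, bandwidth=h)


# ---------------------------------------------------------------------------
# Shape factor
# ---------------------------------------------------------------------------


def shape_factor(
    rg: BlockAverageResult, ree: BlockAverageResult, convention: str = "mean-square"
) -> ShapeFactor:
    """Shape factor from blocked averages of the squared dimensions.

    ``rg`` and ``ree`` are block-average results for the Rg^2 and Ree^2
    series ("mean-square" convention, the default: rs = <Ree^2>/<Rg^2>) or
    for Rg and Ree themselves ("square-of-mean": rs = <Ree>^2/<Rg>^2).
    The error is first-order propagation of the two block errors.
    """
    if rg.mean <= 0:
        raise InputError("mean squared radius of gyration must be positive")
    if convention == "mean-square":
        rs = ree.mean / rg.mean
        err = rs * np.hypot(ree.error / ree.mean, rg.error / rg.mean)
    elif convention == "square-of-mean":
        rs = ree.mean**2 / rg.mean**2
        err = rs * 2.0 * np.hypot(ree.error / ree.mean, rg.error / rg.mean)
    else:
        raise InputError(f"unknown shape-factor convention {convention!r}")
    return ShapeFactor(
        rs=float(rs),
        rg_used=float(rg.mean),
        ree_used=float(ree.mean),
        error=float(err),
        convention=convention,
    )


def shape_factor_from_ensemble(
    ensemble: ConformationalEnsemble,
    endpoint_atom: str = "CA",
    convention: str = "mean-square",
) -> ShapeFactor:
    """Convenience: compute Rg/Ree series, block their (squared) averages
    and form the shape factor in one call."""
    rg = radius_of_gyration(ensemble)
    ree = end_to_end_distance(ensemble, atom=endpoint_atom)
    if convention == "mean-square":
        rg, ree = rg**2, ree**2
    if ensemble.n_frames == 1:
        rg_bar = BlockAverageResult(float(rg.values[0]), 0.0, [(1, 0.0, 0.0)])
        ree_bar = BlockAverageResult(float(ree.values[0]), 0.0, [(1, 0.0, 0.0)])
    else:
        rg_bar = block_average_error(rg)
        ree_bar = block_average_error(ree)
    return shape_factor(rg_bar, ree_bar, convention)
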