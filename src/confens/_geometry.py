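"""Small vector-geometry helpers shared by the builders and analyses.

All functions are vectorised over leading axes; angles are in degrees.
"""

from __future__ import annotations

import numpy as np


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def angle_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Angle at ``p1`` of the triple p0-p1-p2."""
    u = _unit(np.asarray(p0) - np.asarray(p1))
    v = _unit(np.asarray(p2) - np.asarray(p1))
    cosang = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def dihedral_deg(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> np.ndarray:
    """Signed dihedral p0-p1-p2-p3 in (-180, 180], IUPAC sign convention."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _unit(b2))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom d at distance ``bond`` from c, bond angle b-c-d ``angle``
    and dihedral a-b-c-d ``torsion`` (degrees) — the NeRF construction."""
    theta = np.radians(angle)
    phi = np.radians(torsion)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), -np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def superpose_frames(
    coords: np.ndarray, ref: np.ndarray, fit_indices: np.ndarray
) -> np.ndarray:
    """Least-squares superpose every frame onto ``ref`` (batched Kabsch).

    ``coords``: (frames, atoms, 3); ``ref``: (atoms, 3); the rotation is
    fitted on ``fit_indices`` and applied to all atoms, in float64.
    """
    fit = np.asarray(fit_indices, dtype=np.intp)
    ref_fit = ref[fit]
    ref_cen = ref_fit.mean(axis=0)
    x0 = ref_fit - ref_cen
    frame_cen = coords[:, fit].mean(axis=1, keepdims=True)
    y = coords[:, fit] - frame_cen
    h = np.einsum("fai,aj->fij", y, x0)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", u, vt)))
    flip = np.ones((len(coords), 3))
    flip[:, 2] = d
    rot = np.einsum("fij,fj,fjk->fik", u, flip, vt)
    moved = np.einsum("fai,fij->faj", coords - frame_cen, rot)
    return moved + ref_cen


def random_rotation_matrices(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` rotation matrices drawn uniformly from SO(3) (quaternion method)."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    mats = np.empty((n, 3, 3))
    mats[:, 0, 0] = 1 - 2 * (y * y + z * z)
    mats[:, 0, 1] = 2 * (x * y - z * w)
    mats[:, 0, 2] = 2 * (x * z + y * w)
    mats[:, 1, 0] = 2 * (x * y + z * w)
    mats[:, 1, 1] = 1 - 2 * (x * x + z * z)
    mats[:, 1, 2] = 2 * (y * z - x * w)
    mats[:, 2, 0] = 2 * (x * z - y * w)
    mats[:, 2, 1] = 2 * (y * z + x * w)
    mats[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return mats
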