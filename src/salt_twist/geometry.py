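"""Batched 3D geometry primitives shared across the package.

All functions broadcast over arbitrary leading batch dimensions so that
per-frame, per-residue operations on trajectories vectorize.  Angles are in
degrees at every public boundary; quaternions use scalar-last ``(x, y, z, w)``
ordering to match :mod:`scipy.spatial.transform`.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "wrap_angle",
    "unit",
    "rotation_about_axis",
    "signed_angle",
    "dihedral",
    "nerf",
    "quaternion_mean",
    "mean_rotation",
    "kabsch",
    "rotvec_of",
]


def wrap_angle(deg: np.ndarray | float) -> np.ndarray | float:
    """Map angles in degrees to the principal branch (-180, 180]."""
    wrapped = -np.mod(-np.asarray(deg, dtype=float) + 180.0, 360.0) + 180.0
    return wrapped


def unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize vectors along ``axis``; raises on zero norm."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n < 1e-300):
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: np.ndarray | float) -> np.ndarray:
    """Rodrigues rotation matrices (...,3,3) about unit ``axis`` (...,3)."""
    axis = np.asarray(axis, dtype=float)
    theta = np.deg2rad(np.asarray(angle_deg, dtype=float))
    theta = np.broadcast_to(theta, axis.shape[:-1])
    x, y, z = axis[..., 0], axis[..., 1], axis[..., 2]
    c, s = np.cos(theta), np.sin(theta)
    C = 1.0 - c
    R = np.empty(axis.shape[:-1] + (3, 3), dtype=float)
    R[..., 0, 0] = c + x * x * C
    R[..., 0, 1] = x * y * C - z * s
    R[..., 0, 2] = x * z * C + y * s
    R[..., 1, 0] = y * x * C + z * s
    R[..., 1, 1] = c + y * y * C
    R[..., 1, 2] = y * z * C - x * s
    R[..., 2, 0] = z * x * C - y * s
    R[..., 2, 1] = z * y * C + x * s
    R[..., 2, 2] = c + z * z * C
    return R


def signed_angle(v1: np.ndarray, v2: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Signed angle (deg) from ``v1`` to ``v2`` about ``axis`` (right-handed)."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    cross = np.cross(v1, v2)
    s = np.einsum("...i,...i->...", cross, unit(axis))
    c = np.einsum("...i,...i->...", v1, v2)
    return np.rad2deg(np.arctan2(s, c))


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = unit(b1)
    m1 = np.cross(n1, b1u)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    return np.rad2deg(np.arctan2(y, x))


def nerf(a, b, c, bond, angle_deg, torsion_deg) -> np.ndarray:
    """Place atom D from internal coordinates relative to chain a-b-c.

    Natural-extension-reference-frame placement: ``|c-D| = bond``,
    ``angle(b, c, D) = angle_deg`` and ``torsion(a, b, c, D) = torsion_deg``.
    Fully batched; scalar internals broadcast.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    batch = np.broadcast_shapes(
        a.shape[:-1], b.shape[:-1], c.shape[:-1],
        np.shape(bond), np.shape(angle_deg), np.shape(torsion_deg),
    )
    bond = np.broadcast_to(np.asarray(bond, dtype=float), batch)[..., None]
    theta = np.deg2rad(np.broadcast_to(np.asarray(angle_deg, dtype=float), batch))[..., None]
    chi = np.deg2rad(np.broadcast_to(np.asarray(torsion_deg, dtype=float), batch))[..., None]

    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.concatenate(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            -bond * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    return c + d_local[..., 0:1] * bc + d_local[..., 1:2] * m + d_local[..., 2:3] * n


def quaternion_mean(quats: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Average unit quaternions (..., k, 4) by the dominant-eigenvector method.

    Quaternions are sign-aligned to the first entry before accumulating the
    outer-product matrix M = sum w q q^T; the mean is the eigenvector of M with
    the largest eigenvalue (the minimizer of summed squared chordal distance
    for small dispersions).  q and -q are identified.
    """
    q = np.asarray(quats, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError("quaternions must have last dimension 4")
    sign = np.sign(np.einsum("...kj,...j->...k", q, q[..., 0, :]))
    sign = np.where(sign == 0.0, 1.0, sign)
    q = q * sign[..., None]
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        q = q * np.sqrt(w)[..., None]
    M = np.einsum("...ki,...kj->...ij", q, q)
    eigvals, eigvecs = np.linalg.eigh(M)
    mean = eigvecs[..., :, -1]
    return unit(mean)


def mean_rotation(matrices: np.ndarray) -> np.ndarray:
    """Quaternion-average a batch of rotation matrices (..., k, 3, 3)."""
    mats = np.asarray(matrices, dtype=float)
    lead = mats.shape[:-3]
    k = mats.shape[-3]
    quats = Rotation.from_matrix(mats.reshape(-1, 3, 3)).as_quat().reshape(lead + (k, 4))
    qmean = quaternion_mean(quats)
    return Rotation.from_quat(qmean.reshape(-1, 4)).as_matrix().reshape(lead + (3, 3))


def kabsch(template: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation + translation mapping template onto observed.

    Least-squares rigid superposition (no reflection): returns ``(R, t)`` with
    ``R @ x + t ~= y`` for template points ``x`` (m, 3) and observed points
    ``y`` (..., m, 3).  ``R`` is (..., 3, 3), ``t`` is (..., 3).
    """
    x = np.asarray(template, dtype=float)
    y = np.asarray(observed, dtype=float)
    cx = x.mean(axis=-2)
    cy = y.mean(axis=-2)
    xc = x - cx
    yc = y - cy[..., None, :]
    H = np.einsum("...mi,...mj->...ij", np.broadcast_to(xc, yc.shape), yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("...ij,...jk->...ik", U, Vt)))
    D = np.zeros(H.shape[:-2] + (3, 3))
    D[..., 0, 0] = 1.0
    D[..., 1, 1] = 1.0
    D[..., 2, 2] = d
    # R = V D U^T maps template onto observed without reflection
    R = np.einsum("...ji,...jk,...lk->...il", Vt, D, U)
    t = cy - np.einsum("...ij,j->...i", R, cx)
    return R, t


def rotvec_of(R: np.ndarray) -> np.ndarray:
    """Rotation vector (radians) of rotation matrices (..., 3, 3)."""
    mats = np.asarray(R, dtype=float)
    lead = mats.shape[:-2]
    rv = Rotation.from_matrix(mats.reshape(-1, 3, 3)).as_rotvec()
    return rv.reshape(lead + (3,))
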