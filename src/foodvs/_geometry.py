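"""Rigid-body geometry primitives: Kabsch superposition and deterministic
rotation sampling.  Internal module; the public surface is re-exported by
:mod:`foodvs.rigid_align`."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

DEGENERACY_TOL = 1e-8


def kabsch(moving: np.ndarray, target: np.ndarray, *, strict: bool = True):
    """Least-squares optimal proper rotation/translation mapping ``moving``
    onto ``target`` (matched point sets, shape (n, 3)).

    Returns ``(R, t, rmsd)`` with ``R @ p + t`` the transformed point.
    With ``strict=True``, fewer than 3 points or a collinear set raises
    ``ValueError``; with ``strict=False`` rank-deficient sets are allowed
    (the rotation is then one optimal choice among many).
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    n = moving.shape[0]
    if strict and n < 3:
        raise ValueError("need at least 3 matched points")
    cm = moving.mean(axis=0)
    ct = target.mean(axis=0)
    a = moving - cm
    b = target - ct
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    if strict and (s[1] < DEGENERACY_TOL * max(s[0], 1.0)):
        raise ValueError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    rot = vt.T @ corr @ u.T
    t = ct - rot @ cm
    diff = (moving @ rot.T + t) - target
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return rot, t, rmsd


def pairwise_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Best-fit RMSD between two conformations of the same atom ordering."""
    _, _, rmsd = kabsch(coords_a, coords_b, strict=False)
    return rmsd


def rotation_grid(n: int = 60) -> list[np.ndarray]:
    """Deterministic quasi-uniform sample of SO(3) as rotation matrices.

    Uses the super-Fibonacci spiral on the unit quaternions; the identity is
    always included first so that already-aligned inputs are found exactly.
    """
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041
    mats = [np.eye(3)]
    for i in range(n):
        s = i + 0.5
        r = np.sqrt(s / n)
        big_r = np.sqrt(1.0 - s / n)
        alpha = 2.0 * np.pi * s / phi
        beta = 2.0 * np.pi * s / psi
        q = np.array([r * np.sin(alpha), r * np.cos(alpha),
                      big_r * np.sin(beta), big_r * np.cos(beta)])
        mats.append(Rotation.from_quat(q).as_matrix())
    return mats


def rotation_angle_deg(r: np.ndarray) -> float:
    """Rotation angle of a 3x3 rotation matrix, in degrees."""
    c = (np.trace(r) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
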