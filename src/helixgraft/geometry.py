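"""Internal-coordinate geometry helpers.

Everything here is batched: coordinate arguments have shape ``(..., 3)``
and scalar arguments broadcast against the leading dimensions, so the same
code builds a single structure or a whole stack of trajectory frames.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "dihedral",
    "place_atom",
    "rotation_about_axis",
    "rotation_aligning",
]


def unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize vectors along ``axis``; zero vectors raise."""
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = unit(b1)
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def place_atom(a, b, c, bond: float, angle_deg, torsion_deg) -> np.ndarray:
    """Place atom ``d`` from three predecessors (NeRF construction).

    ``d`` is bonded to ``c`` at distance ``bond``, forms angle b-c-d of
    ``angle_deg`` and torsion a-b-c-d of ``torsion_deg``.  ``a, b, c`` are
    ``(..., 3)`` arrays; angles broadcast.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ang, tor = np.broadcast_arrays(
        np.radians(np.asarray(angle_deg, dtype=float)),
        np.radians(np.asarray(torsion_deg, dtype=float)),
    )

    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)

    d_local = np.stack(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ],
        axis=-1,
    )
    return c + (
        d_local[..., 0:1] * bc + d_local[..., 1:2] * m + d_local[..., 2:3] * n
    )


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about ``axis`` (Rodrigues)."""
    u = unit(np.asarray(axis, dtype=float))
    t = np.radians(angle_deg)
    ct, st = np.cos(t), np.sin(t)
    ux, uy, uz = u
    k = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return ct * np.eye(3) + st * k + (1.0 - ct) * np.outer(u, u)


def rotation_aligning(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying direction ``v_from`` onto ``v_to``."""
    f = unit(np.asarray(v_from, dtype=float))
    t = unit(np.asarray(v_to, dtype=float))
    c = float(np.dot(f, t))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any axis orthogonal to f
        helper = np.array([1.0, 0.0, 0.0])
        if abs(f[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(f, helper)
        return rotation_about_axis(axis, 180.0)
    axis = np.cross(f, t)
    angle = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return rotation_about_axis(axis, angle)
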