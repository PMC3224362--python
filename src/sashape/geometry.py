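"""Parametric Cα-trace generators shared by the alphabet model and the
synthetic-structure module.

All generators return ``(n, 3)`` float arrays in Å.  A canonical α-helix is
radius 2.3 Å, rise 1.5 Å/residue, twist 100°/residue; ``curvature`` bends the
helix (or strand) axis by the given number of degrees per residue.
"""

from __future__ import annotations

import numpy as np

__all__ = ["helix_points", "strand_points", "rotation_about_x", "rotation_about_y",
           "superpose", "nerf_place"]


def rotation_about_x(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_about_y(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def _arc_bend(pts: np.ndarray, axis: int, lateral: int,
              step: float, curvature_deg: float) -> np.ndarray:
    """Bend a straight-axis trace onto a circular arc of constant curvature.

    The axis coordinate is wrapped onto a circle whose radius makes the local
    axis direction turn ``curvature_deg`` degrees per axis step; the map is
    an isometry on the axis itself, so Cα–Cα step lengths are preserved up to
    the (small) lateral offset of the trace from its axis.
    """
    r_bend = step / np.radians(curvature_deg)
    out = pts.copy()
    phi = pts[:, axis] / r_bend
    arm = r_bend + pts[:, lateral]
    out[:, lateral] = arm * np.cos(phi) - r_bend
    out[:, axis] = arm * np.sin(phi)
    return out


def helix_points(n: int, radius: float = 2.3, rise: float = 1.5,
                 twist_deg: float = 100.0, curvature_deg: float = 0.0) -> np.ndarray:
    """Cα positions of an ideal (optionally bent) right-handed helix.

    ``curvature_deg`` bends the helix axis by that many degrees per residue
    along a circular arc (0 = straight)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n)
    theta = np.radians(twist_deg) * k
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * k])
    if curvature_deg:
        pts = _arc_bend(pts, axis=2, lateral=1, step=rise,
                        curvature_deg=curvature_deg)
    return pts


def strand_points(n: int, step: float = 3.8, pleat: float = 0.9,
                  twist_deg: float = 0.0, curvature_deg: float = 0.0) -> np.ndarray:
    """Cα positions of an extended (pleated, optionally twisted/bent) strand."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if 2.0 * pleat >= step:
        raise ValueError("pleat amplitude too large for the step length")
    dx = np.sqrt(step ** 2 - (2.0 * pleat) ** 2)
    k = np.arange(n)
    pts = np.column_stack([k * dx, pleat * (-1.0) ** k, np.zeros(n)])
    if twist_deg:
        pts = np.array([rotation_about_x(np.radians(twist_deg) * i) @ p
                        for i, p in enumerate(pts)])
    if curvature_deg:
        # bend within the strand plane: windows stay (nearly) planar, the
        # curvature shows as alternating d1/d3 shortening rather than P4
        pts = _arc_bend(pts, axis=0, lateral=1, step=dx,
                        curvature_deg=curvature_deg)
    return pts


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` best fits ``target``;
    the determinant correction enforces a proper rotation.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("superposition needs >= 3 matched points")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, tc - rot @ mc


def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given atoms A, B, C and the internal coordinates
    |C–D|, ∠(B,C,D) and torsion (A,B,C,D) — the natural-extension reference
    frame construction."""
    ang, tor = np.radians(angle_deg), np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n
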