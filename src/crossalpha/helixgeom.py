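"""Per-helix and helix-pair geometry.

Provides the axis fit used everywhere downstream, the signed helix crossing
angle Ω, tilt angles relative to the filament axis, and optimal rigid
superposition (Kabsch) with CA-substack RMSD built on top of it.

Sign conventions
----------------
* Helix axes are oriented N→C.
* Ω is the angle from axis A to axis B, measured about the common-perpendicular
  unit vector pointing *from A to B* at closest approach. With this convention
  a canonical left-handed-supercoil parallel coiled coil comes out near −20°
  and a right-handed GxxxG-like pair near +40°, matching the packing angles
  quoted for those motifs in the coiled-coil literature.
* Tilt is 90° minus the angle to the filament axis, signed by the axial
  component of the N→C direction, so a helix perpendicular to the filament
  axis (the cross-α limit) has tilt 0°.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .structio import Structure

__all__ = [
    "HelixAxis",
    "CrossingAngle",
    "Superposition",
    "fit_helix_axis",
    "crossing_angle",
    "tilt_angle",
    "superpose",
    "substack_rmsd",
]


@dataclasses.dataclass
class HelixAxis:
    point: np.ndarray       # centroid of the fitted axis points, Å
    direction: np.ndarray   # unit vector, oriented N→C
    fit_rms: float          # RMS distance of local axis points to the line, Å

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, float)
        self.direction = np.asarray(self.direction, float)
        assert abs(np.linalg.norm(self.direction) - 1.0) < 1e-9


@dataclasses.dataclass
class CrossingAngle:
    omega: float             # signed degrees in (−180, 180]
    closest_approach: float  # Å between the two axis lines


@dataclasses.dataclass
class Superposition:
    rotation: np.ndarray     # 3×3 proper orthonormal
    translation: np.ndarray  # Å
    rmsd: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float) @ self.rotation.T + self.translation


def fit_helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Fit a straight helix axis to ordered CA positions.

    Local axis points are recovered by the bisector construction: for each
    interior CA the vector ``(CA[i-1]-CA[i]) + (CA[i+1]-CA[i])`` points at the
    axis with magnitude ``2r(1-cos t)`` where ``t`` is the twist per residue,
    estimated from the angle between consecutive bisectors. A total-least-
    squares line (principal component) through the recovered points gives the
    axis; this stays robust down to the 5–7 residue fragments used in motif
    work, where cylinder fitting is poorly conditioned.
    """
    ca = np.asarray(ca_coords, float).reshape(-1, 3)
    n = len(ca)
    if n < 5:
        raise ValueError(f"need at least 5 CA positions to fit an axis, got {n}")
    bis = (ca[:-2] - ca[1:-1]) + (ca[2:] - ca[1:-1])
    norms = np.linalg.norm(bis, axis=1)
    if np.any(norms < 1e-8):
        raise ValueError("degenerate (collinear) CA trace: bisectors vanish")
    u = bis / norms[:, None]
    # twist per residue from successive bisector directions
    cosines = np.clip(np.sum(u[:-1] * u[1:], axis=1), -1.0, 1.0)
    twist = float(np.mean(np.arccos(cosines)))
    if twist < 1e-6:
        raise ValueError("degenerate CA trace: no measurable twist")
    radii = norms / (2.0 * (1.0 - np.cos(twist)))
    axis_pts = ca[1:-1] + u * radii[:, None]

    centroid = axis_pts.mean(axis=0)
    centered = axis_pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if len(axis_pts) >= 2 and np.ptp(centered @ direction) < 1e-12:
        # all axis points coincide (very short fragment): fall back to CA span
        direction = ca[-1] - ca[0]
        direction = direction / np.linalg.norm(direction)
    # orient N→C
    if np.dot(direction, ca[-1] - ca[0]) < 0:
        direction = -direction
    perp = centered - np.outer(centered @ direction, direction)
    fit_rms = float(np.sqrt(np.mean(np.sum(perp ** 2, axis=1))))
    return HelixAxis(centroid, direction / np.linalg.norm(direction), fit_rms)


def _line_closest_points(a: HelixAxis, b: HelixAxis) -> tuple[np.ndarray, np.ndarray]:
    """Closest points on the two (infinite) axis lines."""
    d1, d2 = a.direction, b.direction
    r = b.point - a.point
    c = np.cross(d1, d2)
    c2 = np.dot(c, c)
    if c2 < 1e-16:  # parallel
        t1 = np.dot(r, d1)
        return a.point + t1 * d1 - (r - np.dot(r, d1) * d1) * 0.0, b.point
    t1 = np.dot(np.cross(r, d2), c) / c2
    t2 = np.dot(np.cross(r, d1), c) / c2
    return a.point + t1 * d1, b.point + t2 * d2


def crossing_angle(a: HelixAxis, b: HelixAxis) -> CrossingAngle:
    """Signed crossing angle Ω between two oriented helix axes."""
    d1, d2 = a.direction, b.direction
    mag = float(np.degrees(np.arccos(np.clip(np.dot(d1, d2), -1.0, 1.0))))
    c = np.cross(d1, d2)
    p1, p2 = _line_closest_points(a, b)
    sep = p2 - p1
    dist = float(np.linalg.norm(sep))
    if np.linalg.norm(c) < 1e-12:
        # exactly (anti)parallel: magnitude is 0 or 180, sign undefined
        return CrossingAngle(mag, dist)
    if dist > 1e-9:
        sign = 1.0 if np.dot(c, sep) >= 0 else -1.0
    else:
        sign = 1.0  # intersecting axes: sign convention degenerate, report +
    omega = sign * mag
    if omega <= -180.0:
        omega += 360.0
    return CrossingAngle(omega, dist)


def tilt_angle(h: HelixAxis, filament_axis: np.ndarray) -> float:
    """Tilt of a helix relative to the plane normal to the filament axis.

    Returns ``90° − angle(direction, filament_axis)`` in [−90, 90]: zero for a
    helix lying in the cross-sectional plane, +90° for one parallel to the
    filament axis.
    """
    f = np.asarray(filament_axis, float)
    nf = np.linalg.norm(f)
    if nf < 1e-12:
        raise ValueError("filament axis must be a nonzero vector")
    f = f / nf
    return float(np.degrees(np.arcsin(np.clip(np.dot(h.direction, f), -1.0, 1.0))))


def superpose(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-RMSD proper rigid superposition of *moving* onto *fixed* (Kabsch).

    The optimal rotation comes from the SVD of the cross-covariance matrix
    with the determinant sign corrected so no reflection is ever returned.
    """
    x = np.asarray(moving, float).reshape(-1, 3)
    y = np.asarray(fixed, float).reshape(-1, 3)
    if x.shape != y.shape:
        raise ValueError(f"point counts differ: {x.shape[0]} vs {y.shape[0]}")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a rigid superposition")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc
    diff = x0 @ rot.T - y0
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return Superposition(rot, trans, rmsd)


def substack_rmsd(stack_a: Structure, stack_b: Structure,
                  correspondence: list[tuple[tuple[str, int], tuple[str, int]]]
                  | None = None) -> float:
    """CA-only RMSD of two helix stacks after optimal superposition.

    ``correspondence`` maps ``(chain_id, seq_id)`` in *stack_a* to
    ``(chain_id, seq_id)`` in *stack_b*; when omitted, chains and residues are
    paired in order (requires identical layout).
    """
    if correspondence is None:
        correspondence = []
        for ca_chain, cb_chain in zip(stack_a.chains, stack_b.chains):
            for ra, rb in zip(ca_chain.residues, cb_chain.residues):
                correspondence.append(((ca_chain.chain_id, ra.seq_id),
                                       (cb_chain.chain_id, rb.seq_id)))
    if not correspondence:
        raise ValueError("empty residue correspondence")
    pa, pb = [], []
    for (cid_a, sid_a), (cid_b, sid_b) in correspondence:
        ra = stack_a.chain(cid_a).residue(sid_a)
        rb = stack_b.chain(cid_b).residue(sid_b)
        if ra.has_atom("CA") and rb.has_atom("CA"):
            pa.append(ra.atom("CA").position)
            pb.append(rb.atom("CA").position)
    if not pa:
        raise ValueError("correspondence matched no CA atom pairs")
    return superpose(np.array(pa), np.array(pb)).rmsd
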