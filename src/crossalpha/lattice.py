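"""Helical-symmetry and surface-lattice mathematics for filaments.

A filament is generated from an asymmetric unit by a screw operation
(*rise* Å of axial translation plus *twist* degrees of rotation per subunit),
optionally combined with Cn point-group symmetry. The subunits then lie on a
cylindrical surface lattice; the *n-start* families are the sets of lattice
lines connecting every n-th subunit of the 1-start helix. Which family runs
closest to the filament axis identifies the axial stacking direction of the
protofilaments, and hence the protofilament count, directly from the refined
symmetry parameters.

Twist sign convention: positive twist means a right-handed 1-start helix; an
n-start family is left-handed exactly when ``wrap(n*twist) < 0``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .helixgeom import superpose
from .structio import Structure

__all__ = [
    "HelicalSymmetry",
    "NStartFamily",
    "HelicalNet",
    "IdealHelixParams",
    "wrap_angle",
    "helical_displacement",
    "enumerate_nstart",
    "stacking_direction",
    "helical_net",
    "fit_symmetry",
]


def wrap_angle(theta: float) -> float:
    """Wrap an angle in degrees to the interval (−180, 180]."""
    if not math.isfinite(theta):
        raise ValueError("angle must be finite")
    w = theta % 360.0
    if w > 180.0:
        w -= 360.0
    return w


@dataclasses.dataclass(frozen=True)
class HelicalSymmetry:
    """Screw symmetry of a 1-start helical lattice of asymmetric units."""

    rise: float           # Å / subunit
    twist: float          # degrees / subunit, in (−180, 180], + = right-handed
    cyclic_order: int = 1  # Cn point group

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if wrap_angle(self.twist) == 0:
            raise ValueError("twist must be nonzero")
        if self.cyclic_order < 1:
            raise ValueError("cyclic order must be >= 1")
        object.__setattr__(self, "twist", wrap_angle(self.twist))

    @property
    def subunits_per_turn(self) -> float:
        return 360.0 / abs(self.twist)

    @property
    def pitch(self) -> float:
        """Axial length of one full turn of the 1-start helix, Å."""
        return self.rise * self.subunits_per_turn


@dataclasses.dataclass(frozen=True)
class IdealHelixParams:
    """Parameters of the canonical α-helix (3.6 residues/turn, 1.5 Å rise)."""

    twist_per_res: float = 100.0  # degrees / residue, right-handed
    rise_per_res: float = 1.5     # Å / residue
    ca_radius: float = 2.27       # Å, CA distance from the helix axis
    phi: float = -57.0
    psi: float = -47.0
    omega: float = 180.0

    def __post_init__(self) -> None:
        if not 0 < self.twist_per_res < 180:
            raise ValueError("twist_per_res must lie in (0, 180)")
        if self.rise_per_res <= 0:
            raise ValueError("rise_per_res must be positive")


def helical_displacement(k: int, params: IdealHelixParams | None = None
                         ) -> tuple[float, float]:
    """Angular (degrees, wrapped) and axial (Å) offset between residues i, i+k.

    With the canonical helix parameters this gives the i,i+4 arrangement an
    angular displacement of +40° at 6.0 Å axial separation, and the i,i+3
    arrangement −60° at 4.5 Å — the geometry separating an RxxxR from an RxxR
    pair on one helix face.
    """
    params = params or IdealHelixParams()
    return (wrap_angle(k * params.twist_per_res), k * params.rise_per_res)


@dataclasses.dataclass(frozen=True)
class NStartFamily:
    """One family of lattice lines connecting every n-th subunit."""

    n: int
    axial_step: float         # Å, n * rise
    angular_step: float       # degrees, wrap(n * twist)
    handedness: str           # "right" | "left"
    chord: float              # Å, straight-line circumferential step at radius r
    inclination: float        # degrees from the filament axis, at radius r
    neighbor_distance: float  # Å, 3D distance between successive line subunits


def _family(n: int, sym: HelicalSymmetry, radius: float) -> NStartFamily:
    axial = n * sym.rise
    ang = wrap_angle(n * sym.twist)
    chord = 2.0 * radius * math.sin(abs(math.radians(ang)) / 2.0)
    arc = radius * abs(math.radians(ang))
    inclination = math.degrees(math.atan2(arc, axial))
    neighbor = math.hypot(axial, chord)
    return NStartFamily(n, axial, ang, "right" if ang > 0 else "left",
                        chord, inclination, neighbor)


def enumerate_nstart(sym: HelicalSymmetry, radius: float, n_max: int
                     ) -> list[NStartFamily]:
    """n-start families for n = 1..n_max at the given lattice radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    return [_family(n, sym, radius) for n in range(1, n_max + 1)]


def stacking_direction(sym: HelicalSymmetry, radius: float,
                       axial_cutoff: float = 15.0,
                       max_angular_step: float = 90.0) -> NStartFamily | None:
    """Identify the n-start family along which protofilaments stack axially.

    Among families whose axial step does not exceed ``axial_cutoff`` (default
    15 Å, roughly one cross-α helix diameter above the ~10 Å stacking
    spacing), the family with the smallest 3D neighbour distance at the given
    radius is selected, ties broken toward smaller n. The winner must advance
    less than ``max_angular_step`` degrees in azimuth per step — a scale-free
    axiality gate, so the assignment does not depend on the radius at which
    the lattice is drawn. Returns None when no family qualifies.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if axial_cutoff <= sym.rise:
        raise ValueError("axial_cutoff must exceed the rise")
    n_max = int(axial_cutoff // sym.rise)
    candidates = [f for f in enumerate_nstart(sym, radius, n_max)
                  if f.axial_step <= axial_cutoff]
    if not candidates:
        return None
    best = min(candidates, key=lambda f: (f.neighbor_distance, f.n))
    if abs(best.angular_step) >= max_angular_step:
        return None
    return best


@dataclasses.dataclass
class HelicalNet:
    """The filament surface lattice unrolled onto a plane.

    Each subunit k sits at axial position ``z = k*rise`` and unrolled abscissa
    ``x = r * theta_k`` (theta accumulated, rendered modulo the circumference
    2πr, viewed from outside the filament). Family line membership tags allow
    the n-start lines to be drawn through every n-th point.
    """

    radius: float
    points: pd.DataFrame  # columns: k, z, theta_deg, x, line_<n> per family

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)

    def plot(self, ax=None, families: list[int] | None = None):
        """Draw the net with matplotlib; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        circ = 2 * math.pi * self.radius
        ax.scatter(self.points["x"], self.points["z"], s=12, color="k", zorder=3)
        fam_cols = [c for c in self.points.columns if c.startswith("line_")]
        if families is not None:
            fam_cols = [f"line_{n}" for n in families if f"line_{n}" in fam_cols]
        for col in fam_cols:
            n = int(col.split("_")[1])
            for line_id, grp in self.points.groupby(col):
                grp = grp.sort_values("k")
                # break wrapped segments at the seam
                xs, zs = grp["x"].to_numpy(), grp["z"].to_numpy()
                for i in range(len(xs) - 1):
                    if abs(xs[i + 1] - xs[i]) < circ / 2:
                        ax.plot(xs[i:i + 2], zs[i:i + 2], lw=0.8,
                                label=f"{n}-start" if (line_id == 0 and i == 0) else None)
        ax.set_xlabel("circumferential arc length (Å)")
        ax.set_ylabel("axial rise (Å)")
        ax.set_xlim(0, circ)
        if fam_cols:
            ax.legend(loc="upper right", fontsize=8)
        return ax


def helical_net(sym: HelicalSymmetry, radius: float, n_subunits: int,
                families: list[int] | None = None) -> HelicalNet:
    """Unroll the surface lattice of n_subunits onto the plane."""
    if n_subunits < 2:
        raise ValueError("need at least 2 subunits for a net")
    if radius <= 0:
        raise ValueError("radius must be positive")
    families = families or []
    k = np.arange(n_subunits)
    theta = (k * sym.twist) % 360.0
    rows = {
        "k": k,
        "z": k * sym.rise,
        "theta_deg": theta,
        "x": radius * np.radians(theta),
    }
    for n in families:
        rows[f"line_{n}"] = k % n
    return HelicalNet(radius, pd.DataFrame(rows))


def _screw_parameters(rot: np.ndarray, trans: np.ndarray
                      ) -> tuple[float, float, np.ndarray]:
    """(rise, signed twist deg, axis unit vector with positive rise)."""
    from scipy.spatial.transform import Rotation

    rv = Rotation.from_matrix(rot).as_rotvec()
    angle = np.linalg.norm(rv)
    if angle < 1e-12:
        raise ValueError("subunit transform has no rotation component")
    axis = rv / angle
    d = float(np.dot(axis, trans))
    if d < 0:
        axis, angle, d = -axis, -angle, -d
    return d, math.degrees(angle), axis


def fit_symmetry(filament: Structure, chains_per_subunit: int = 1,
                 cyclic_order: int = 1, congruence_tol: float = 1.0
                 ) -> tuple[HelicalSymmetry, float]:
    """Recover (rise, twist) from a filament of congruent subunits.

    Chains are grouped ``chains_per_subunit`` at a time, in order, into
    subunits (for a Cn filament pass the full ring — n × asymmetric-unit
    chains — as one subunit). Consecutive subunits are superposed optimally;
    the screw parameters of each transform are averaged. Returns the fitted
    symmetry and the worst superposition residual (Å).

    Raises if fewer than 3 subunits are present or if any consecutive pair
    fails to superpose within ``congruence_tol`` Å.
    """
    chains = filament.chains
    if chains_per_subunit < 1 or len(chains) % chains_per_subunit:
        raise ValueError("chain count is not a multiple of chains_per_subunit")
    groups = [chains[i:i + chains_per_subunit]
              for i in range(0, len(chains), chains_per_subunit)]
    if len(groups) < 3:
        raise ValueError(f"need >= 3 consecutive subunits, got {len(groups)}")

    def group_coords(g):
        return np.concatenate([
            np.array([a.position for r in c.residues for a in r.atoms])
            for c in g])

    rises, twists, residuals = [], [], []
    axis_ref = None
    for ga, gb in zip(groups, groups[1:]):
        xa, xb = group_coords(ga), group_coords(gb)
        if xa.shape != xb.shape:
            raise ValueError("subunits have different atom counts")
        sup = superpose(xa, xb)
        residuals.append(sup.rmsd)
        if sup.rmsd > congruence_tol:
            raise ValueError(
                f"subunits not congruent: superposition residual "
                f"{sup.rmsd:.3f} Å exceeds {congruence_tol} Å")
        rise, twist, axis = _screw_parameters(sup.rotation, sup.translation)
        if axis_ref is None:
            axis_ref = axis
        elif np.dot(axis, axis_ref) < 0:
            raise ValueError("inconsistent screw axis orientation along filament")
        rises.append(rise)
        twists.append(twist)
    sym = HelicalSymmetry(float(np.mean(rises)), wrap_angle(float(np.mean(twists))),
                          cyclic_order)
    return sym, float(np.max(residuals))
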