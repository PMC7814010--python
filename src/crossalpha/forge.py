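"""Synthetic structure generators.

Everything downstream — lattice fitting, helix-pair geometry, interface
characterization and the motif-search pipeline — is exercised on structures
built here: ideal α-helices of a given sequence, filaments generated by
applying helical symmetry to an asymmetric unit, a cross-α nanotube fixture,
and decoy structure databases with a motif planted at a controlled
coordinate-jitter level.

CA atoms of an ideal helix are placed *parametrically* on a cylinder
(twist 100°/residue, rise 1.5 Å/residue, radius 2.27 Å by default), so the
i→i+k displacement arithmetic is exact by construction; N, C and O are then
attached from standard internal coordinates (bond lengths 1.46/1.53/1.33 Å,
angles 111/117/121°, dihedrals φ=−57°, ψ=−47°, ω=180°). Side chains are
reduced to CB plus a per-residue-type pseudo-centroid atom (``CEN``), enough
for knobs-into-holes and clasp-contact detection.

All generators are seed-deterministic.
"""

from __future__ import annotations

import dataclasses
import functools
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .helixgeom import fit_helix_axis, superpose
from .lattice import HelicalSymmetry, IdealHelixParams
from .structio import AA1_TO_3, Atom, Chain, Residue, Structure, write_structure

__all__ = [
    "IdealHelixParams",
    "JitterSpec",
    "DecoyDatabaseSpec",
    "build_ideal_helix",
    "generate_filament",
    "make_cross_alpha_filament",
    "jitter_structure",
    "make_decoy_database",
    "write_decoy_database",
]

#: Distance (Å) from CA to the side-chain centroid pseudo-atom, by residue.
_CENTROID_DIST = {
    "A": 1.53, "C": 2.05, "D": 2.47, "E": 3.00, "F": 3.41, "H": 3.15,
    "I": 2.31, "K": 3.53, "L": 2.60, "M": 2.95, "N": 2.47, "P": 1.87,
    "Q": 3.00, "R": 4.10, "S": 1.90, "T": 1.93, "V": 1.97, "W": 3.86,
    "Y": 3.80, "X": 2.50,
}

_CHAIN_ALPHABET = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                   "abcdefghijklmnopqrstuvwxyz0123456789")


def _chain_id(index: int) -> str:
    n = len(_CHAIN_ALPHABET)
    if index < n:
        return _CHAIN_ALPHABET[index]
    return _CHAIN_ALPHABET[index // n - 1] + _CHAIN_ALPHABET[index % n]


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom d from internal coordinates (a-b-c-d)."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(dih),
                        bond * math.sin(ang) * math.sin(dih)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal CB for an L-amino acid from its backbone N, CA, C."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def _nerf_backbone(params: IdealHelixParams, n_res: int) -> np.ndarray:
    """(n_res, 4, 3) N/CA/C/O backbone built purely from internal coordinates."""
    coords = np.zeros((n_res, 4, 3))
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.46, 0.0, 0.0])
    ang = math.radians(111.0)
    c0 = ca0 + 1.53 * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords[0, 0], coords[0, 1], coords[0, 2] = n0, ca0, c0
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2]
        ni = _place_atom(n_prev, ca_prev, c_prev, 1.33, 117.0, params.psi)
        cai = _place_atom(ca_prev, c_prev, ni, 1.46, 121.0, params.omega)
        ci = _place_atom(c_prev, ni, cai, 1.53, 111.0, params.phi)
        coords[i, 0], coords[i, 1], coords[i, 2] = ni, cai, ci
        coords[i - 1, 3] = _place_atom(ni, ca_prev, c_prev, 1.23, 121.0,
                                       params.psi + 180.0)
    # last carbonyl O: use the psi dihedral continued from a virtual next N
    virt_n = _place_atom(coords[-1, 0], coords[-1, 1], coords[-1, 2],
                         1.33, 117.0, params.psi)
    coords[-1, 3] = _place_atom(virt_n, coords[-1, 1], coords[-1, 2],
                                1.23, 121.0, params.psi + 180.0)
    return coords


@functools.lru_cache(maxsize=8)
def _frame_offsets(params: IdealHelixParams) -> dict[str, np.ndarray]:
    """Mean offsets of N, C, O, CB from CA in the local cylindrical frame.

    Derived once from a helix built with the parameter set's internal
    coordinates: the helix axis is fitted, and for interior residues each
    backbone atom's displacement from its CA is expressed in the
    (radial, tangential, axial) basis at that CA.
    """
    n_res = 31
    bb = _nerf_backbone(params, n_res)
    axis = fit_helix_axis(bb[:, 1, :])
    z = axis.direction
    offsets: dict[str, list[np.ndarray]] = {"N": [], "C": [], "O": [], "CB": []}
    for i in range(8, n_res - 8):
        ca = bb[i, 1]
        radial = ca - axis.point
        radial = radial - np.dot(radial, z) * z
        u = radial / np.linalg.norm(radial)
        t = np.cross(z, u)
        basis = np.stack([u, t, z])
        cb = _cb_position(bb[i, 0], ca, bb[i, 2])
        for name, pos in (("N", bb[i, 0]), ("C", bb[i, 2]),
                          ("O", bb[i, 3]), ("CB", cb)):
            offsets[name].append(basis @ (pos - ca))
    return {k: np.mean(v, axis=0) for k, v in offsets.items()}


def build_ideal_helix(sequence: str, params: IdealHelixParams | None = None,
                      chain_id: str = "A", start_seq_id: int = 1,
                      structure_id: str = "ideal-helix") -> Structure:
    """Build an ideal α-helix of the given sequence along the +z axis.

    CA of residue i (0-based) sits exactly at angle ``i * twist_per_res`` and
    height ``i * rise_per_res`` on a cylinder of radius ``ca_radius``; the
    helix is right-handed and runs N→C along +z.
    """
    params = params or IdealHelixParams()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in AA1_TO_3:
            raise ValueError(f"invalid amino-acid {aa!r} at position {pos}")
    off = _frame_offsets(params)
    residues = []
    for i, aa in enumerate(sequence):
        theta = math.radians(i * params.twist_per_res)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        t = np.array([-math.sin(theta), math.cos(theta), 0.0])
        z = np.array([0.0, 0.0, 1.0])
        basis = np.stack([u, t, z])  # rows
        ca = params.ca_radius * u + i * params.rise_per_res * z
        atoms = [Atom("N", "N", ca + off["N"] @ basis),
                 Atom("CA", "C", ca),
                 Atom("C", "C", ca + off["C"] @ basis),
                 Atom("O", "O", ca + off["O"] @ basis)]
        if aa != "G":
            cb = ca + off["CB"] @ basis
            atoms.append(Atom("CB", "C", cb))
            d = _CENTROID_DIST[aa]
            if d > 0:
                cen_dir = (cb - ca) / np.linalg.norm(cb - ca)
                atoms.append(Atom("CEN", "C", ca + d * cen_dir))
        residues.append(Residue(start_seq_id + i, aa, atoms))
    return Structure(structure_id, [Chain(chain_id, residues)])


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_filament(asym_unit: Structure, sym: HelicalSymmetry,
                      n_copies: int, structure_id: str | None = None) -> Structure:
    """Apply helical symmetry to an asymmetric unit (filament axis = +z).

    Copy k is the asymmetric unit rotated by ``k * twist`` about z (signed,
    right-handed) and translated by ``k * rise`` along +z; a cyclic order c
    additionally generates c rotated copies per subunit at 360/c spacing.
    Chain ids are uniquified in subunit-major order.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if not asym_unit.chains:
        raise ValueError("asymmetric unit is empty")
    chains: list[Chain] = []
    idx = 0
    for k in range(n_copies):
        for j in range(sym.cyclic_order):
            rot = _rot_z(k * sym.twist + j * 360.0 / sym.cyclic_order)
            trans = np.array([0.0, 0.0, k * sym.rise])
            copy = asym_unit.transformed(rot, trans)
            for c in copy.chains:
                chains.append(Chain(_chain_id(idx), c.residues))
                idx += 1
    meta = {"symmetry": {"rise": sym.rise, "twist": sym.twist,
                         "cyclic_order": sym.cyclic_order},
            "chains_per_subunit": len(asym_unit.chains) * sym.cyclic_order,
            "n_subunits": n_copies}
    return Structure(structure_id or f"{asym_unit.id}-filament", chains, meta)


def make_cross_alpha_filament(sequence: str, sym: HelicalSymmetry,
                              n_copies: int, radius: float,
                              tilt_deg: float = 0.0,
                              params: IdealHelixParams | None = None,
                              structure_id: str = "cross-alpha") -> Structure:
    """Compose a cross-α nanotube fixture.

    One ideal helix is placed with its axis perpendicular to the filament
    axis (tangential to the tube surface) at the given radius, tilted by
    ``tilt_deg`` about the local radial direction, and helical symmetry is
    then applied. The tilt is a free parameter of the fixture, not a claim
    about any particular assembly.
    """
    helix = build_ideal_helix(sequence, params, structure_id=structure_id)
    ca = helix.coords(("CA",))
    axis = fit_helix_axis(ca)
    center = ca.mean(axis=0)
    # move helix center to origin, axis to +y (tangential direction at (r,0,0))
    zhat = np.array([0.0, 0.0, 1.0])
    yhat = np.array([0.0, 1.0, 0.0])
    v = axis.direction
    rot_align = _rotation_between(v, yhat)
    helix = helix.transformed(rot_align, -rot_align @ center)
    # tilt about the radial (+x) direction, then push out to the tube radius
    ct, st = math.cos(math.radians(tilt_deg)), math.sin(math.radians(tilt_deg))
    rot_tilt = np.array([[1.0, 0.0, 0.0], [0.0, ct, -st], [0.0, st, ct]])
    helix = helix.transformed(rot_tilt, np.array([radius, 0.0, 0.0]))
    del zhat
    return generate_filament(helix, sym, n_copies, structure_id=structure_id)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


@dataclasses.dataclass(frozen=True)
class JitterSpec:
    """Isotropic per-coordinate Gaussian noise, Å."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def jitter_structure(s: Structure, spec: JitterSpec) -> Structure:
    """Perturb every coordinate with independent Gaussian noise (seeded)."""
    rng = np.random.default_rng(spec.seed)
    chains = []
    for c in s.chains:
        residues = []
        for r in c.residues:
            atoms = [Atom(a.name, a.element,
                          a.position + rng.normal(0.0, spec.sigma, 3))
                     for a in r.atoms]
            residues.append(Residue(r.seq_id, r.aa, atoms))
        chains.append(Chain(c.chain_id, residues))
    return Structure(s.id, chains, dict(s.meta))


@dataclasses.dataclass(frozen=True)
class DecoyDatabaseSpec:
    """Recipe for a decoy structure database with an optional planted motif."""

    n_structures: int
    chain_length_range: tuple[int, int] = (30, 60)
    planted_motif: object | None = None  # a motifsearch.MotifQuery
    plant_sigma: float = 0.0
    n_planted: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.plant_sigma < 0:
            raise ValueError("plant_sigma must be >= 0")
        if not 0 <= self.n_planted <= self.n_structures:
            raise ValueError("n_planted must lie in [0, n_structures]")


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_helix_structure(rng: np.random.Generator, sid: str,
                            length_range: tuple[int, int]) -> Structure:
    """A decoy: 1–3 ideal helices of random sequence in random poses."""
    n_chains = int(rng.integers(1, 4))
    chains = []
    for i in range(n_chains):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list(_AA20), size=length))
        h = build_ideal_helix(seq, chain_id=_chain_id(i))
        # random rigid pose: uniform rotation + translation in a 60 Å box
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(rng=rng).as_matrix()
        trans = rng.uniform(-30.0, 30.0, 3)
        chains.extend(h.transformed(rot, trans).chains)
    st = Structure(sid, chains)
    st.meta.update({"resolution": round(float(rng.uniform(1.2, 2.5)), 2),
                    "method": "synthetic", "planted": False})
    return st


def _plant_motif(host_rng: np.random.Generator, sid: str, motif,
                 sigma: float) -> Structure:
    """Build a structure embedding the (jittered) motif backbone.

    Each motif segment becomes one chain: an ideal helix carrying the segment
    sequence flanked by random residues is superposed onto the jittered
    segment backbone, and the window's N/CA/C/O atoms are then set to the
    target coordinates exactly. Planting locations go into ``meta['plant']``.
    """
    pad = 5
    chains = []
    locations = []
    for s_idx, seg in enumerate(motif.segments):
        target = np.array(seg.backbone, float)  # (L, 4, 3)
        if sigma > 0:
            target = target + host_rng.normal(0.0, sigma, target.shape)
        length = seg.length
        flank_l = "".join(host_rng.choice(list(_AA20), size=pad))
        flank_r = "".join(host_rng.choice(list(_AA20), size=pad))
        seq = flank_l + seg.sequence + flank_r
        h = build_ideal_helix(seq, chain_id=_chain_id(s_idx))
        host_bb = np.array(
            [[h.chains[0].residues[pad + i].atom(nm).position
              for nm in ("N", "CA", "C", "O")] for i in range(length)])
        sup = superpose(host_bb.reshape(-1, 3), target.reshape(-1, 3))
        h = h.transformed(sup.rotation, sup.translation)
        for i in range(length):
            res = h.chains[0].residues[pad + i]
            for j, nm in enumerate(("N", "CA", "C", "O")):
                res.atom(nm).position[:] = target[i, j]
        chains.extend(h.chains)
        locations.append({"segment": s_idx, "chain": _chain_id(s_idx),
                          "start": pad + 1, "length": length})
    st = Structure(sid, chains)
    st.meta.update({"resolution": 1.5, "method": "synthetic",
                    "planted": True, "plant": locations, "plant_sigma": sigma})
    return st


def make_decoy_database(spec: DecoyDatabaseSpec) -> list[Structure]:
    """Generate a seed-deterministic decoy database.

    When a motif is planted, ``n_planted`` structures (default one, at
    seed-chosen indices) contain its backbone independently perturbed at
    ``plant_sigma``; each location is recorded in that structure's ``meta``.
    """
    rng = np.random.default_rng(spec.seed)
    plant_indices: set[int] = set()
    if spec.planted_motif is not None and spec.n_planted:
        plant_indices = set(rng.choice(spec.n_structures, spec.n_planted,
                                       replace=False).tolist())
    out = []
    for i in range(spec.n_structures):
        sid = f"decoy{i:04d}"
        sub_rng = np.random.default_rng(rng.integers(2 ** 31))
        if i in plant_indices:
            out.append(_plant_motif(sub_rng, sid, spec.planted_motif,
                                    spec.plant_sigma))
        else:
            out.append(_random_helix_structure(sub_rng, sid,
                                               spec.chain_length_range))
    return out


def write_decoy_database(structures: list[Structure], directory: str | Path
                         ) -> Path:
    """Write decoys as PDB files plus a TSV manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for st in structures:
        path = directory / f"{st.id}.pdb"
        write_structure(st, path, "pdb")
        rows.append({
            "id": st.id,
            "path": path.name,
            "resolution": st.meta.get("resolution", ""),
            "method": st.meta.get("method", ""),
            "n_residues": st.n_residues,
            "n_chains": len(st.chains),
            "protein_fraction": 1.0,
            "planted": int(bool(st.meta.get("planted"))),
            "plant": repr(st.meta.get("plant", "")),
            "plant_sigma": st.meta.get("plant_sigma", ""),
        })
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
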