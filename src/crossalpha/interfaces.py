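"""Interface characterization for helix pairs and protofilament pairs.

Covers four things:

* solvent-accessible surface area (SASA) by Shrake–Rupley sphere sampling,
  with a fixed van-der-Waals radii table shipped as package data;
* buried area per peptide for two disjoint chain groups, using the symmetric
  ΔSASA/2 convention normalized by an explicitly chosen reporting group;
* knobs-into-holes (KIH) detection between two helices by the side-chain
  centroid criterion (a knob's centroid within a cutoff of ≥4 partner
  centroids) — a deliberate simplification of the full SOCKET algorithm with
  no packing-angle classification;
* arginine-clasp contact mapping: for each subunit of a symmetric filament,
  which symmetry neighbour's C-terminal residue engages the RxxxR (or RxxR)
  guanidinium groups, aggregated into a consensus lattice offset.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from collections import Counter

import numpy as np
from scipy.spatial import cKDTree

from .lattice import HelicalSymmetry
from .structio import Chain, Residue, Structure

__all__ = [
    "SASAResult",
    "KIHContact",
    "ClaspContact",
    "InterfaceReport",
    "vdw_radius",
    "sasa",
    "buried_area_per_peptide",
    "detect_kih",
    "find_clasp_contacts",
    "consensus_offset",
    "characterize_interface",
]

HEPTAD = "abcdefg"


def _load_radii() -> dict[str, float]:
    ref = importlib.resources.files("crossalpha") / "data" / "vdw_radii.json"
    return {k.upper(): float(v)
            for k, v in json.loads(ref.read_text())["radii"].items()}


_RADII = _load_radii()


def vdw_radius(element: str) -> float:
    try:
        return _RADII[element.upper()]
    except KeyError:
        raise KeyError(f"no van-der-Waals radius for element {element!r}") from None


@dataclasses.dataclass
class SASAResult:
    per_atom: np.ndarray   # Å² per heavy atom, in structure atom order
    probe_radius: float
    sample_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(s: Structure, probe: float = 1.4, n_points: int = 960) -> SASAResult:
    """Shrake–Rupley accessible surface area per heavy atom."""
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("need at least 100 sample points")
    atoms = [(a.position, a.element) for _, _, a in s.iter_atoms()]
    coords = np.array([p for p, _ in atoms])
    unknown = sorted({e for _, e in atoms if e.upper() not in _RADII})
    if unknown:
        raise KeyError(f"atoms with unknown element(s): {', '.join(unknown)}")
    radii = np.array([_RADII[e.upper()] for _, e in atoms]) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(len(coords))
    eps = 1e-9
    for i, (ci, ri) in enumerate(zip(coords, radii)):
        neighbors = [j for j in tree.query_ball_point(ci, ri + max_r)
                     if j != i
                     and np.linalg.norm(coords[j] - ci) < ri + radii[j] + eps]
        pts = ci + ri * unit
        if neighbors:
            nb = coords[neighbors]
            nr = radii[neighbors]
            lower = np.array(neighbors) < i
            d2 = np.sum((pts[:, None, :] - nb[None, :, :]) ** 2, axis=2)
            # strictly inside a neighbour occludes; exactly on a neighbour's
            # surface (coincident spheres) is broken by atom order so a
            # degenerate pair still totals one sphere's area
            inside = d2 < (nr ** 2)[None, :] - eps
            on_surface = (d2 <= (nr ** 2)[None, :] + eps) & lower[None, :]
            frac = np.mean(~np.any(inside | on_surface, axis=1))
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ri ** 2
    return SASAResult(areas, probe, n_points)


def _subset(s: Structure, chain_ids: set[str], sid: str) -> Structure:
    chains = [c for c in s.chains if c.chain_id in chain_ids]
    missing = chain_ids - {c.chain_id for c in chains}
    if missing:
        raise KeyError(f"chains not in structure: {sorted(missing)}")
    return Structure(sid, chains)


def buried_area_per_peptide(filament: Structure, group_a: set[str],
                            group_b: set[str], report_group: str = "a",
                            probe: float = 1.4, n_points: int = 960) -> float:
    """Interface area buried per peptide between two chain groups.

    Computed as ``(SASA(A) + SASA(B) − SASA(A∪B)) / 2`` divided by the number
    of peptide chains in the reporting group (``"a"`` or ``"b"``); which group
    normalizes the area is always explicit because conventions differ.
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("chain groups must be non-empty")
    if group_a & group_b:
        raise ValueError(f"chain groups overlap: {sorted(group_a & group_b)}")
    if report_group not in ("a", "b"):
        raise ValueError("report_group must be 'a' or 'b'")
    sa = sasa(_subset(filament, group_a, "A"), probe, n_points).total
    sb = sasa(_subset(filament, group_b, "B"), probe, n_points).total
    sab = sasa(_subset(filament, group_a | group_b, "AB"), probe, n_points).total
    buried = max(0.0, (sa + sb - sab) / 2.0)
    n_pep = len(group_a if report_group == "a" else group_b)
    return buried / n_pep


@dataclasses.dataclass
class KIHContact:
    knob: tuple[str, int]          # (chain_id, seq_id)
    holes: list[tuple[str, int]]   # >= 4 residues on the partner helix
    knob_face: str | None = None   # heptad letter when a register is provided
    centroid_distances: list[float] = dataclasses.field(default_factory=list)


def heptad_letter(seq_id: int, register: tuple[int, str]) -> str:
    """Heptad position of a residue given one anchored assignment."""
    ref_id, ref_letter = register
    return HEPTAD[(seq_id - ref_id + HEPTAD.index(ref_letter)) % 7]


def _centroids(chain: Chain) -> tuple[list[Residue], np.ndarray]:
    res = list(chain.residues)
    return res, np.array([r.sidechain_centroid() for r in res])


def detect_kih(s: Structure, helix_a: str, helix_b: str, cutoff: float = 7.0,
               register_a: tuple[int, str] | None = None) -> list[KIHContact]:
    """Knobs on helix_a packing into holes on helix_b (centroid criterion).

    A residue of A is a knob iff its side-chain centroid lies within
    ``cutoff`` of at least four side-chain centroids of B (glycine uses CA).
    The reciprocal direction is a separate call with the helices swapped.
    """
    ca_chain, cb_chain = s.chain(helix_a), s.chain(helix_b)
    if not ca_chain.residues or not cb_chain.residues:
        raise ValueError("empty helix selection")
    res_a, cen_a = _centroids(ca_chain)
    res_b, cen_b = _centroids(cb_chain)
    out = []
    for ra, ca in zip(res_a, cen_a):
        d = np.linalg.norm(cen_b - ca, axis=1)
        idx = np.nonzero(d <= cutoff)[0]
        if len(idx) >= 4:
            order = idx[np.argsort(d[idx])]
            face = heptad_letter(ra.seq_id, register_a) if register_a else None
            out.append(KIHContact(
                knob=(helix_a, ra.seq_id),
                holes=[(helix_b, res_b[j].seq_id) for j in order],
                knob_face=face,
                centroid_distances=[float(d[j]) for j in order]))
    return out


@dataclasses.dataclass
class ClaspContact:
    arg_pair: tuple[tuple[str, int], tuple[str, int]]  # (chain, seq_id) x2
    partner_terminus: tuple[str, int]
    lattice_offset: int
    min_heavy_atom_distance: float


_GUANIDINIUM = ("NE", "CZ", "NH1", "NH2")


def _arg_probe_atoms(res: Residue) -> np.ndarray:
    """Guanidinium atoms when present, else the reduced side-chain proxy."""
    pts = [a.position for a in res.atoms if a.name in _GUANIDINIUM]
    if not pts:
        pts = [res.sidechain_centroid()]
    return np.array(pts)


def find_clasp_contacts(filament: Structure, arg_positions: tuple[int, int],
                        sym: HelicalSymmetry | None = None,
                        distance_cutoff: float = 4.0,
                        chains_per_subunit: int = 1,
                        max_offset: int = 8) -> list[ClaspContact]:
    """Map which symmetry neighbour's C-terminus engages each subunit's clasp.

    For every subunit, heavy atoms of the C-terminal residue of neighbouring
    subunits (offsets ±1..±max_offset) are tested against the guanidinium
    atoms of the two clasp arginines; the closest neighbour within
    ``distance_cutoff`` is reported. An empty list means no clasp geometry.
    """
    chains = filament.chains
    if chains_per_subunit < 1 or len(chains) % chains_per_subunit:
        raise ValueError("chain count is not a multiple of chains_per_subunit")
    subunits = [chains[i:i + chains_per_subunit]
                for i in range(0, len(chains), chains_per_subunit)]
    if len(subunits) < 2:
        raise ValueError("filament must contain at least 2 subunits")
    i1, i2 = arg_positions
    contacts: list[ClaspContact] = []
    for si, sub in enumerate(subunits):
        arg_res = []
        for c in sub:
            for sid in (i1, i2):
                try:
                    arg_res.append((c.chain_id, c.residue(sid)))
                except KeyError:
                    pass
        if len(arg_res) < 2:
            raise ValueError(f"arginine positions {arg_positions} not found "
                             f"in subunit {si}")
        probe = np.concatenate([_arg_probe_atoms(r) for _, r in arg_res])
        best: ClaspContact | None = None
        for off in range(-max_offset, max_offset + 1):
            sj = si + off
            if off == 0 or not 0 <= sj < len(subunits):
                continue
            for c in subunits[sj]:
                cterm = c.residues[-1]
                heavy = np.array([a.position for a in cterm.atoms])
                d = float(np.min(np.linalg.norm(
                    probe[:, None, :] - heavy[None, :, :], axis=2)))
                if d <= distance_cutoff and (best is None
                                             or d < best.min_heavy_atom_distance):
                    best = ClaspContact(
                        arg_pair=((arg_res[0][0], i1), (arg_res[1][0], i2)),
                        partner_terminus=(c.chain_id, cterm.seq_id),
                        lattice_offset=off,
                        min_heavy_atom_distance=d)
        if best is not None:
            contacts.append(best)
    return contacts


def consensus_offset(contacts: list[ClaspContact]) -> int | None:
    """Most common lattice offset among clasp contacts (None if empty)."""
    if not contacts:
        return None
    return Counter(c.lattice_offset for c in contacts).most_common(1)[0][0]


@dataclasses.dataclass
class InterfaceReport:
    buried_area_per_peptide: float
    contact_pairs: list[tuple[tuple[str, int], tuple[str, int], float]]
    kih: list[KIHContact]
    clasps: list[ClaspContact]

    def to_dict(self) -> dict:
        return {
            "buried_area_per_peptide": self.buried_area_per_peptide,
            "contact_pairs": [
                {"a": list(a), "b": list(b), "min_distance": d}
                for a, b, d in self.contact_pairs],
            "kih": [{"knob": list(k.knob), "holes": [list(h) for h in k.holes],
                     "knob_face": k.knob_face} for k in self.kih],
            "clasps": [{"arg_pair": [list(p) for p in c.arg_pair],
                        "partner_terminus": list(c.partner_terminus),
                        "lattice_offset": c.lattice_offset,
                        "min_heavy_atom_distance": c.min_heavy_atom_distance}
                       for c in self.clasps],
        }


def characterize_interface(filament: Structure, group_a: set[str],
                           group_b: set[str], contact_cutoff: float = 4.0,
                           kih_cutoff: float = 7.0, probe: float = 1.4,
                           n_points: int = 960,
                           clasp: tuple[tuple[int, int], int] | None = None
                           ) -> InterfaceReport:
    """One-stop interface report between two chain groups.

    ``clasp``, when given, is ``(arg_positions, chains_per_subunit)`` and adds
    clasp-contact mapping over the whole filament.
    """
    area = buried_area_per_peptide(filament, group_a, group_b, "a",
                                   probe, n_points)
    # residue-residue heavy-atom contacts across the interface
    pairs = []
    for ca in (filament.chain(cid) for cid in sorted(group_a)):
        for ra in ca.residues:
            pa = np.array([a.position for a in ra.atoms])
            for cb in (filament.chain(cid) for cid in sorted(group_b)):
                for rb in cb.residues:
                    pb = np.array([a.position for a in rb.atoms])
                    d = float(np.min(np.linalg.norm(
                        pa[:, None, :] - pb[None, :, :], axis=2)))
                    if d <= contact_cutoff:
                        pairs.append(((ca.chain_id, ra.seq_id),
                                      (cb.chain_id, rb.seq_id), d))
    kih = []
    for cid_a in sorted(group_a):
        for cid_b in sorted(group_b):
            kih.extend(detect_kih(filament, cid_a, cid_b, kih_cutoff))
    clasps = []
    if clasp is not None:
        arg_positions, cps = clasp
        clasps = find_clasp_contacts(filament, arg_positions,
                                     chains_per_subunit=cps)
    return InterfaceReport(area, pairs, kih, clasps)
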