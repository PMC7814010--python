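"""Shared synthetic fixtures.

All structures are generated at test time; nothing is downloaded or stored.
"""

import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from crossalpha.forge import _rot_z, build_ideal_helix, generate_filament
from crossalpha.lattice import HelicalSymmetry
from crossalpha.structio import Chain, Structure

# the two computationally designed 36-residue sequences (string fixtures)
SEQ_RR = "TLEELRAEARILEAKAEILKAKAEVLKAKAEILKAQ"
SEQ_LL = "TLEELLAEALILKAKAEILKAKAEVLKAKAEILKAL"

FORM2_SYM = HelicalSymmetry(1.93, 124.4)       # double-walled, 3 protofilaments
SYM_36_31_3 = HelicalSymmetry(2.51, 124.0)
SYM_36_31_3_RR = HelicalSymmetry(2.49, 124.5)


def rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


@pytest.fixture(scope="session")
def ideal_helix():
    return build_ideal_helix(SEQ_RR)


def tangential_helix(sequence: str, phase_deg: float, radius: float,
                     y_shift: float = 0.0) -> Structure:
    """An ideal helix rotated ``phase_deg`` about its own axis, then laid
    tangentially (axis along +y) at ``(radius, y_shift, 0)``."""
    h = build_ideal_helix(sequence)
    cen = h.coords(("CA",)).mean(axis=0)
    t = h.transformed(_rot_z(phase_deg), -_rot_z(phase_deg) @ cen)
    return t.transformed(rot_x(-90), np.array([radius, y_shift, 0.0]))


@pytest.fixture(scope="session")
def clasp_filament():
    """Square-cross-section ring of tangential helices in which the C-terminal
    tip of subunit k+1 docks onto the RxxxR (R6/R10) side of subunit k —
    consensus lattice offset +1 by construction."""
    asym = tangential_helix(SEQ_RR, 225.0, 24.0)
    return generate_filament(asym, HelicalSymmetry(1.5, -90.0), 6,
                             structure_id="clasp-ring")


@pytest.fixture(scope="session")
def clasp_motif(clasp_filament):
    """Two-segment query: the 7-residue RxxxR fragment of one helix plus the
    5-residue C-terminal fragment of the laterally docked neighbour."""
    from crossalpha.motifsearch import define_motif

    a = clasp_filament.chains[0].chain_id
    b = clasp_filament.chains[1].chain_id
    return define_motif(clasp_filament, [(a, 6, 7), (b, 32, 5)])


@pytest.fixture(scope="session")
def control_motif(clasp_filament):
    """Same-size control: the 7-residue fragment plus a 5-residue fragment of
    the *same* helix one turn up (axial-stacking-like context)."""
    from crossalpha.motifsearch import define_motif

    a = clasp_filament.chains[0].chain_id
    return define_motif(clasp_filament, [(a, 6, 7), (a, 17, 5)])


def heptad_sequence(pattern: dict, length: int, default: str = "A") -> str:
    """Sequence with ``pattern`` letters at given heptad positions (a=0)."""
    return "".join(pattern.get(i % 7, default) for i in range(length))


@pytest.fixture(scope="session")
def coiled_coil_dimer():
    """Parallel two-helix coiled coil with the a/d faces of both helices
    rotated to oppose each other across the interface."""
    seq = heptad_sequence({0: "L", 3: "L"}, 28)
    h = build_ideal_helix(seq)
    a = h.transformed(_rot_z(-300), np.zeros(3))
    b = h.transformed(_rot_z(180 - 300), np.array([9.8, 0.0, 0.0]))
    return Structure("cc-dimer", [Chain("A", a.chains[0].residues),
                                  Chain("B", b.chains[0].residues)])


def _face_mean_z(chain, letters: str) -> float:
    from crossalpha.interfaces import heptad_letter

    vals = [(r.sidechain_centroid() - r.atom("CA").position)[2]
            for r in chain.residues
            if heptad_letter(r.seq_id, (1, "a")) in letters]
    return float(np.mean(vals))


@pytest.fixture(scope="session")
def stacked_pair():
    """Two parallel tangential helices stacked axially, built to the cross-α
    register: the lower helix's a/d face packs up against the upper helix's
    c/f face."""
    seq = heptad_sequence({0: "I", 3: "L"}, 28)

    def placed(phase, z):
        s = tangential_helix(seq, phase, 0.0)
        return s.transformed(np.eye(3), np.array([0.0, 0.0, z]))

    phase_ad = max(range(0, 360, 5),
                   key=lambda p: _face_mean_z(placed(p, 0).chains[0], "ad"))
    phase_cf = min(range(0, 360, 5),
                   key=lambda p: _face_mean_z(placed(p, 0).chains[0], "cf"))
    lower = placed(phase_ad, 0.0)
    upper = placed(phase_cf, 9.5)
    upper = upper.transformed(np.eye(3), np.array([0.0, 1.5, 0.0]))
    return Structure("stack-pair", [Chain("A", lower.chains[0].residues),
                                    Chain("B", upper.chains[0].residues)])
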