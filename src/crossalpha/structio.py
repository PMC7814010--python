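"""Atomic-structure I/O and the coordinate data model.

The package works on small peptide assemblies (single helices, protofilaments,
whole nanotube filaments), so the model is deliberately lightweight: plain
dataclasses holding numpy coordinates, with gemmi doing the heavy lifting for
PDB and mmCIF syntax.

Conventions
-----------
* Residue numbering is 1-based author numbering; insertion codes are rejected.
* Only polymer amino-acid residues are read; waters, ligands and hydrogens are
  skipped.
* Alternate conformations: the first altloc encountered per atom name wins.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ParseError",
    "parse_structure",
    "write_structure",
    "extract_sequence",
    "write_fasta",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA1_TO_3["X"] = "UNK"

#: Maximum atom count representable in fixed-width PDB serial numbers.
PDB_MAX_ATOMS = 99_999


class ParseError(ValueError):
    """Raised for syntactically or semantically unusable structure files."""


@dataclasses.dataclass
class Atom:
    """A heavy atom: label (e.g. ``CA``), element symbol, position in Å."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclasses.dataclass
class Residue:
    seq_id: int
    aa: str
    atoms: list[Atom] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.aa not in AA1_TO_3:
            raise ValueError(f"unknown one-letter amino-acid code {self.aa!r}")

    @property
    def name3(self) -> str:
        return AA1_TO_3[self.aa]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name3}{self.seq_id} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def sidechain_centroid(self) -> np.ndarray:
        """Centroid of side-chain heavy atoms; CA for glycine.

        Falls back through CB and CA when no further side-chain atoms exist, so
        it is well defined both for full-atom models and for the reduced
        CB+pseudo-centroid representation used by the synthetic generators.
        """
        side = [a.position for a in self.atoms
                if a.name not in ("N", "CA", "C", "O", "OXT")
                and not a.element.upper().startswith("H")]
        if side:
            return np.mean(side, axis=0)
        return self.atom("CA").position


@dataclasses.dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.seq_id for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError(f"chain {self.chain_id}: seq_id not strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, seq_id: int) -> Residue:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        raise KeyError(f"chain {self.chain_id} has no residue {seq_id}")

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclasses.dataclass
class Structure:
    id: str
    chains: list[Chain] = dataclasses.field(default_factory=list)
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"structure {self.id}: duplicate chain ids {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"structure {self.id} has no chain {chain_id!r}")

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def coords(self, atom_names: tuple[str, ...] | None = None) -> np.ndarray:
        """All coordinates, optionally restricted to the named atom labels."""
        pts = [a.position for _, _, a in self.iter_atoms()
               if atom_names is None or a.name in atom_names]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A rigid-motion copy: x -> R @ x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        new_chains = []
        for c in self.chains:
            residues = [
                Residue(r.seq_id, r.aa,
                        [Atom(a.name, a.element, rotation @ a.position + translation)
                         for a in r.atoms])
                for r in c.residues
            ]
            new_chains.append(Chain(c.chain_id, residues))
        return Structure(self.id, new_chains, dict(self.meta))


def _one_letter(resname: str) -> str | None:
    """One-letter code for an amino-acid residue name, else None."""
    if resname in AA3_TO_1:
        return AA3_TO_1[resname]
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code in AA1_TO_3 else "X"
    return None


def parse_structure(path: str | Path, format: str | None = None,
                    biounit: int | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path : file path.
    format : ``"pdb"`` or ``"mmcif"``; inferred from the suffix when None.
    biounit : optional 1-based index of the biological assembly to expand
        (mmCIF only); never applied implicitly.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such structure file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = "mmcif" if suffix in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown structure format {format!r} (use 'pdb' or 'mmcif')")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise ParseError(f"{path}: no atomic coordinates found")
    st.setup_entities()
    if biounit is not None:
        if biounit < 1 or biounit > len(st.assemblies):
            raise ValueError(
                f"{path}: biounit {biounit} not present "
                f"({len(st.assemblies)} assemblies)")
        how = gemmi.HowToNameCopiedChain.AddNumber
        st.transform_to_assembly(st.assemblies[biounit - 1].name, how)

    model = st[0]
    chains: list[Chain] = []
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            aa = _one_letter(gres.name)
            if aa is None or gres.is_water():
                continue  # hetero/solvent skipped
            if str(gres.seqid.icode).strip():
                raise ParseError(
                    f"{path}: insertion code {gres.seqid.icode!r} at "
                    f"{gch.name}/{gres.name}{gres.seqid.num} is not supported")
            seen: set[str] = set()
            atoms: list[Atom] = []
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                if ga.name in seen:
                    continue  # first altloc wins
                seen.add(ga.name)
                atoms.append(Atom(ga.name, ga.element.name,
                                  np.array([ga.pos.x, ga.pos.y, ga.pos.z])))
            if atoms:
                residues.append(Residue(gres.seqid.num, aa, atoms))
        if residues:
            chains.append(Chain(gch.name, residues))
    if not chains:
        raise ParseError(f"{path}: no polymer amino-acid residues found")

    meta: dict = {}
    if st.resolution and st.resolution > 0:
        meta["resolution"] = float(st.resolution)
    if "_exptl.method" in st.info:
        meta["method"] = st.info["_exptl.method"]
    if biounit is not None:
        meta["biounit"] = biounit
    return Structure(st.name or path.stem, chains, meta)


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    serial = 1
    for c in s.chains:
        gch = gemmi.Chain(c.chain_id)
        for r in c.residues:
            gres = gemmi.Residue()
            gres.name = r.name3
            gres.seqid = gemmi.SeqId(r.seq_id, " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.occ = 1.0
                ga.serial = serial
                serial += 1
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | Path, format: str | None = None) -> None:
    """Write a :class:`Structure` as PDB (fixed width) or mmCIF."""
    path = Path(path)
    if not s.chains:
        raise ValueError("cannot write an empty structure")
    if format is None:
        suffix = path.suffix.lower()
        format = "mmcif" if suffix in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown structure format {format!r}")
    if format == "pdb":
        if s.n_atoms > PDB_MAX_ATOMS:
            raise ValueError(
                f"{s.n_atoms} atoms exceed the PDB serial-number limit "
                f"({PDB_MAX_ATOMS}); write mmCIF instead")
        if any(len(c.chain_id) > 1 for c in s.chains):
            raise ValueError("PDB format requires single-character chain ids; "
                             "write mmCIF instead")
    st = _to_gemmi(s)
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def extract_sequence(s: Structure) -> dict[str, str]:
    """Per-chain one-letter sequences, in chain order."""
    if not s.chains or any(len(c) == 0 for c in s.chains):
        raise ValueError("structure has an empty chain")
    return {c.chain_id: c.sequence for c in s.chains}


def write_fasta(s: Structure, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, seq in extract_sequence(s).items():
            fh.write(f">{s.id}_{cid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
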