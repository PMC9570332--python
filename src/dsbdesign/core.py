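"""Core containers for structures, sequences and atom addressing.

A :class:`Structure` is a light hierarchical container (chains -> residues ->
atoms) holding Cartesian coordinates in Angstrom.  It deliberately stays close
to the PDB data model: author residue numbering with insertion codes, HETATM
groups retained but flagged, one coordinate set per structure (ensembles are a
separate container, see :mod:`dsbdesign.ensemble`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ProteinSequence",
    "AtomSpec",
    "ResidueRef",
    "THREE_TO_ONE",
]

#: 3-letter -> 1-letter mapping for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    """A single atom: name, element, coordinate (Angstrom), occupancy, B."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    bfactor_in: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coordinate must be a finite 3-vector")


@dataclass
class Residue:
    """One residue group; ``is_hetatm`` flags non-polymer (HETATM) groups."""

    name: str
    resseq: int
    icode: str = ""
    atoms: dict[str, Atom] = field(default_factory=dict)
    is_hetatm: bool = False

    @property
    def key(self) -> tuple[int, str]:
        return (self.resseq, self.icode)

    def add_atom(self, atom: Atom) -> None:
        if atom.name in self.atoms:
            raise ValueError(
                f"duplicate atom {atom.name!r} in residue {self.name} {self.resseq}{self.icode}"
            )
        self.atoms[atom.name] = atom

    def get(self, atom_name: str) -> Optional[Atom]:
        return self.atoms.get(atom_name)

    def coord(self, atom_name: str) -> np.ndarray:
        atom = self.atoms.get(atom_name)
        if atom is None:
            raise KeyError(
                f"residue {self.name} {self.resseq}{self.icode} has no atom {atom_name!r}"
            )
        return atom.coord

    def has_backbone(self) -> bool:
        return all(n in self.atoms for n in ("N", "CA", "C"))


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def add_residue(self, residue: Residue) -> None:
        if any(r.key == residue.key for r in self.residues):
            raise ValueError(
                f"duplicate residue {residue.resseq}{residue.icode} in chain {self.chain_id}"
            )
        self.residues.append(residue)

    def find_residue(self, resseq: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.resseq == resseq and r.icode == icode:
                return r
        return None

    def polymer(self) -> list[Residue]:
        """Polymer (non-HETATM) residues in order."""
        return [r for r in self.residues if not r.is_hetatm]

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates of polymer residues that have a CA atom, (n, 3)."""
        coords = [r.atoms["CA"].coord for r in self.polymer() if "CA" in r.atoms]
        return np.array(coords, dtype=float).reshape(-1, 3)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "pdb"

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def add_chain(self, chain: Chain) -> None:
        if chain.chain_id in self.chain_ids:
            raise ValueError(f"duplicate chain id {chain.chain_id!r}")
        self.chains.append(chain)

    def __getitem__(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def __contains__(self, chain_id: str) -> bool:
        return chain_id in self.chain_ids

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c)

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c:
                for a in r.atoms.values():
                    yield c, r, a

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every coordinate mapped to R @ x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = Structure(self.id, [], self.source_format)
        for c in self.chains:
            nc = Chain(c.chain_id)
            for r in c:
                nr = Residue(r.name, r.resseq, r.icode, {}, r.is_hetatm)
                for a in r.atoms.values():
                    nr.add_atom(Atom(a.name, a.element, rotation @ a.coord + translation,
                                     a.occupancy, a.bfactor_in))
                nc.add_residue(nr)
            out.add_chain(nc)
        return out


@dataclass
class ProteinSequence:
    """A protein sequence in 1-letter code (20 standard residues + 'X')."""

    id: str
    residues: str

    _ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

    def __post_init__(self) -> None:
        bad = set(self.residues) - self._ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id!r}: invalid residue codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class AtomSpec:
    """Address of a single atom: chain, residue number, insertion code, atom name.

    Must resolve to exactly one atom in a given topology (``resolve`` raises
    otherwise).  The string form is ``chain:resseq[icode]:atom``, e.g.
    ``A:98:OE1``.
    """

    chain_id: str
    resseq: int
    icode: str = ""
    atom_name: str = ""

    @classmethod
    def parse(cls, text: str) -> "AtomSpec":
        parts = text.strip().split(":")
        if len(parts) != 3:
            raise ValueError(f"atom spec {text!r}: expected 'chain:resseq[icode]:atom'")
        chain_id, res, atom_name = parts
        res = res.strip()
        icode = ""
        if res and res[-1].isalpha():
            res, icode = res[:-1], res[-1]
        return cls(chain_id.strip(), int(res), icode, atom_name.strip())

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.resseq}{self.icode}:{self.atom_name}"

    def resolve(self, structure: Structure) -> Atom:
        if self.chain_id not in structure:
            raise KeyError(f"atom spec {self}: chain {self.chain_id!r} not found")
        residue = structure[self.chain_id].find_residue(self.resseq, self.icode)
        if residue is None:
            raise KeyError(f"atom spec {self}: residue {self.resseq}{self.icode} not found")
        atom = residue.get(self.atom_name)
        if atom is None:
            raise KeyError(f"atom spec {self}: atom {self.atom_name!r} not found")
        return atom


@dataclass(frozen=True)
class ResidueRef:
    """Address of a residue within a structure."""

    chain_id: str
    resseq: int
    icode: str = ""
    name: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.name}{self.resseq}{self.icode}"

    def lookup(self, structure: Structure) -> Residue:
        residue = structure[self.chain_id].find_residue(self.resseq, self.icode)
        if residue is None:
            raise KeyError(f"residue {self} not found")
        return residue
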