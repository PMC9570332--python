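"""Structure and ensemble I/O, sequence extraction and global identity.

Reading goes through gemmi (robust PDB parsing, altloc bookkeeping); writing
uses an in-package fixed-width PDB record writer so ATOM/HETATM/MODEL records
reflect the containers exactly.  Sequences travel as FASTA via Biopython, and
pairwise global identity uses a Needleman-Wunsch alignment (BLOSUM62, gap
open 10, extend 0.5) with identity counted over gap-free aligned columns --
the convention under which structure-template identity is normally quoted.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .core import THREE_TO_ONE, Atom, Chain, ProteinSequence, Residue, Structure
from .ensemble import Ensemble

__all__ = [
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "extract_sequence",
    "global_identity",
    "read_fasta",
    "write_fasta",
]

#: default mapping for non-standard polymer residues in sequence extraction
DEFAULT_NONSTANDARD_MAP: Mapping[str, str] = {"MSE": "M"}


def _convert_residue(gres: "gemmi.Residue") -> Residue:
    """Convert a gemmi residue, resolving altlocs to highest occupancy
    (ties broken by file order, which gemmi preserves)."""
    res = Residue(
        name=gres.name.strip(),
        resseq=gres.seqid.num,
        icode=gres.seqid.icode.strip(),
        is_hetatm=(gres.het_flag == "H"),
    )
    best: dict[str, "gemmi.Atom"] = {}
    for ga in gres:
        prev = best.get(ga.name)
        if prev is None or ga.occ > prev.occ:
            best[ga.name] = ga
    for ga in gres:  # preserve file order of atoms
        if best.get(ga.name) is not ga:
            continue
        res.add_atom(Atom(
            name=ga.name,
            element=ga.element.name,
            coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
            occupancy=float(ga.occ),
            bfactor_in=float(ga.b_iso),
        ))
        del best[ga.name]
    return res


def _convert_model(gmodel: "gemmi.Model", struct_id: str) -> Structure:
    structure = Structure(id=struct_id, source_format="pdb")
    for gchain in gmodel:
        chain = Chain(gchain.name)
        for gres in gchain:
            chain.add_residue(_convert_residue(gres))
        structure.add_chain(chain)
    return structure


def read_structure(path: str | os.PathLike, model_index: int = 1) -> Structure:
    """Read one MODEL of a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path : path to a PDB file.
    model_index : 1-based index into the file's MODEL records (a file without
        MODEL records counts as one model).

    Alternate locations are resolved to the highest-occupancy conformer
    (ties -> first in file order); HETATM residues are retained and flagged.
    """
    if model_index < 1:
        raise ValueError(f"model_index must be >= 1, got {model_index}")
    st = gemmi.read_structure(os.fspath(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    if model_index > len(st):
        raise ValueError(f"{path}: model {model_index} absent (file has {len(st)} models)")
    structure = _convert_model(st[model_index - 1], st.name or os.path.basename(os.fspath(path)))
    n_poly = sum(len(r.atoms) for c in structure for r in c if not r.is_hetatm)
    if n_poly == 0:
        raise ValueError(f"{path}: structure contains zero protein (polymer) atoms")
    return structure


def read_ensemble(path: str | os.PathLike) -> Ensemble:
    """Read a multi-model PDB file as a conformational :class:`Ensemble`.

    Every MODEL must carry an identical atom roster in identical order;
    a mismatch raises naming the first differing atom.
    """
    st = gemmi.read_structure(os.fspath(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    frames = [_convert_model(m, st.name or "ensemble") for m in st]
    topology = frames[0]
    roster = [(c.chain_id, r.resseq, r.icode, a.name)
              for c, r, a in topology.iter_atoms()]
    coords = np.empty((len(frames), len(roster), 3))
    for f, frame in enumerate(frames):
        frame_roster = [(c.chain_id, r.resseq, r.icode, a.name)
                        for c, r, a in frame.iter_atoms()]
        if frame_roster != roster:
            for k, (want, got) in enumerate(zip(roster, frame_roster)):
                if want != got:
                    raise ValueError(
                        f"{path}: model {f + 1} atom roster mismatch at atom {k + 1}: "
                        f"expected {want}, found {got}")
            raise ValueError(
                f"{path}: model {f + 1} has {len(frame_roster)} atoms, expected {len(roster)}")
        coords[f] = np.array([a.coord for _, _, a in frame.iter_atoms()])
    return Ensemble(topology=topology, frames=coords)


# ---------------------------------------------------------------------------
# PDB writing

def _format_atom_line(record: str, serial: int, atom: Atom, res: Residue,
                      chain_id: str) -> str:
    name = atom.name
    # standard PDB alignment: 1-2 char element names start in column 14
    if len(name) < 4 and len(atom.element) < 2:
        name = " " + name
    return (
        f"{record:<6}{serial:>5} {name:<4}{'':1}{res.name:>3} {chain_id:1}"
        f"{res.resseq:>4}{res.icode or ' ':1}   "
        f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
        f"{atom.occupancy:6.2f}{atom.bfactor_in:6.2f}          {atom.element:>2}"
    )


def _structure_lines(structure: Structure, serial_start: int = 1) -> list[str]:
    lines: list[str] = []
    serial = serial_start
    for chain in structure:
        last_polymer = None
        for res in chain:
            record = "HETATM" if res.is_hetatm else "ATOM"
            for atom in res.atoms.values():
                lines.append(_format_atom_line(record, serial, atom, res, chain.chain_id))
                serial += 1
            if not res.is_hetatm:
                last_polymer = res
        if last_polymer is not None:
            lines.append(
                f"{'TER':<6}{serial:>5}      {last_polymer.name:>3} {chain.chain_id:1}"
                f"{last_polymer.resseq:>4}{last_polymer.icode or ' ':1}")
            serial += 1
    return lines


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a single-model PDB file."""
    lines = _structure_lines(structure)
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_ensemble(ensemble: Ensemble, path: str | os.PathLike) -> None:
    """Write an :class:`Ensemble` as a multi-model PDB file."""
    lines: list[str] = []
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL {f + 1:>8}")
        lines.extend(_structure_lines(ensemble.frame_structure(f)))
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sequences

def extract_sequence(structure: Structure, chain_id: str,
                     nonstandard_map: Mapping[str, str] = DEFAULT_NONSTANDARD_MAP,
                     ) -> ProteinSequence:
    """1-letter sequence of the polymer residues of a chain, in order.

    HETATM groups (ligands, waters) are excluded.  Non-standard polymer
    residues map through `nonstandard_map` (default: MSE -> M), anything
    still unknown becomes 'X'.
    """
    chain = structure[chain_id]  # KeyError on unknown chain
    letters = []
    for res in chain.polymer():
        one = THREE_TO_ONE.get(res.name) or nonstandard_map.get(res.name, "X")
        letters.append(one)
    return ProteinSequence(id=f"{structure.id}_{chain_id}", residues="".join(letters))


def global_identity(seq_a: ProteinSequence | str, seq_b: ProteinSequence | str) -> float:
    """Percent identity from a Needleman-Wunsch global alignment.

    Scoring: BLOSUM62, gap open 10, gap extend 0.5.  Identity is the number of
    identical aligned pairs over the number of gap-free aligned columns, x100.
    """
    a = str(seq_a)
    b = str(seq_b)
    if not a or not b:
        raise ValueError("global_identity: sequences must be non-empty")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(a, b)[0]
    identical = 0
    aligned_cols = 0
    for (s1, e1), (s2, e2) in zip(*alignment.aligned):
        aligned_cols += e1 - s1
        identical += sum(a[i] == b[j] for i, j in zip(range(s1, e1), range(s2, e2)))
    if aligned_cols == 0:
        return 0.0
    return 100.0 * identical / aligned_cols


def read_fasta(path: str | os.PathLike) -> list[ProteinSequence]:
    return [ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
            for rec in SeqIO.parse(os.fspath(path), "fasta")]


def write_fasta(sequences: Sequence[ProteinSequence], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i:i + 60] + "\n")
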