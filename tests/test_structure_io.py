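"""PDB reading/writing, altloc resolution, sequence extraction and global
identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsbdesign.structure_io import (extract_sequence, global_identity,
                                    read_ensemble, read_structure,
                                    write_ensemble, write_structure)


def _atom_line(serial, name, resname, chain, resseq, x, y, z, occ=1.0,
               record="ATOM", altloc=" ", element=None):
    element = element or name[0]
    nm = f" {name:<3}" if len(name) < 4 else name
    return (f"{record:<6}{serial:>5} {nm}{altloc}{resname:>3} {chain}"
            f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2}")


def _toy_pdb(tmp_path, name="toy.pdb"):
    lines = []
    serial = 1
    for ci, chain in enumerate("AB"):
        for ri in range(4):
            resname = ["ALA", "GLY", "SER", "VAL"][ri]
            for ai, atom in enumerate(["N", "CA", "C"]):
                lines.append(_atom_line(serial, atom, resname, chain, ri + 1,
                                        10.0 * ci + ri, float(ai), 1.0))
                serial += 1
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def test_read_structure_counts(tmp_path):
    structure = read_structure(_toy_pdb(tmp_path))
    assert len(structure.chains) == 2
    assert structure.n_residues() == 8
    assert structure.n_atoms() == 24


def test_read_structure_selects_model(tmp_path):
    lines = ["MODEL        1",
             _atom_line(1, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0),
             _atom_line(2, "CA", "ALA", "A", 2, 4.8, 0.0, 0.0),
             "ENDMDL",
             "MODEL        2",
             _atom_line(1, "CA", "ALA", "A", 1, 9.0, 0.0, 0.0),
             _atom_line(2, "CA", "ALA", "A", 2, 13.8, 0.0, 0.0),
             "ENDMDL", "END"]
    path = tmp_path / "mm.pdb"
    path.write_text("\n".join(lines) + "\n")
    st2 = read_structure(path, model_index=2)
    assert st2["A"].residues[0].atoms["CA"].coord[0] == pytest.approx(9.0)
    with pytest.raises(ValueError):
        read_structure(path, model_index=3)
    with pytest.raises(ValueError):
        read_structure(path, model_index=0)


def test_altloc_highest_occupancy_wins(tmp_path):
    lines = [
        _atom_line(1, "N", "SER", "A", 1, 0.0, 0.0, 0.0),
        _atom_line(2, "CA", "SER", "A", 1, 1.0, 0.0, 0.0, occ=0.6, altloc="A"),
        _atom_line(3, "CA", "SER", "A", 1, 2.0, 0.0, 0.0, occ=0.4, altloc="B"),
        _atom_line(4, "C", "SER", "A", 1, 3.0, 0.0, 0.0),
        _atom_line(5, "OG", "SER", "A", 1, 4.0, 0.0, 0.0, occ=0.5, altloc="A"),
        _atom_line(6, "OG", "SER", "A", 1, 5.0, 0.0, 0.0, occ=0.5, altloc="B"),
        "END"]
    path = tmp_path / "alt.pdb"
    path.write_text("\n".join(lines) + "\n")
    res = read_structure(path)["A"].residues[0]
    assert res.atoms["CA"].coord[0] == pytest.approx(1.0)   # higher occupancy
    assert res.atoms["OG"].coord[0] == pytest.approx(4.0)   # tie -> first in file


def test_hetatm_retained_and_flagged_but_not_in_sequence(tmp_path):
    lines = [_atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
             _atom_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0),
             _atom_line(3, "C", "ALA", "A", 1, 2.0, 1.0, 0.0),
             _atom_line(4, "N", "GLY", "A", 2, 3.0, 1.0, 0.0),
             _atom_line(5, "CA", "GLY", "A", 2, 4.0, 1.5, 0.0),
             _atom_line(6, "C", "GLY", "A", 2, 5.0, 1.0, 0.0),
             _atom_line(7, "N", "SER", "A", 3, 6.0, 1.0, 0.0),
             _atom_line(8, "CA", "SER", "A", 3, 7.0, 1.5, 0.0),
             _atom_line(9, "C", "SER", "A", 3, 8.0, 1.0, 0.0),
             _atom_line(10, "C1", "LIG", "A", 101, 9.0, 9.0, 9.0, record="HETATM"),
             "END"]
    path = tmp_path / "het.pdb"
    path.write_text("\n".join(lines) + "\n")
    structure = read_structure(path)
    chain = structure["A"]
    assert len(chain) == 4
    assert chain.residues[-1].is_hetatm
    assert str(extract_sequence(structure, "A")) == "AGS"


def test_nonstandard_residue_mapping(tmp_path):
    lines = [_atom_line(1, "N", "MSE", "A", 1, 0.0, 0.0, 0.0),
             _atom_line(2, "CA", "MSE", "A", 1, 1.5, 0.0, 0.0),
             _atom_line(3, "C", "MSE", "A", 1, 2.0, 1.0, 0.0),
             _atom_line(4, "N", "ALA", "A", 2, 3.0, 1.0, 0.0),
             _atom_line(5, "CA", "ALA", "A", 2, 4.0, 1.5, 0.0),
             _atom_line(6, "C", "ALA", "A", 2, 5.0, 1.0, 0.0),
             "END"]
    path = tmp_path / "mse.pdb"
    path.write_text("\n".join(lines) + "\n")
    structure = read_structure(path)
    assert str(extract_sequence(structure, "A")) == "MA"
    assert str(extract_sequence(structure, "A", nonstandard_map={})) == "XA"
    with pytest.raises(KeyError):
        extract_sequence(structure, "Z")


def test_write_read_round_trip(tmp_path, hexamer):
    path = tmp_path / "rt.pdb"
    write_structure(hexamer, path)
    back = read_structure(path)
    assert back.chain_ids == hexamer.chain_ids
    assert back.n_residues() == hexamer.n_residues()
    assert back.n_atoms() == hexamer.n_atoms()
    for (_, _, a), (_, _, b) in zip(hexamer.iter_atoms(), back.iter_atoms()):
        assert np.allclose(a.coord, b.coord, atol=5e-4)  # PDB prints 3 decimals


def test_read_ensemble_frame_count(tmp_path, small_ensemble):
    path = tmp_path / "ens.pdb"
    write_ensemble(small_ensemble, path)
    back = read_ensemble(path)
    assert back.n_frames == small_ensemble.n_frames
    assert back.n_atoms == small_ensemble.n_atoms
    assert np.allclose(back.frames, small_ensemble.frames, atol=5e-4)


def test_read_ensemble_single_model_degenerate(tmp_path, helix20):
    path = tmp_path / "one.pdb"
    write_structure(helix20, path)
    ens = read_ensemble(path)
    assert ens.n_frames == 1


def test_read_ensemble_roster_mismatch_names_atom(tmp_path):
    lines = ["MODEL        1",
             _atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
             _atom_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0),
             "ENDMDL",
             "MODEL        2",
             _atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
             _atom_line(2, "CB", "ALA", "A", 1, 1.5, 0.0, 0.0),
             "ENDMDL", "END"]
    path = tmp_path / "bad.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValueError, match="CA"):
        read_ensemble(path)


def test_identity_trivial_cases():
    assert global_identity("MKTAYIAKQR", "MKTAYIAKQR") == pytest.approx(100.0)
    assert global_identity("ACDE", "ACDF") == pytest.approx(75.0)
    with pytest.raises(ValueError):
        global_identity("", "ACDE")


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=40),
       st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=40))
def test_identity_symmetric_and_bounded(a, b):
    ab = global_identity(a, b)
    ba = global_identity(b, a)
    assert ab == pytest.approx(ba, abs=1e-9)
    assert 0.0 <= ab <= 100.0
    assert global_identity(a, a) == pytest.approx(100.0)
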