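"""Disulfide scanner: Cbeta modelling, pair enumeration, geometric scoring,
locality and multiplicity."""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dsbdesign.core import Atom, Residue, ResidueRef
from dsbdesign.geometry import angle_deg, dihedral_deg, place_atom
from dsbdesign.scanner import (ScanConfig, classify_locality, enumerate_pairs,
                               geometry_score, model_cb, multiplicity, scan,
                               score_disulfide)
from dsbdesign.symmetry import detect_symmetry
from dsbdesign.synthetic import (make_helix_chain, make_ideal_disulfide_pair,
                                 make_oligomer, plant_interface_pair)


# ---------------------------------------------------------------------------
# Cbeta modelling

def test_model_cb_returns_observed_cb():
    res = Residue("VAL", 1)
    res.add_atom(Atom("N", "N", [0.0, 0.0, 0.0]))
    res.add_atom(Atom("CA", "C", [1.5, 0.0, 0.0]))
    res.add_atom(Atom("C", "C", [2.0, 1.4, 0.0]))
    res.add_atom(Atom("CB", "C", [9.0, 9.0, 9.0]))
    assert np.allclose(model_cb(res), [9.0, 9.0, 9.0])


def test_model_cb_ideal_geometry(helix20):
    """Modelled Cbeta: 1.53 A bond, N-CA-CB and C-CA-CB within 0.5 deg of
    110.5 (checked with a direct trigonometric computation)."""
    for res in helix20.chains[0].polymer()[2:5]:
        cb = model_cb(res)
        n, ca, c = (res.coord(x) for x in ("N", "CA", "C"))
        assert np.linalg.norm(cb - ca) == pytest.approx(1.53, abs=1e-9)
        assert angle_deg(n, ca, cb) == pytest.approx(110.5, abs=0.5)
        assert angle_deg(c, ca, cb) == pytest.approx(110.5, abs=0.5)


def test_model_cb_matches_l_amino_acid_chirality():
    """The modelled Cbeta must land on the observed L-side of a real residue
    (biotite's ideal ALA as the reference geometry)."""
    info = pytest.importorskip("biotite.structure.info")
    ala = info.residue("ALA")

    def coord(name):
        return ala.coord[ala.atom_name == name][0]

    res = Residue("ALA", 1)
    for name in ("N", "CA", "C"):
        res.add_atom(Atom(name, name[0], np.asarray(coord(name), float)))
    cb = model_cb(res)
    assert np.linalg.norm(cb - coord("CB")) < 0.25


def test_model_cb_requires_backbone():
    res = Residue("GLY", 1)
    res.add_atom(Atom("CA", "C", [0.0, 0.0, 0.0]))
    with pytest.raises(ValueError, match="backbone"):
        model_cb(res)


# ---------------------------------------------------------------------------
# pair enumeration

def test_enumerate_pairs_window(planted_hexamer):
    structure, _ = planted_hexamer
    cfg = ScanConfig()
    pairs = enumerate_pairs(structure, cfg)
    for a, b, d in pairs:
        assert cfg.ca_min <= d <= cfg.ca_max
        if a.chain_id == b.chain_id:
            assert abs(a.resseq - b.resseq) > 1


def test_enumerate_pairs_equals_brute_force(planted_hexamer):
    structure, _ = planted_hexamer
    cfg = ScanConfig()
    got = {frozenset([(a.chain_id, a.resseq), (b.chain_id, b.resseq)])
           for a, b, _ in enumerate_pairs(structure, cfg)}
    entries = [(c.chain_id, r.resseq, r.atoms["CA"].coord)
               for c in structure for r in c.polymer() if r.has_backbone()]
    expected = set()
    for (ca_id, ra, pa), (cb_id, rb, pb) in combinations(entries, 2):
        if ca_id == cb_id and abs(ra - rb) <= 1:
            continue
        d = np.linalg.norm(pa - pb)
        if cfg.ca_min <= d <= cfg.ca_max:
            expected.add(frozenset([(ca_id, ra), (cb_id, rb)]))
    assert got == expected


def test_enumerate_pairs_empty_window(helix20):
    assert enumerate_pairs(helix20, ScanConfig(ca_min=5.0, ca_max=5.0)) == []


# ---------------------------------------------------------------------------
# scoring

def test_geometry_score_zero_at_textbook_geometry():
    assert geometry_score(2.05, 104.15, 104.15, -87.0) == pytest.approx(0.0)
    assert geometry_score(2.05, 104.15, 104.15, 87.0) == pytest.approx(0.0)


def test_geometry_score_distance_term():
    # 0.5 A off ideal S-S at w_dist=1: ((0.5)/0.05)^2 = 100
    assert geometry_score(2.55, 104.15, 104.15, 87.0) == pytest.approx(100.0)


def test_score_disulfide_zero_for_ideal_pair():
    res_a, res_b = make_ideal_disulfide_pair()
    d_ss, chi_ss, score = score_disulfide(res_a, res_b)
    assert score == pytest.approx(0.0, abs=1e-12)
    assert d_ss == pytest.approx(2.05, abs=1e-6)
    assert abs(chi_ss) == pytest.approx(87.0, abs=1e-6)


def test_score_disulfide_matches_exhaustive_grid(helix20):
    """The vectorised grid minimum equals a scalar double loop over the full
    chi1 x chi1 grid."""
    cfg = ScanConfig(chi1_grid=np.arange(-180.0, 180.0, 30.0))
    res_a = helix20.chains[0].residues[2]
    res_b = helix20.chains[0].residues[6]
    got = score_disulfide(res_a, res_b, cfg)

    def sg(res, chi):
        cb = model_cb(res)
        return place_atom(res.coord("N"), res.coord("CA"), cb, 1.81, 114.0, chi), cb

    best = (None, None, np.inf)
    for chi_a in cfg.chi1_grid:
        for chi_b in cfg.chi1_grid:
            sg_a, cb_a = sg(res_a, chi_a)
            sg_b, cb_b = sg(res_b, chi_b)
            d = np.linalg.norm(sg_a - sg_b)
            th_a = angle_deg(cb_a, sg_a, sg_b)
            th_b = angle_deg(cb_b, sg_b, sg_a)
            chi_ss = dihedral_deg(cb_a, sg_a, sg_b, cb_b)
            s = ((d - 2.05) / 0.05) ** 2 + ((th_a - 104.15) / 5) ** 2 \
                + ((th_b - 104.15) / 5) ** 2 + ((abs(chi_ss) - 87) / 10) ** 2
            if s < best[2]:
                best = (d, chi_ss, s)
    assert got[2] == pytest.approx(best[2], rel=1e-9)
    assert got[0] == pytest.approx(best[0], rel=1e-9)


# ---------------------------------------------------------------------------
# locality & multiplicity

def test_classify_locality(hexamer):
    sym = detect_symmetry(hexamer)
    ref = lambda chain: ResidueRef(chain, 5, "", "ALA")
    assert classify_locality((ref("A"), ref("A")), sym) == "intra-subunit"
    assert classify_locality((ref("A"), ref("B")), sym) == "intra-dimer"
    assert classify_locality((ref("A"), ref("C")), sym) == "inter-dimer"
    with pytest.raises(KeyError):
        classify_locality((ref("A"), ref("Z")), sym)


def test_multiplicity_planted_pair_is_symmetry_order(planted_hexamer):
    structure, pairs = planted_hexamer
    sym = detect_symmetry(structure)
    assert multiplicity(pairs[0], sym, structure) == 3


def test_multiplicity_intra_subunit_pair_counts_chains(hexamer):
    sym = detect_symmetry(hexamer)
    # an i,i+3 helix pair exists identically in all six equivalent chains
    pair = (ResidueRef("A", 5, "", "ALA"), ResidueRef("A", 8, "", "ALA"))
    assert multiplicity(pair, sym, hexamer) == 6


def test_multiplicity_monomer(helix20):
    from dsbdesign.symmetry import SymmetryMap
    sym = SymmetryMap([["A"]], {}, 1, [])
    pair = (ResidueRef("A", 5, "", "ALA"), ResidueRef("A", 8, "", "ALA"))
    assert multiplicity(pair, sym, helix20) == 1


# ---------------------------------------------------------------------------
# full scan

def test_scan_finds_planted_pair_with_multiplicity(planted_hexamer):
    structure, pairs = planted_hexamer
    cands = scan(structure, ScanConfig(score_cutoff=None))
    planted = {frozenset([(a.chain_id, a.resseq), (b.chain_id, b.resseq)])
               for a, b in pairs}
    hits = [c for c in cands
            if frozenset([(c.res_a.chain_id, c.res_a.resseq),
                          (c.res_b.chain_id, c.res_b.resseq)]) in planted]
    assert len(hits) == 3
    for h in hits:
        assert h.locality == "intra-dimer"
        assert h.multiplicity == 3
        assert h.d_ca == pytest.approx(6.5, abs=0.05)
        assert h.mutations_required  # ALA positions need mutating to CYS


def test_scan_deterministic_and_sorted(planted_hexamer):
    structure, _ = planted_hexamer
    cfg = ScanConfig(score_cutoff=None)
    a = scan(structure, cfg)
    b = scan(structure, cfg)
    assert [c.as_row() for c in a] == [c.as_row() for c in b]
    scores = [c.score for c in a]
    assert scores == sorted(scores)


def test_scan_invariant_under_rigid_motion(planted_hexamer):
    structure, _ = planted_hexamer
    rot = Rotation.random(random_state=9).as_matrix()
    moved = structure.transformed(rot, np.array([8.0, -3.0, 12.0]))
    cfg = ScanConfig(score_cutoff=None)
    # symmetry-equivalent candidates tie in score to float precision, so the
    # ordering within a tie block is not meaningful: compare as sets
    rows_a = {(str(c.res_a), str(c.res_b), round(c.d_ca, 6), round(c.score, 6),
               c.locality, c.multiplicity) for c in scan(structure, cfg)}
    rows_b = {(str(c.res_a), str(c.res_b), round(c.d_ca, 6), round(c.score, 6),
               c.locality, c.multiplicity) for c in scan(moved, cfg)}
    assert rows_a == rows_b


def test_scan_cutoff_is_monotone(planted_hexamer):
    structure, _ = planted_hexamer
    loose = {(str(c.res_a), str(c.res_b)) for c in
             scan(structure, ScanConfig(score_cutoff=100.0))}
    tight = {(str(c.res_a), str(c.res_b)) for c in
             scan(structure, ScanConfig(score_cutoff=20.0))}
    assert tight <= loose


def test_scan_empty_window(hexamer):
    assert scan(hexamer, ScanConfig(ca_min=5.0, ca_max=5.0)) == []
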