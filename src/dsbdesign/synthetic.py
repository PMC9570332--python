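"""Synthetic fixtures: cyclic-symmetric toy oligomers with planted interface
pairs, harmonic (Gaussian) conformational ensembles, and Gaussian catalytic
distance series.

The generators emulate the study conditions every stage of the pipeline is
exercised on:

* ideal alpha-helical poly-ALA chains assembled into Cn rings or
  trimer-of-dimers style (Cn of C2 dimers) assemblies with *exact* planted
  symmetry;
* interface residue pairs planted at a controlled Calpha-Calpha separation
  inside (or outside) the disulfide-compatible window;
* per-residue harmonic fluctuations whose amplitudes stand in for
  temperature (sigma as an amplitude multiplier, not simulated physics),
  optionally contaminated with per-frame rigid-body motion;
* Gaussian distance series with stated mean/SD for the productive-complex
  classifier.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .catalytic import DistanceSeries
from .core import Atom, AtomSpec, Chain, Residue, ResidueRef, Structure
from .ensemble import Ensemble
from .geometry import place_atom, rotation_about_axis

__all__ = [
    "GeneratorSpec",
    "make_helix_chain",
    "make_oligomer",
    "plant_interface_pair",
    "make_harmonic_ensemble",
    "make_distance_series",
    "make_ideal_disulfide_pair",
]

# ideal backbone internal coordinates (alpha-helix: phi=-57, psi=-47)
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5

DIMER_SEPARATION = 5.0  # Angstrom, half-gap of the C2 dimer interface


@dataclass
class GeneratorSpec:
    """Bundle of generator parameters (mirrors the CLI `simulate` flags)."""

    seed: int = 0
    n_res: int = 20
    symmetry_order: int = 3
    dimerize: bool = True
    ring_radius: float = 16.0
    sigma_profile: Optional[np.ndarray] = None
    n_frames: int = 100
    rigid_motion: bool = False


def make_helix_chain(n_res: int, seed: int = 0, chain_id: str = "A") -> Structure:
    """Single-chain poly-ALA ideal alpha-helix (N, CA, C, O per residue).

    Built by chaining ideal internal coordinates (phi = -57, psi = -47,
    omega = 180), which yields the canonical ~1.5 A rise and ~100 deg twist
    per residue; the chain is centred at the origin with its helix axis on z.
    The output is deterministic (the seed is accepted for interface symmetry
    with the stochastic generators and recorded, not consumed).
    """
    if n_res < 4:
        raise ValueError("helix needs at least 4 residues")
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    t = np.radians(180.0 - _A_N_CA_C)
    c = ca + _B_CA_C * np.array([np.cos(t), np.sin(t), 0.0])
    backbone = [(n, ca, c)]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_next = place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, _PSI)
        ca_next = place_atom(ca_prev, c_prev, n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_next = place_atom(c_prev, n_next, ca_next, _B_CA_C, _A_N_CA_C, _PHI)
        backbone.append((n_next, ca_next, c_next))

    coords_o = []
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        if i + 1 < n_res:
            n_ref = backbone[i + 1][0]
            o_i = place_atom(n_ref, ca_i, c_i, _B_C_O, _A_CA_C_O, 180.0)
        else:
            o_i = place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, _PSI + 180.0)
        coords_o.append(o_i)

    # align the exact screw axis of the residue-to-residue transform with z:
    # the rotation/translation mapping residue i onto i+1 defines the helix
    # axis (direction = rotation axis, a point on it from (I - R) p = t_perp)
    from .geometry import kabsch, rotation_axis
    res0 = np.array([*backbone[0], coords_o[0]])
    res1 = np.array([*backbone[1], coords_o[1]])
    rot_step, t_step, _ = kabsch(res0, res1)
    axis = rotation_axis(rot_step)
    if float(np.dot(axis, t_step)) < 0:
        axis = -axis
    t_perp = t_step - np.dot(t_step, axis) * axis
    point = np.linalg.lstsq(np.eye(3) - rot_step, t_perp, rcond=None)[0]
    point = point - np.dot(point, axis) * axis

    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        rot = np.eye(3) if axis[2] > 0 else rotation_about_axis([1.0, 0, 0], 180.0)
    else:
        ang = np.degrees(np.arctan2(s, float(np.dot(axis, z))))
        rot = rotation_about_axis(v / s, ang)

    cas = np.array([b[1] for b in backbone])
    z_mid = rot @ (cas.mean(axis=0) - point)

    chain = Chain(chain_id)
    for i in range(n_res):
        res = Residue(name="ALA", resseq=i + 1)
        for name, coord in zip(("N", "CA", "C", "O"),
                               (*backbone[i], coords_o[i])):
            elem = name[0]
            res.add_atom(Atom(name, elem,
                              rot @ (coord - point) - [0.0, 0.0, z_mid[2]]))
        chain.add_residue(res)
    st = Structure(id=f"helix{n_res}", source_format="synthetic")
    st.add_chain(chain)
    return st


def _chain_ids(n: int) -> list[str]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"
    if n > len(alphabet):
        raise ValueError(f"cannot label {n} chains with single-character PDB ids")
    return list(alphabet[:n])


def _subunit_operators(symmetry_order: int, dimerize: bool) -> list[np.ndarray]:
    """Rotation operators (about the origin) generating each chain from the
    base subunit: Cn about z, optionally composed with C2 about x."""
    ops = []
    c2x = rotation_about_axis([1.0, 0.0, 0.0], 180.0)
    for k in range(symmetry_order):
        rz = rotation_about_axis([0.0, 0.0, 1.0], 360.0 * k / symmetry_order)
        ops.append(rz)
        if dimerize:
            ops.append(rz @ c2x)
    return ops


def make_oligomer(chain: Structure, symmetry_order: int, dimerize: bool = False,
                  ring_radius: float = 16.0,
                  base_offset: Optional[np.ndarray] = None) -> Structure:
    """Assemble copies of a single-chain structure around the z axis.

    The base chain is translated to ring position (ring_radius, s, 0) with
    s = DIMER_SEPARATION when dimerizing (0 otherwise) and replicated by the
    cyclic group Cn about z; with ``dimerize`` each subunit additionally gets
    a C2 mate (axis x), giving 2n chains and exact Dn-style symmetry -- the
    trimer-of-dimers hexamer for n = 3.  Chain ids run A, B, C, ...
    """
    if symmetry_order < 1:
        raise ValueError("symmetry_order must be >= 1")
    if len(chain.chains) != 1:
        raise ValueError("make_oligomer expects a single-chain structure")
    if base_offset is None:
        base_offset = np.zeros(3)
    s = DIMER_SEPARATION if dimerize else 0.0
    shift = np.array([ring_radius, s, 0.0]) + np.asarray(base_offset, float)
    base = chain.transformed(np.eye(3), shift)

    ops = _subunit_operators(symmetry_order, dimerize)
    ids = _chain_ids(len(ops))
    out = Structure(id=f"{chain.id}_x{len(ops)}", source_format="synthetic")
    for cid, op in zip(ids, ops):
        copy = base.transformed(op, np.zeros(3))
        copy.chains[0].chain_id = cid
        out.add_chain(copy.chains[0])
    return out


def plant_interface_pair(chain: Structure, target_d_ca: float,
                         symmetry_order: int = 3, dimerize: bool = True,
                         ring_radius: float = 16.0
                         ) -> tuple[Structure, list[tuple[ResidueRef, ResidueRef]]]:
    """Build an oligomer in which one same-position cross-chain Calpha pair
    sits at ``target_d_ca`` (to well within 0.05 A), plus all its symmetry
    images.

    The generator picks the residue with the most adjustable interface
    geometry and shifts the base chain along the interface normal (towards
    the C2 mate when dimerizing, radially for a pure Cn ring) before
    symmetrising, so the planted symmetry stays exact.  Raises if the target
    is unreachable for every residue.
    """
    if len(chain.chains) != 1:
        raise ValueError("plant_interface_pair expects a single-chain structure")
    s = DIMER_SEPARATION if dimerize else 0.0
    base_shift = np.array([ring_radius, s, 0.0])
    cas = chain.chains[0].ca_coords() + base_shift
    resseqs = [r.resseq for r in chain.chains[0].polymer() if "CA" in r.atoms]

    if dimerize:
        # mate pair distance: |p - C2x p| = 2 sqrt(y^2 + z^2); adjust y
        half = target_d_ca / 2.0
        best = None
        for i, p in enumerate(cas):
            if abs(p[2]) > half:
                continue
            for root in (+1.0, -1.0):
                y_new = root * np.sqrt(half ** 2 - p[2] ** 2)
                t = y_new - p[1]
                if p[1] + t < 0.5:     # keep the subunit on its own side
                    continue
                if best is None or abs(t) < abs(best[1]):
                    best = (i, t)
        if best is None:
            raise ValueError(f"target d_ca {target_d_ca} A unreachable for this chain")
        i, t = best
        offset = np.array([0.0, t, 0.0])
        oligomer = make_oligomer(chain, symmetry_order, True, ring_radius, offset)
        ids = _chain_ids(2 * symmetry_order)
        pairs = [(ResidueRef(ids[2 * k], resseqs[i], "", "ALA"),
                  ResidueRef(ids[2 * k + 1], resseqs[i], "", "ALA"))
                 for k in range(symmetry_order)]
        return oligomer, pairs

    if symmetry_order < 2:
        raise ValueError("planting a cross-chain pair needs symmetry_order >= 2")
    # adjacent-copy distance: 2 sin(pi/n) * rho; adjust radial (x) position
    factor = 2.0 * np.sin(np.pi / symmetry_order)
    rho_target = target_d_ca / factor
    best = None
    for i, p in enumerate(cas):
        if abs(p[1]) > rho_target:
            continue
        x_new = np.sqrt(rho_target ** 2 - p[1] ** 2)
        t = x_new - p[0]
        if best is None or abs(t) < abs(best[1]):
            best = (i, t)
    if best is None:
        raise ValueError(f"target d_ca {target_d_ca} A unreachable for this chain")
    i, t = best
    oligomer = make_oligomer(chain, symmetry_order, False, ring_radius,
                             np.array([t, 0.0, 0.0]))
    ids = _chain_ids(symmetry_order)
    pairs = [(ResidueRef(ids[k], resseqs[i], "", "ALA"),
              ResidueRef(ids[(k + 1) % symmetry_order], resseqs[i], "", "ALA"))
             for k in range(symmetry_order)]
    return oligomer, pairs


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_harmonic_ensemble(structure: Structure, sigma_profile: Sequence[float],
                           n_frames: int, seed: int = 0,
                           rigid_motion: bool = False) -> Ensemble:
    """Ensemble of `n_frames` frames with i.i.d. per-axis Gaussian displacement
    of amplitude sigma_i around the reference, sigma shared by all atoms of
    residue i (harmonic/isotropic fluctuation model; expected RMSF is
    sigma_i * sqrt(3)).

    ``sigma_profile`` must have one non-negative entry per residue (HETATM
    groups included, in topology order).  With ``rigid_motion`` each frame
    additionally receives a uniformly random rotation about the centroid and
    a random translation (up to 5 A per axis) -- superposition-based
    analytics must be blind to it.
    """
    sigma = np.asarray(sigma_profile, float)
    residues = [r for c in structure for r in c]
    if sigma.shape != (len(residues),):
        raise ValueError(
            f"sigma_profile length {sigma.size} != residue count {len(residues)}")
    if np.any(sigma < 0):
        raise ValueError("sigma_profile must be non-negative")
    per_atom = np.concatenate([
        np.full(len(res.atoms), sig) for res, sig in zip(residues, sigma)])
    ref = np.array([a.coord for _, _, a in structure.iter_atoms()])
    rng = np.random.default_rng(seed)
    frames = ref[None, :, :] + rng.normal(
        size=(n_frames, len(ref), 3)) * per_atom[None, :, None]
    if rigid_motion:
        centroid = ref.mean(axis=0)
        for f in range(n_frames):
            rot = _random_rotation(rng)
            trans = rng.uniform(-5.0, 5.0, size=3)
            frames[f] = (frames[f] - centroid) @ rot.T + centroid + trans
    return Ensemble(topology=structure, frames=frames)


def make_distance_series(mu: float, sigma: float, n_frames: int, seed: int = 0,
                         label: str = "synthetic") -> DistanceSeries:
    """Seeded Gaussian distance series, truncated at zero."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    values = np.clip(mu + sigma * rng.normal(size=n_frames), 0.0, None)
    endpoints = (AtomSpec("A", 1, "", "X1"), AtomSpec("A", 1, "", "X2"))
    return DistanceSeries(label=label, endpoints=endpoints, values=values)


def make_ideal_disulfide_pair(chi1_a: float = -60.0, chi1_b: float = -60.0,
                              chi_ss: float = -87.0
                              ) -> tuple[Residue, Residue]:
    """Two CYS residues whose backbones admit an exactly textbook disulfide
    (d_SS = 2.05 A, CB-S-S angles 104.15 deg, |chi_SS| = 87 deg) at the given
    chi1 rotamers -- the geometric ground truth for the scanner's score.
    """
    sg1 = np.array([0.0, 0.0, 0.0])
    sg2 = np.array([2.05, 0.0, 0.0])
    ref = np.array([0.3, 1.1, 0.6])
    cb1 = place_atom(ref, sg2, sg1, 1.81, 104.15, 37.0)
    cb2 = place_atom(cb1, sg1, sg2, 1.81, 104.15, chi_ss)
    ca1 = place_atom(sg2, sg1, cb1, 1.53, 114.0, 63.0)
    n1 = place_atom(sg1, cb1, ca1, 1.458, 110.5, chi1_a)
    c1 = place_atom(cb1, n1, ca1, 1.525, 111.2, -122.0)
    ca2 = place_atom(sg1, sg2, cb2, 1.53, 114.0, -58.0)
    n2 = place_atom(sg2, cb2, ca2, 1.458, 110.5, chi1_b)
    c2 = place_atom(cb2, n2, ca2, 1.525, 111.2, -122.0)

    def _residue(resseq, n, ca, c, cb):
        res = Residue(name="CYS", resseq=resseq)
        res.add_atom(Atom("N", "N", n))
        res.add_atom(Atom("CA", "C", ca))
        res.add_atom(Atom("C", "C", c))
        res.add_atom(Atom("CB", "C", cb))
        return res

    return _residue(1, n1, ca1, c1, cb1), _residue(2, n2, ca2, c2, cb2)
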