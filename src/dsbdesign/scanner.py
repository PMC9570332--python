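"""Cysteine-pair (disulfide) engineering-site scanner.

Enumerates residue pairs of an oligomeric structure whose Calpha-Calpha
separation lies inside the disulfide-compatible window (default 3.0-7.5 A),
models the mutant cystine geometry on the fixed backbone (ideal Cbeta, then
Sgamma swept over a chi1 grid), scores each pair against textbook disulfide
geometry, and annotates candidates with symmetry-derived locality
(intra-subunit / intra-dimer / inter-dimer) and multiplicity -- the number of
bridge copies one sequence mutation creates in the whole assembly.

The score is a weighted sum of squared reduced deviations from ideal
disulfide geometry (lower = better; 0 = textbook):

    score = w_d * ((d_SS - 2.05 A) / 0.05 A)^2
          + w_a * sum over both CB-S-S angles ((theta - 104.15 deg) / 5 deg)^2
          + w_x * ((|chi_SS| - 87 deg) / 10 deg)^2

The denominators are the roughly observed spreads of each coordinate in
native disulfides, so the three terms are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Residue, ResidueRef, Structure
from .geometry import place_atom
from .symmetry import SymmetryMap, detect_symmetry

__all__ = [
    "ScanConfig",
    "DisulfideCandidate",
    "model_cb",
    "enumerate_pairs",
    "geometry_score",
    "score_disulfide",
    "classify_locality",
    "multiplicity",
    "scan",
]

# ideal side-chain construction constants
CB_BOND = 1.53        # CA-CB, Angstrom
CB_ANGLE = 110.5      # N-CA-CB and C-CA-CB, degrees
SG_BOND = 1.81        # CB-SG, Angstrom
SG_ANGLE = 114.0      # CA-CB-SG, degrees


def _default_chi1_grid() -> np.ndarray:
    return np.arange(-180.0, 180.0, 10.0)


@dataclass
class ScanConfig:
    """Geometry window, scoring constants and weights for a scan."""

    ca_min: float = 3.0
    ca_max: float = 7.5
    chi1_grid: np.ndarray = field(default_factory=_default_chi1_grid)
    ideal_ss: float = 2.05
    ideal_angle: float = 104.15
    ideal_chi_ss: float = 87.0
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    score_cutoff: Optional[float] = 50.0

    def __post_init__(self) -> None:
        if not self.ca_min < self.ca_max:
            if self.ca_min == self.ca_max:
                pass  # degenerate window allowed: yields an empty scan
            else:
                raise ValueError("ca_min must not exceed ca_max")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        self.chi1_grid = np.asarray(self.chi1_grid, float)


@dataclass
class DisulfideCandidate:
    """One scored candidate cysteine pair."""

    res_a: ResidueRef
    res_b: ResidueRef
    d_ca: float
    d_cb: float
    best_d_ss: float
    best_chi_ss: float
    score: float
    locality: str
    multiplicity: int
    mutations_required: list[ResidueRef]

    def as_row(self) -> dict:
        return {
            "chain_a": self.res_a.chain_id, "res_a": self.res_a.resseq,
            "name_a": self.res_a.name,
            "chain_b": self.res_b.chain_id, "res_b": self.res_b.resseq,
            "name_b": self.res_b.name,
            "d_ca": round(self.d_ca, 3), "d_cb": round(self.d_cb, 3),
            "d_ss": round(self.best_d_ss, 3), "chi_ss": round(self.best_chi_ss, 1),
            "score": round(self.score, 3), "locality": self.locality,
            "multiplicity": self.multiplicity,
            "mutations": ";".join(str(m) for m in self.mutations_required),
        }


def model_cb(residue: Residue) -> np.ndarray:
    """Cbeta coordinate for a residue: observed CB if present, else an ideal
    Cbeta built on the backbone frame (1.53 A from CA, N-CA-CB = C-CA-CB =
    110.5 deg, L-configuration)."""
    if "CB" in residue.atoms:
        return residue.atoms["CB"].coord
    if not residue.has_backbone():
        raise ValueError(
            f"residue {residue.name} {residue.resseq}: backbone incomplete, cannot model CB")
    n = residue.coord("N")
    ca = residue.coord("CA")
    c = residue.coord("C")
    v1 = n - ca
    v2 = c - ca
    v1h = v1 / np.linalg.norm(v1)
    v2h = v2 / np.linalg.norm(v2)
    nrm = np.cross(v1h, v2h)
    nn = np.linalg.norm(nrm)
    if nn < 1e-8:
        raise ValueError(
            f"residue {residue.name} {residue.resseq}: collinear backbone")
    nrm /= nn
    cos_t = np.cos(np.radians(CB_ANGLE))
    dot12 = float(np.dot(v1h, v2h))
    alpha = cos_t / (1.0 + dot12)
    rad = 1.0 - alpha ** 2 * (2.0 + 2.0 * dot12)
    beta = np.sqrt(max(rad, 0.0))  # + sign gives the L-amino-acid side
    u = alpha * (v1h + v2h) + beta * nrm
    return ca + CB_BOND * u / np.linalg.norm(u)


def _scannable(structure: Structure) -> list[tuple[ResidueRef, Residue]]:
    out = []
    skipped = 0
    for chain in structure:
        for res in chain.polymer():
            if res.has_backbone():
                out.append((ResidueRef(chain.chain_id, res.resseq, res.icode, res.name),
                            res))
            else:
                skipped += 1
    if skipped:
        warnings.warn(f"{skipped} residue(s) skipped: incomplete backbone",
                      stacklevel=3)
    return out


def enumerate_pairs(structure: Structure, config: ScanConfig = ScanConfig()
                    ) -> list[tuple[ResidueRef, ResidueRef, float]]:
    """All unordered residue pairs whose Calpha separation falls in the
    disulfide window ``[ca_min, ca_max]``.

    Sequence-adjacent pairs (|resseq| difference <= 1 in the same chain) and
    residues with incomplete backbones are excluded; both intra- and
    inter-chain pairs are produced.  Returns (ref_a, ref_b, d_ca) triples in
    deterministic order.
    """
    entries = _scannable(structure)
    if len(entries) < 2:
        return []
    refs = [e[0] for e in entries]
    ca = np.array([e[1].atoms["CA"].coord for e in entries])
    d2 = np.sum((ca[:, None, :] - ca[None, :, :]) ** 2, axis=2)
    lo2, hi2 = config.ca_min ** 2, config.ca_max ** 2
    ii, jj = np.nonzero(np.triu((d2 >= lo2) & (d2 <= hi2), k=1))
    pairs = []
    for i, j in zip(ii.tolist(), jj.tolist()):
        a, b = refs[i], refs[j]
        if a.chain_id == b.chain_id and abs(a.resseq - b.resseq) <= 1 \
                and a.icode == b.icode == "":
            continue
        pairs.append((a, b, float(np.sqrt(d2[i, j]))))
    return pairs


def geometry_score(d_ss, theta_a, theta_b, chi_ss, config: ScanConfig = ScanConfig()):
    """The disulfide geometry score (array-capable; 0 at textbook geometry)."""
    w_d, w_a, w_x = config.weights
    d_ss = np.asarray(d_ss, float)
    theta_a = np.asarray(theta_a, float)
    theta_b = np.asarray(theta_b, float)
    chi_ss = np.asarray(chi_ss, float)
    return (w_d * ((d_ss - config.ideal_ss) / 0.05) ** 2
            + w_a * (((theta_a - config.ideal_angle) / 5.0) ** 2
                     + ((theta_b - config.ideal_angle) / 5.0) ** 2)
            + w_x * ((np.abs(chi_ss) - config.ideal_chi_ss) / 10.0) ** 2)


def _sg_positions(residue: Residue, cb: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Sgamma position for every chi1 on the grid (chi1 = N-CA-CB-SG)."""
    n = residue.coord("N")
    ca = residue.coord("CA")
    return np.array([place_atom(n, ca, cb, SG_BOND, SG_ANGLE, chi) for chi in grid])


def score_disulfide(res_a: Residue, res_b: Residue,
                    config: ScanConfig = ScanConfig()
                    ) -> tuple[float, float, float]:
    """Best disulfide geometry for a residue pair over the chi1 x chi1 grid.

    Sgamma is placed at 1.81 A from the (observed or modelled) Cbeta with
    CA-CB-SG = 114 deg for every chi1 on the grid of each residue; over all
    grid^2 combinations the minimum of :func:`geometry_score` is returned as
    ``(best_d_ss, best_chi_ss, score)``.
    """
    cb_a = model_cb(res_a)
    cb_b = model_cb(res_b)
    sg_a = _sg_positions(res_a, cb_a, config.chi1_grid)   # (g, 3)
    sg_b = _sg_positions(res_b, cb_b, config.chi1_grid)   # (g, 3)

    diff = sg_b[None, :, :] - sg_a[:, None, :]            # (g, g, 3)
    d_ss = np.linalg.norm(diff, axis=2)
    d_ss_safe = np.where(d_ss < 1e-9, 1e-9, d_ss)

    def _angle_at(sg_self, cb_self, toward, sign):
        # angle CB-SG-SG' at each sg_self against every sg of the partner
        u = cb_self - sg_self                             # (g, 3)
        cosang = np.einsum("ik,ijk->ij", u, sign * diff) / (
            np.linalg.norm(u, axis=1)[:, None] * d_ss_safe)
        return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    theta_a = _angle_at(sg_a, cb_a, None, +1.0)
    # for residue b the roles transpose: angle at sg_b towards sg_a
    u_b = cb_b - sg_b                                     # (g, 3)
    cos_b = np.einsum("jk,ijk->ij", u_b, -diff) / (
        np.linalg.norm(u_b, axis=1)[None, :] * d_ss_safe)
    theta_b = np.degrees(np.arccos(np.clip(cos_b, -1.0, 1.0)))

    # dihedral CB_a - SG_a - SG_b - CB_b, vectorised over the (g, g) grid
    b0 = sg_a - cb_a                                      # (g, 3)
    b1 = diff                                             # (g, g, 3)
    b2 = (cb_b - sg_b)                                    # (g, 3)
    n1 = np.cross(np.broadcast_to(b0[:, None, :], b1.shape), b1)
    n2 = np.cross(b1, np.broadcast_to(b2[None, :, :], b1.shape))
    b1h = b1 / d_ss_safe[:, :, None]
    m1 = np.cross(n1, b1h)
    x = np.einsum("ijk,ijk->ij", n1, n2)
    y = np.einsum("ijk,ijk->ij", m1, n2)
    chi_ss = np.degrees(np.arctan2(y, x))

    scores = geometry_score(d_ss, theta_a, theta_b, chi_ss, config)
    i, j = np.unravel_index(int(np.argmin(scores)), scores.shape)
    return float(d_ss[i, j]), float(chi_ss[i, j]), float(scores[i, j])


def classify_locality(pair: tuple[ResidueRef, ResidueRef],
                      symmetry_map: SymmetryMap) -> str:
    """'intra-subunit' (same chain), 'intra-dimer' (dimer mates) or
    'inter-dimer' (everything else across chains)."""
    a, b = pair
    for ref in (a, b):
        symmetry_map.class_of(ref.chain_id)  # raises on unknown chain
    if a.chain_id == b.chain_id:
        return "intra-subunit"
    if symmetry_map.same_dimer(a.chain_id, b.chain_id):
        return "intra-dimer"
    return "inter-dimer"


def multiplicity(pair: tuple[ResidueRef, ResidueRef], symmetry_map: SymmetryMap,
                 structure: Structure, config: ScanConfig = ScanConfig()) -> int:
    """Number of symmetry images of the pair in the assembly.

    Images are same-position residue pairs on chains structurally equivalent
    to the original chains (same chain for an intra-subunit pair, distinct
    chains otherwise) whose Calpha separation also satisfies the scan window.
    A planted C2-interface pair in a trimer-of-dimers hexamer therefore
    counts 3; an intra-subunit pair in a hexamer of equivalent chains, 6.
    """
    a, b = pair
    class_a = symmetry_map.class_of(a.chain_id)
    class_b = symmetry_map.class_of(b.chain_id)
    count = 0
    seen: set[frozenset] = set()
    for ca_id in class_a:
        for cb_id in class_b:
            if (a.chain_id == b.chain_id) != (ca_id == cb_id):
                continue
            ra = structure[ca_id].find_residue(a.resseq, a.icode)
            rb = structure[cb_id].find_residue(b.resseq, b.icode)
            if ra is None or rb is None or "CA" not in ra.atoms or "CA" not in rb.atoms:
                continue
            key = frozenset([(ca_id, a.resseq, a.icode), (cb_id, b.resseq, b.icode)])
            if len(key) < 2 or key in seen:
                continue
            d = float(np.linalg.norm(ra.atoms["CA"].coord - rb.atoms["CA"].coord))
            if config.ca_min <= d <= config.ca_max:
                seen.add(key)
                count += 1
    return max(count, 1)


def scan(structure: Structure, config: ScanConfig = ScanConfig(),
         symmetry_map: Optional[SymmetryMap] = None) -> list[DisulfideCandidate]:
    """Full scan: enumerate -> score -> classify -> rank.

    Candidates with score <= ``config.score_cutoff`` (all, if the cutoff is
    None) are returned sorted ascending by score, ties broken by
    (d_ca, res_a, res_b).  Output is deterministic for a given input.
    """
    if symmetry_map is None:
        if len(structure.chains) >= 2:
            symmetry_map = detect_symmetry(structure)
        else:
            symmetry_map = SymmetryMap(
                equivalence_classes=[[c.chain_id] for c in structure.chains],
                rotation_angle_deg={}, symmetry_order=1, dimers=[])
    candidates = []
    for ref_a, ref_b, d_ca in enumerate_pairs(structure, config):
        res_a = ref_a.lookup(structure)
        res_b = ref_b.lookup(structure)
        try:
            cb_a = model_cb(res_a)
            cb_b = model_cb(res_b)
            d_ss, chi_ss, score = score_disulfide(res_a, res_b, config)
        except ValueError as exc:
            warnings.warn(f"pair {ref_a}/{ref_b} skipped: {exc}", stacklevel=2)
            continue
        if config.score_cutoff is not None and score > config.score_cutoff:
            continue
        mutations = [r for r, res in ((ref_a, res_a), (ref_b, res_b))
                     if res.name != "CYS"]
        candidates.append(DisulfideCandidate(
            res_a=ref_a, res_b=ref_b, d_ca=d_ca,
            d_cb=float(np.linalg.norm(cb_a - cb_b)),
            best_d_ss=d_ss, best_chi_ss=chi_ss, score=score,
            locality=classify_locality((ref_a, ref_b), symmetry_map),
            multiplicity=multiplicity((ref_a, ref_b), symmetry_map, structure, config),
            mutations_required=mutations,
        ))
    candidates.sort(key=lambda c: (c.score, c.d_ca, str(c.res_a), str(c.res_b)))
    return candidates
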