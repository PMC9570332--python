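"""Conformational-ensemble analytics: superposition-based RMSD series,
per-residue RMSF, B-factors (Debye-Waller) and cross-condition fold changes.

The flexibility proxies computed here are the standard trajectory observables
used to compare a rigidified (e.g. disulfide-locked) variant against the
wild type across temperatures:

* RMSD(t)  -- deviation of each frame from a reference after optimal rigid
  superposition; drift/unfolding indicator.
* RMSF_i   -- fluctuation of residue i about its ensemble-mean position after
  superposing all frames onto the iterated mean structure.
* B_i      -- (8 pi^2 / 3) * RMSF_i^2, the isotropic atomic displacement
  parameter on the crystallographic scale (A^2).
* fold change -- ratio of mean B between a high- and a low-temperature
  ensemble; a rigidified variant shows a smaller ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .core import Structure
from .geometry import kabsch

__all__ = [
    "Ensemble",
    "FlexibilityProfile",
    "BFACTOR_CONSTANT",
    "rmsd_series",
    "rmsf",
    "bfactor",
    "flexibility_profile",
    "fold_change",
]

#: B = BFACTOR_CONSTANT * rmsf^2  (isotropic Debye-Waller relation)
BFACTOR_CONSTANT = 8.0 * np.pi ** 2 / 3.0

_BACKBONE = ("N", "CA", "C", "O")

#: atomic masses for optional mass weighting (Da); unknown elements -> 12.0
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974, "SE": 78.971}


@dataclass
class Ensemble:
    """A topology plus F frames of coordinates (F x A x 3, Angstrom).

    Every frame shares the topology's atom roster and order.  Atom order is
    the iteration order of the topology (chains, then residues, then atoms).
    """

    topology: Structure
    frames: np.ndarray
    frame_labels: Optional[list[str]] = None
    _atom_table: list = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, A, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms():
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology atom count "
                f"{self.topology.n_atoms()}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def atom_table(self) -> list[tuple[str, int, str, str, str, bool]]:
        """Per-atom (chain_id, resseq, icode, atom_name, element, is_hetatm)."""
        if self._atom_table is None:
            self._atom_table = [
                (c.chain_id, r.resseq, r.icode, a.name, a.element, r.is_hetatm)
                for c, r, a in self.topology.iter_atoms()]
        return self._atom_table

    def select(self, selection: Union[str, Sequence[int]] = "ca") -> np.ndarray:
        """Atom indices for a named selection: 'ca', 'backbone' or 'all'
        (polymer residues only), or an explicit index sequence."""
        if not isinstance(selection, str):
            idx = np.asarray(selection, int)
            if idx.size == 0:
                raise ValueError("empty selection")
            return idx
        sel = selection.lower()
        table = self.atom_table
        if sel == "ca":
            idx = [i for i, t in enumerate(table) if t[3] == "CA" and not t[5]]
        elif sel == "backbone":
            idx = [i for i, t in enumerate(table) if t[3] in _BACKBONE and not t[5]]
        elif sel == "all":
            idx = [i for i, t in enumerate(table) if not t[5]]
        else:
            raise ValueError(f"unknown selection {selection!r}")
        if not idx:
            raise ValueError(f"selection {selection!r} matches no atoms")
        return np.array(idx, int)

    def residue_keys(self, indices: np.ndarray) -> list[tuple[str, int, str]]:
        """(chain_id, resseq, icode) for each selected atom index."""
        table = self.atom_table
        return [(table[i][0], table[i][1], table[i][2]) for i in indices]

    def masses(self, indices: np.ndarray) -> np.ndarray:
        table = self.atom_table
        return np.array([_MASSES.get(table[i][4].upper(), 12.0) for i in indices])

    def frame_structure(self, frame: int) -> Structure:
        """Topology with the coordinates of one frame (a deep copy)."""
        coords = self.frames[frame]
        out = self.topology.transformed(np.eye(3), np.zeros(3))
        k = 0
        for _, _, atom in out.iter_atoms():
            atom.coord = coords[k].copy()
            k += 1
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Ensemble":
        """Apply one rigid motion to every frame (testing aid)."""
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return Ensemble(self.topology, self.frames @ rot.T + t, self.frame_labels)


@dataclass
class FlexibilityProfile:
    """Per-residue flexibility summary of one ensemble/condition."""

    selection: str
    residue_keys: list[tuple[str, int, str]]
    rmsf: np.ndarray            # per-residue, Angstrom
    bfactor: np.ndarray         # per-residue, Angstrom^2
    mean_bfactor: float
    temperature_label: str = ""

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, float)
        self.bfactor = np.asarray(self.bfactor, float)
        if np.any(self.rmsf < 0) or np.any(self.bfactor < 0):
            raise ValueError("rmsf and bfactor must be non-negative")
        if not np.allclose(self.bfactor, BFACTOR_CONSTANT * self.rmsf ** 2,
                           rtol=1e-10, atol=1e-12):
            raise ValueError("bfactor must equal (8*pi^2/3) * rmsf^2")


def _reference_coords(ensemble: Ensemble, reference, idx: np.ndarray) -> np.ndarray:
    if reference is None:
        return ensemble.frames[0, idx]
    if isinstance(reference, (int, np.integer)):
        return ensemble.frames[int(reference), idx]
    if isinstance(reference, Structure):
        ref_ens = Ensemble(reference, np.array(
            [[a.coord for _, _, a in reference.iter_atoms()]]))
        if ref_ens.atom_table != ensemble.atom_table:
            raise ValueError("reference structure atom roster differs from ensemble")
        return ref_ens.frames[0, idx]
    raise TypeError("reference must be a frame index or a Structure")


def rmsd_series(ensemble: Ensemble, reference=None, selection: str = "ca",
                mass_weighted: bool = False) -> np.ndarray:
    """Per-frame RMSD (Angstrom) after Kabsch superposition onto a reference.

    `reference` is a frame index (default 0) or a Structure sharing the
    ensemble's atom roster.  Superposition and RMSD use the same selection.
    """
    idx = ensemble.select(selection)
    ref = _reference_coords(ensemble, reference, idx)
    w = ensemble.masses(idx) if mass_weighted else None
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        _, _, out[f] = kabsch(ensemble.frames[f, idx], ref, w)
    return out


def _superpose_all(coords: np.ndarray, ref: np.ndarray,
                   weights: np.ndarray | None) -> np.ndarray:
    fitted = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, t, _ = kabsch(coords[f], ref, weights)
        fitted[f] = coords[f] @ rot.T + t
    return fitted


def rmsf(ensemble: Ensemble, selection: str = "ca", mass_weighted: bool = False,
         return_keys: bool = False):
    """Per-residue RMSF (Angstrom) about the iterated mean structure.

    Frames are superposed onto the ensemble mean in two passes (superpose on
    the first-pass mean, recompute the mean, superpose again) to remove
    reference bias; rmsf_i = sqrt(<|r_i - <r_i>|^2>).  With multi-atom
    selections the per-atom fluctuations are RMS-averaged within a residue.

    Requires at least two frames.
    """
    if ensemble.n_frames < 2:
        raise ValueError("rmsf is undefined for a single-frame ensemble")
    idx = ensemble.select(selection)
    w = ensemble.masses(idx) if mass_weighted else None
    coords = ensemble.frames[:, idx]
    fitted = _superpose_all(coords, coords[0], w)
    for _ in range(2):
        mean = fitted.mean(axis=0)
        fitted = _superpose_all(coords, mean, w)
    mean = fitted.mean(axis=0)
    msf_atom = np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0)  # per atom

    keys = ensemble.residue_keys(idx)
    order: list[tuple[str, int, str]] = []
    groups: dict[tuple[str, int, str], list[int]] = {}
    for k, key in enumerate(keys):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(k)
    values = np.array([np.sqrt(np.mean(msf_atom[groups[key]])) for key in order])
    if return_keys:
        return order, values
    return values


def bfactor(rmsf_values: np.ndarray) -> np.ndarray:
    """Isotropic B-factor from RMSF: B = (8 pi^2 / 3) * rmsf^2 (A^2)."""
    arr = np.asarray(rmsf_values, float)
    if np.any(arr < 0):
        raise ValueError("rmsf must be non-negative")
    return BFACTOR_CONSTANT * arr ** 2


def flexibility_profile(ensemble: Ensemble, selection: str = "ca",
                        temperature_label: str = "",
                        mass_weighted: bool = False) -> FlexibilityProfile:
    """RMSF + B-factor profile of one ensemble (one condition/temperature)."""
    keys, fluct = rmsf(ensemble, selection, mass_weighted, return_keys=True)
    b = bfactor(fluct)
    return FlexibilityProfile(
        selection=selection, residue_keys=keys, rmsf=fluct, bfactor=b,
        mean_bfactor=float(b.mean()), temperature_label=temperature_label)


def fold_change(profile_low: FlexibilityProfile, profile_high: FlexibilityProfile
                ) -> tuple[float, np.ndarray]:
    """Mean-B fold change high/low plus the per-residue ratio vector.

    The scalar ratio is the thermostability proxy: how much the average
    B-factor inflates on heating (smaller = more rigid).
    """
    if profile_low.selection != profile_high.selection:
        raise ValueError("profiles use different selections")
    if profile_low.residue_keys != profile_high.residue_keys:
        raise ValueError("profiles cover different residues")
    if profile_low.mean_bfactor == 0:
        raise ZeroDivisionError("low-condition mean B-factor is zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_residue = profile_high.bfactor / profile_low.bfactor
    return profile_high.mean_bfactor / profile_low.mean_bfactor, per_residue
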