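"""Catalytic-distance analysis of enzyme-substrate ensembles.

For a deoxyribosyltransferase-type shared active site, the productive
(reaction-ready) complex is diagnosed by two distances measured per frame:

* d1 -- catalytic glutamate carboxylate oxygen (e.g. Glu98 OE1) to the
  substrate anomeric carbon C1'; must be below 3.45 A.
* d2 -- the C-terminal carboxyl proton of the neighbouring subunit's
  catalytic tyrosine (e.g. Tyr157#) to the substrate O4; must be below 2.5 A.

A frame is productive when *both* strict inequalities hold; the productive
fraction over an ensemble is the activity proxy used to rank variants.
Distances are frame-internal (no superposition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AtomSpec
from .ensemble import Ensemble

__all__ = [
    "DistanceSeries",
    "ProductivityReport",
    "distance_series",
    "classify_productive",
    "summarize",
    "distribution_overlap",
    "nearest_symmetry_mate",
]

#: default productive-complex thresholds (Angstrom): d1 < 3.45 and d2 < 2.5
THR_D1 = 3.45
THR_D2 = 2.5


@dataclass
class DistanceSeries:
    """A per-frame distance between two fixed atoms."""

    label: str
    endpoints: tuple[AtomSpec, AtomSpec]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("distance series must be a non-empty 1-D array")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ProductivityReport:
    """Per-frame productive-complex classification and aggregates."""

    thr_d1: float
    thr_d2: float
    per_frame_productive: np.ndarray
    fraction_productive: float
    mean_d1: float
    mean_d2: float

    def to_dict(self, include_frames: bool = False) -> dict:
        out = {
            "thr_d1": self.thr_d1,
            "thr_d2": self.thr_d2,
            "n_frames": int(len(self.per_frame_productive)),
            "fraction_productive": self.fraction_productive,
            "mean_d1": self.mean_d1,
            "mean_d2": self.mean_d2,
        }
        if include_frames:
            out["per_frame_productive"] = self.per_frame_productive.astype(bool).tolist()
        return out


def _atom_index(ensemble: Ensemble, spec: AtomSpec) -> int:
    matches = [i for i, (ch, seq, ic, name, _, _) in enumerate(ensemble.atom_table)
               if ch == spec.chain_id and seq == spec.resseq
               and ic == spec.icode and name == spec.atom_name]
    if len(matches) != 1:
        raise KeyError(
            f"atom spec {spec} resolves to {len(matches)} atoms in the topology "
            f"(need exactly 1)")
    return matches[0]


def distance_series(ensemble: Ensemble, spec_a: AtomSpec, spec_b: AtomSpec,
                    label: str = "") -> DistanceSeries:
    """Euclidean distance between two addressed atoms in every frame."""
    ia = _atom_index(ensemble, spec_a)
    ib = _atom_index(ensemble, spec_b)
    values = np.linalg.norm(ensemble.frames[:, ia] - ensemble.frames[:, ib], axis=1)
    return DistanceSeries(label=label or f"{spec_a}--{spec_b}",
                          endpoints=(spec_a, spec_b), values=values)


def nearest_symmetry_mate(ensemble: Ensemble, spec: AtomSpec,
                          partner: AtomSpec) -> AtomSpec:
    """Resolve a '#' (neighbouring-subunit) endpoint: among all chains carrying
    an atom with the residue number/name of `spec`, pick the chain whose copy
    is closest to `partner` in frame 1."""
    ip = _atom_index(ensemble, partner)
    best: tuple[float, AtomSpec] | None = None
    for i, (ch, seq, ic, name, _, _) in enumerate(ensemble.atom_table):
        if seq == spec.resseq and ic == spec.icode and name == spec.atom_name:
            d = float(np.linalg.norm(ensemble.frames[0, i] - ensemble.frames[0, ip]))
            cand = AtomSpec(ch, seq, ic, name)
            if best is None or d < best[0]:
                best = (d, cand)
    if best is None:
        raise KeyError(f"no atom {spec.atom_name!r} at residue {spec.resseq} in any chain")
    return best[1]


def classify_productive(d1: DistanceSeries, d2: DistanceSeries,
                        thr_d1: float = THR_D1, thr_d2: float = THR_D2
                        ) -> ProductivityReport:
    """Per-frame AND of the two strict threshold inequalities.

    A frame is productive iff d1 < thr_d1 and d2 < thr_d2 (strictly); values
    exactly at a threshold are non-productive.
    """
    if len(d1) != len(d2):
        raise ValueError(f"series length mismatch: {len(d1)} vs {len(d2)}")
    flags = (d1.values < thr_d1) & (d2.values < thr_d2)
    return ProductivityReport(
        thr_d1=thr_d1, thr_d2=thr_d2,
        per_frame_productive=flags,
        fraction_productive=float(np.count_nonzero(flags) / len(flags)),
        mean_d1=float(d1.values.mean()),
        mean_d2=float(d2.values.mean()),
    )


def _histogram(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Counts on left-closed right-open bins aligned to zero."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = int(np.floor(values.min() / bin_width))
    hi = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    idx = np.floor(values / bin_width).astype(int) - lo
    counts = np.bincount(idx, minlength=hi - lo).astype(float)
    return counts, edges


def summarize(series: DistanceSeries, bin_width: float = 0.1
              ) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Arithmetic mean, sample SD (ddof=1; 0 for a single frame) and a
    zero-aligned histogram (counts, edges) of a distance series."""
    v = series.values
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    return float(v.mean()), sd, _histogram(v, bin_width)


def distribution_overlap(series_a: DistanceSeries, series_b: DistanceSeries,
                         bin_width: float = 0.1) -> float:
    """Overlap coefficient OVL = sum over bins of min(p, q) in [0, 1].

    Both series are histogrammed on the same zero-aligned grid spanning the
    union of their ranges and normalised to unit mass; identical histograms
    give 1, disjoint supports give 0.
    """
    va, vb = series_a.values, series_b.values
    lo = int(np.floor(min(va.min(), vb.min()) / bin_width))
    hi = int(np.floor(max(va.max(), vb.max()) / bin_width)) + 1
    n_bins = hi - lo
    pa = np.bincount(np.floor(va / bin_width).astype(int) - lo,
                     minlength=n_bins).astype(float)
    pb = np.bincount(np.floor(vb / bin_width).astype(int) - lo,
                     minlength=n_bins).astype(float)
    pa /= pa.sum()
    pb /= pb.sum()
    return float(np.minimum(pa, pb).sum())
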