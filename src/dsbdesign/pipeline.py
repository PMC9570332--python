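"""End-to-end design pipeline: symmetry detection -> disulfide scan ->
optional ensemble flexibility and catalytic-geometry analytics, driven by a
single YAML config and writing machine-readable reports plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalytic import classify_productive, distance_series
from .core import AtomSpec
from .ensemble import flexibility_profile, fold_change, rmsd_series
from .scanner import ScanConfig, scan
from .structure_io import read_ensemble, read_structure
from .symmetry import detect_symmetry

__all__ = ["PipelineConfig", "run_pipeline", "profile_to_frame"]

log = logging.getLogger("dsbdesign")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see `from_yaml`)."""

    structure: str
    output_dir: str = "dsbdesign_out"
    scan: ScanConfig = field(default_factory=ScanConfig)
    rmsd_threshold: float = 2.0
    contact_cutoff: float = 8.0
    selection: str = "ca"
    ensemble_low: Optional[str] = None
    ensemble_high: Optional[str] = None
    catalytic_ensemble: Optional[str] = None
    d1: Optional[tuple[str, str]] = None
    d2: Optional[tuple[str, str]] = None
    thr_d1: float = 3.45
    thr_d2: float = 2.5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        scan_raw = dict(raw.pop("scan", {}))
        if "chi1_step" in scan_raw:
            step = float(scan_raw.pop("chi1_step"))
            scan_raw["chi1_grid"] = np.arange(-180.0, 180.0, step)
        ens = raw.pop("ensembles", {}) or {}
        cat = raw.pop("catalytic", {}) or {}
        kwargs = dict(raw)
        kwargs["scan"] = ScanConfig(**scan_raw)
        kwargs["ensemble_low"] = ens.get("low")
        kwargs["ensemble_high"] = ens.get("high")
        if cat:
            kwargs["catalytic_ensemble"] = cat.get("ensemble")
            kwargs["d1"] = tuple(cat["d1"]) if "d1" in cat else None
            kwargs["d2"] = tuple(cat["d2"]) if "d2" in cat else None
            kwargs["thr_d1"] = float(cat.get("thr_d1", 3.45))
            kwargs["thr_d2"] = float(cat.get("thr_d2", 2.5))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "output_dir": self.output_dir,
            "scan": {
                "ca_min": self.scan.ca_min, "ca_max": self.scan.ca_max,
                "ideal_ss": self.scan.ideal_ss, "ideal_angle": self.scan.ideal_angle,
                "ideal_chi_ss": self.scan.ideal_chi_ss,
                "weights": list(self.scan.weights),
                "score_cutoff": self.scan.score_cutoff,
                "chi1_grid": self.scan.chi1_grid.tolist(),
            },
            "rmsd_threshold": self.rmsd_threshold,
            "contact_cutoff": self.contact_cutoff,
            "selection": self.selection,
            "ensembles": {"low": self.ensemble_low, "high": self.ensemble_high},
            "catalytic": {"ensemble": self.catalytic_ensemble,
                          "d1": list(self.d1) if self.d1 else None,
                          "d2": list(self.d2) if self.d2 else None,
                          "thr_d1": self.thr_d1, "thr_d2": self.thr_d2},
            "seed": self.seed,
            "log_level": self.log_level,
        }


def candidates_to_frame(candidates) -> pd.DataFrame:
    return pd.DataFrame([c.as_row() for c in candidates], columns=[
        "chain_a", "res_a", "name_a", "chain_b", "res_b", "name_b",
        "d_ca", "d_cb", "d_ss", "chi_ss", "score", "locality",
        "multiplicity", "mutations"])


def profile_to_frame(profile) -> pd.DataFrame:
    return pd.DataFrame({
        "chain": [k[0] for k in profile.residue_keys],
        "resseq": [k[1] for k in profile.residue_keys],
        "rmsf_A": np.round(profile.rmsf, 6),
        "bfactor_A2": np.round(profile.bfactor, 6),
    })


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute the configured stages; returns {artifact name: path}.

    Always: symmetry.json and candidates.tsv.  With ensembles configured:
    profiles.tsv (+ foldchange.json when both conditions are given).  With
    catalytic endpoints configured: productivity.json.  A manifest.json
    (version, config, config hash, seed) is always written.
    """
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    log.info("stage symmetry: reading %s", config.structure)
    structure = read_structure(config.structure)
    if len(structure.chains) >= 2:
        sym = detect_symmetry(structure, config.rmsd_threshold,
                              contact_cutoff=config.contact_cutoff)
    else:
        from .symmetry import SymmetryMap
        sym = SymmetryMap([[c.chain_id] for c in structure.chains], {}, 1, [])
    path = out / "symmetry.json"
    path.write_text(json.dumps(sym.to_dict(), indent=2) + "\n")
    artifacts["symmetry"] = str(path)
    log.info("symmetry order %d, %d dimer(s)", sym.symmetry_order, len(sym.dimers))

    log.info("stage scan")
    candidates = scan(structure, config.scan, sym)
    path = out / "candidates.tsv"
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)
    artifacts["candidates"] = str(path)
    log.info("%d candidate(s) within score cutoff", len(candidates))

    profiles = {}
    for label, src in (("low", config.ensemble_low), ("high", config.ensemble_high)):
        if src is None:
            continue
        log.info("stage flexibility (%s): %s", label, src)
        ens = read_ensemble(src)
        prof = flexibility_profile(ens, config.selection, temperature_label=label)
        profiles[label] = prof
        frame = profile_to_frame(prof)
        frame["rmsd_mean_A"] = np.round(float(rmsd_series(
            ens, selection=config.selection).mean()), 6)
        frame["condition"] = label
        if "profiles" in artifacts:
            frame.to_csv(artifacts["profiles"], sep="\t", index=False,
                         mode="a", header=False)
        else:
            path = out / "profiles.tsv"
            frame.to_csv(path, sep="\t", index=False)
            artifacts["profiles"] = str(path)
    if len(profiles) == 2:
        ratio, per_res = fold_change(profiles["low"], profiles["high"])
        path = out / "foldchange.json"
        path.write_text(json.dumps({
            "mean_bfactor_low": profiles["low"].mean_bfactor,
            "mean_bfactor_high": profiles["high"].mean_bfactor,
            "fold_change": ratio,
            "per_residue": np.round(per_res, 6).tolist(),
        }, indent=2) + "\n")
        artifacts["foldchange"] = str(path)

    if config.catalytic_ensemble and config.d1 and config.d2:
        log.info("stage catalytic geometry: %s", config.catalytic_ensemble)
        ens = read_ensemble(config.catalytic_ensemble)
        s1 = distance_series(ens, AtomSpec.parse(config.d1[0]),
                             AtomSpec.parse(config.d1[1]), "d1")
        s2 = distance_series(ens, AtomSpec.parse(config.d2[0]),
                             AtomSpec.parse(config.d2[1]), "d2")
        report = classify_productive(s1, s2, config.thr_d1, config.thr_d2)
        path = out / "productivity.json"
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
        artifacts["productivity"] = str(path)

    config_doc = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_doc.encode()).hexdigest(),
        "artifacts": artifacts,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    artifacts["manifest"] = str(path)
    return artifacts
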