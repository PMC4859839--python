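"""End-to-end orchestration: synthesize → trajectory statistics →
representative frame → dimer decomposition → component statistics.

Each stage consumes and produces only declared files inside the artifact
directory; a manifest JSON records the seed, thresholds, per-stage wall
times and SHA-256 checksums of every emitted file, so two runs with the
same configuration are byte-identical and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, templates
from .eda import decompose
from .frame_selection import select_representative
from .fragments import write_dimer_xyz
from .interaction_stats import (AMINO_ACID_EXCLUDE, ComponentTable,
                                correlation_table, covalency_report,
                                load_reference_components)
from .synthetic_data import (DimerScanSpec, HBondSpec, RingSpec,
                             load_hbond_specs, make_dimer_scan,
                             make_hbond_trajectory, write_pdb_trajectory)
from .trajectory_stats import (DEFAULT_OCCUPANCY_CUTOFF,
                               DEFAULT_RING_THRESHOLD, fraction_below,
                               hbond_series, occupancy, bin_hbond_series,
                               ring_centroid_series, write_histogram_csv,
                               RingPair)

log = logging.getLogger("pocket_eda.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; earlier outputs are preserved."""


DEFAULT_SPECS = {
    "n_frames": 2000,
    "hbonds": [
        {"bond_id": "ILE117", "mixture": [[0.75, 2.35, 0.25],
                                          [0.25, 2.9, 0.25]]},
        {"bond_id": "ASP118_O1", "mixture": [[0.55, 1.85, 0.12],
                                             [0.45, 2.9, 0.45]]},
        {"bond_id": "ASN248", "mixture": [[1.0, 2.15, 0.2]]},
        {"bond_id": "LEU249", "mixture": [[1.0, 2.2, 0.22]]},
        {"bond_id": "ALA33", "mixture": [[1.0, 2.1, 0.18]]},
    ],
    "rings": [
        {"ring_id": "PHE44", "mixture": [[0.5, 4.6, 0.35],
                                         [0.5, 5.6, 0.6]]},
    ],
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (thresholds in Å / dimensionless)."""

    outdir: Path
    seed: int = 2016
    specs: dict = field(default_factory=lambda: DEFAULT_SPECS)
    occupancy_cutoff: float = DEFAULT_OCCUPANCY_CUTOFF
    ring_threshold: float = DEFAULT_RING_THRESHOLD
    covalency_threshold: float = 0.45
    basis: str = "STO-3G"
    component_table: Path | None = None     # default: packaged reference
    stages: tuple[str, ...] = ("synth", "hbonds", "select", "decompose",
                               "stats")

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.occupancy_cutoff <= 0 or self.ring_threshold <= 0 \
                or self.covalency_threshold <= 0:
            raise PipelineError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["outdir"] = Path(raw.get("outdir", "pocket_eda_out"))
        if "component_table" in raw and raw["component_table"]:
            raw["component_table"] = Path(raw["component_table"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest (also written as
    manifest.json in the artifact directory)."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "thresholds": {"occupancy_cutoff": config.occupancy_cutoff,
                               "ring_threshold": config.ring_threshold,
                               "covalency_threshold":
                                   config.covalency_threshold},
                "basis": config.basis, "stages": {}}
    state: dict = {}
    for stage in config.stages:
        fn = _STAGES.get(stage)
        if fn is None:
            raise PipelineError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        try:
            files = fn(config, state)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        rec = {"seconds": round(dt, 3),
               "files": {f.name: _sha256(f) for f in files}}
        manifest["stages"][stage] = rec
        log.info("stage %-10s %6.2fs  %s", stage, dt,
                 " ".join(f.name for f in files))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _stage_synth(cfg: PipelineConfig, state: dict) -> list[Path]:
    hb, rg = load_hbond_specs(cfg.specs)
    traj = make_hbond_trajectory(hb, seed=cfg.seed, ring_specs=rg)
    state["trajectory"] = traj
    path = cfg.outdir / "trajectory.pdb"
    write_pdb_trajectory(traj, path)
    return [path]


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise PipelineError(f"stage {stage!r} needs output of an earlier "
                            f"stage ({key}) that did not run")
    return state[key]


def _stage_hbonds(cfg: PipelineConfig, state: dict) -> list[Path]:
    traj = _require(state, "trajectory", "hbonds")
    series = [hbond_series(traj, pair, bond_id=bid)
              for bid, pair in traj.monitored_pairs.items()]
    tables = [bin_hbond_series(s) for s in series]
    state["hbond_series"] = series
    ring = {}
    for rid, (ra, rb) in traj.ring_pairs.items():
        ring[rid] = ring_centroid_series(traj, RingPair(ra, rb))
    state["ring_series"] = ring
    t1 = cfg.outdir / "hbond_frequencies.csv"
    write_histogram_csv(tables, t1)
    occ = {s.bond_id: round(occupancy(s, cfg.occupancy_cutoff), 1)
           for s in series}
    ring_frac = {rid: round(100 * fraction_below(v, cfg.ring_threshold), 1)
                 for rid, v in ring.items()}
    t2 = cfg.outdir / "occupancy.json"
    t2.write_text(json.dumps(
        {"occupancy_percent": occ, "cutoff": cfg.occupancy_cutoff,
         "ring_contact_percent": ring_frac,
         "ring_threshold": cfg.ring_threshold}, indent=2) + "\n")
    return [t1, t2]


def _stage_select(cfg: PipelineConfig, state: dict) -> list[Path]:
    traj = _require(state, "trajectory", "select")
    series = _require(state, "hbond_series", "select")
    report = select_representative(series, state.get("ring_series", {}))
    state["selection"] = report
    p1 = cfg.outdir / "selection.json"
    p1.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    chosen = traj.frames[report.chosen_frame]
    single = type(traj)(chosen[None, :, :], traj.atom_labels,
                        traj.monitored_pairs, traj.ring_pairs)
    p2 = cfg.outdir / "representative_frame.pdb"
    write_pdb_trajectory(single, p2)
    return [p1, p2]


def _stage_decompose(cfg: PipelineConfig, state: dict) -> list[Path]:
    # demo-scale decomposition: hydrogen-bonded water dimer
    dimer = make_dimer_scan(DimerScanSpec(
        templates.water("donor"), templates.water("acceptor"),
        separations=(3.0,), basis_name=cfg.basis))[0]
    res = decompose(dimer, label="water-dimer")
    state["eda_result"] = res
    p1 = cfg.outdir / "eda_water_dimer.json"
    res.to_json(p1)
    p2 = cfg.outdir / "dimer.xyz"
    write_dimer_xyz(dimer, p2)
    return [p1, p2]


def _stage_stats(cfg: PipelineConfig, state: dict) -> list[Path]:
    if cfg.component_table is not None:
        table = ComponentTable.from_csv(cfg.component_table)
    else:
        table = load_reference_components()
    corr = correlation_table(table, exclude=AMINO_ACID_EXCLUDE)
    cov = covalency_report(table, threshold=cfg.covalency_threshold)
    p1 = cfg.outdir / "component_correlations.csv"
    corr.to_csv(p1)
    p2 = cfg.outdir / "covalency.csv"
    cov.to_csv(p2)
    state["correlations"], state["covalency"] = corr, cov
    return [p1, p2]


_STAGES = {"synth": _stage_synth, "hbonds": _stage_hbonds,
           "select": _stage_select, "decompose": _stage_decompose,
           "stats": _stage_stats}
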