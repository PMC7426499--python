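"""End-to-end cohort runs and small utilities.

:func:`run_cohort` drives the simulate → (optionally render → track) →
quantize → profile → compare chain for a multi-group cohort described by
one flat configuration mapping, writing all intermediate tables plus a
manifest with parameters, seed and file checksums.  Rerunning with the
same configuration and seed reproduces byte-identical outputs.

:func:`tissue_conc_to_molar` converts a tissue mass concentration
(μg analyte per g fresh weight) into a molar concentration (mM), assuming
a tissue density near 1 g/mL; e.g. 396 μg/g of 3-hydroxykynurenine
(molar mass 224.21 g/mol) is about 1.77 mM.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .group_stats import build_comparison_table, summary_table
from .io import trajectory_from_ground_truth, write_trajectory
from .sla import AnalysisConfig, compute_profile, quantize, segment_bouts
from .synthetic import RenderParams, WalkerParams, render_frames, simulate_walker
from .tracking import Calibration, track_frames

__all__ = ["run_cohort", "tissue_conc_to_molar", "MOLAR_MASS_3HOK", "simulate_fly_profile"]

#: Molar mass of 3-hydroxykynurenine, g/mol.
MOLAR_MASS_3HOK = 224.21

SLA_PARAMETERS = ["index_of_activity", "run_frequency", "running_speed",
                  "total_speed", "run_bout_time", "centrophobia_index"]


def tissue_conc_to_molar(mass_conc: float, molar_mass: float,
                         density: float = 1.0) -> float:
    """Convert μg analyte per g fresh tissue to mM.

    ``mass_conc`` [μg/g] × ``density`` [g/mL] / ``molar_mass`` [g/mol]
    gives μmol/mL ÷ 1000 … i.e. exactly mmol/L, so the expression returns
    millimolar directly.
    """
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    if mass_conc < 0 or density <= 0:
        raise ValueError("mass concentration must be >= 0 and density > 0")
    return mass_conc * density / molar_mass


def _fly_seed(base_seed: int, index: int) -> int:
    # deterministic, collision-free per fly, kept below 2**31
    return int((base_seed * 1_000_003 + index) % (2 ** 31 - 1))


def simulate_fly_profile(params: WalkerParams, cfg: AnalysisConfig,
                         fly_id: Optional[str] = None,
                         render: Optional[RenderParams] = None,
                         threshold: float = 60.0):
    """Simulate one fly and score it; optionally round-trip through rendering.

    With ``render`` given, frames are rendered and re-tracked with the
    threshold-centroid tracker instead of scoring the generative positions
    directly (slower; exercises the full measurement chain).
    """
    truth = simulate_walker(params)
    if render is not None:
        frames = render_frames(truth, render, seed=params.seed)
        cal = Calibration(mm_per_pixel=render.mm_per_pixel,
                          arena_center=(render.center_px, render.center_px),
                          arena_radius_px=params.arena_radius / render.mm_per_pixel)
        traj = track_frames(frames, cal, threshold=threshold,
                            frame_rate=params.frame_rate)
    else:
        traj = trajectory_from_ground_truth(truth)
    qt = quantize(traj, cfg)
    profile = compute_profile(qt, segment_bouts(qt), cfg, fly_id=fly_id)
    return profile, truth, traj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_cohort(config: Union[dict, str, Path], outdir) -> dict:
    """Run a full simulated cohort and write profiles, stats and a manifest.

    ``config`` is a mapping (or path to a JSON/YAML file) with keys:

    ``seed``
        master seed; every fly's seed derives from it.
    ``groups``
        list of ``{"strain": str, "age": number, "n_flies": int,
        "walker": {...overrides...}}``.
    ``walker``
        shared :class:`WalkerParams` overrides (optional).
    ``analysis``
        :class:`AnalysisConfig` overrides (optional).
    ``baseline_age``
        age used for within-strain baseline comparisons (optional).
    ``parameters``
        SLA parameters to compare (default: all six).

    Returns a dict with the profiles / summary / comparison DataFrames and
    the manifest.  Files written: ``profiles.csv``, ``summary.csv``,
    ``comparison.csv``, ``manifest.json`` and per-fly trajectories under
    ``trajectories/`` when ``save_trajectories`` is true.
    """
    if not isinstance(config, dict):
        cfg_path = Path(config)
        if not cfg_path.exists():
            raise FileNotFoundError(f"configuration file {cfg_path} does not exist")
        text = cfg_path.read_text()
        if cfg_path.suffix in (".yaml", ".yml"):
            import yaml
            config = yaml.safe_load(text)
        else:
            config = json.loads(text)
    for key in ("groups",):
        if key not in config:
            raise ValueError(f"configuration missing required key {key!r}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    analysis = AnalysisConfig(**config.get("analysis", {}))
    shared_walker = dict(config.get("walker", {}))
    parameters = config.get("parameters", SLA_PARAMETERS)
    save_traj = bool(config.get("save_trajectories", False))
    if save_traj:
        (outdir / "trajectories").mkdir(exist_ok=True)

    rows = []
    fly_index = 0
    for group in config["groups"]:
        strain = group["strain"]
        age = group.get("age", 0)
        overrides = {**shared_walker, **group.get("walker", {})}
        for j in range(int(group["n_flies"])):
            fly_id = f"{strain}_a{age}_f{j:03d}"
            params = WalkerParams(**{**overrides, "seed": _fly_seed(seed, fly_index)})
            fly_index += 1
            profile, _, traj = simulate_fly_profile(params, analysis, fly_id=fly_id)
            if save_traj:
                write_trajectory(traj, outdir / "trajectories" / f"{fly_id}.csv")
            row = profile.as_dict()
            row.update({"strain": strain, "age": age, "seed": params.seed})
            rows.append(row)

    profiles = pd.DataFrame(rows)
    summary = summary_table(profiles, parameters)
    ages = set(profiles["age"])
    strains = set(profiles["strain"])
    comparison = None
    if len(strains) > 1 or len(ages) > 1:
        comparison = build_comparison_table(
            profiles, parameters, baseline_age=config.get("baseline_age"))

    files = {}
    profiles.to_csv(outdir / "profiles.csv", index=False)
    files["profiles.csv"] = _sha256(outdir / "profiles.csv")
    summary.to_csv(outdir / "summary.csv", index=False)
    files["summary.csv"] = _sha256(outdir / "summary.csv")
    if comparison is not None:
        comparison.to_csv(outdir / "comparison.csv", index=False)
        files["comparison.csv"] = _sha256(outdir / "comparison.csv")

    manifest = {
        "seed": seed,
        "config": config,
        "analysis": dataclasses.asdict(analysis),
        "n_flies": fly_index,
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return {"profiles": profiles, "summary": summary, "comparison": comparison,
            "manifest": manifest}
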