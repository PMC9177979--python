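"""End-to-end analysis pipeline: trajectory -> frames -> observables -> report.

Mirrors the measurement workflow: twist and conformational observables are
computed per frame, block-averaged after an equilibration discard, and
reported as changes relative to a reference condition; ion frames, when
present in the input, are profiled radially and by binding site.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .frames import end_to_end_twist, twist_profile
from .helix_params import block_average, helix_profile
from .io import (
    PipelineConfig,
    read_structure,
    write_json,
    write_twist_csv,
)
from .ion_atmosphere import radial_profile, site_occupancy

log = logging.getLogger("salt_twist")


def _config_hash(config: PipelineConfig) -> str:
    payload = repr(sorted(vars(config).items())).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _summarize(profile, times, config: PipelineConfig) -> dict:
    """Block-averaged mean +/- SE for each observable column, when possible."""
    out = {}
    for col in ("twist_deg_bp", "h", "beta_deg", "radius_A", "pucker_deg", "groove_A"):
        if col not in profile:
            continue
        series = profile[col].to_numpy()
        try:
            ba = block_average(series, times, config.block_ns, config.equilibration_ns)
            out[col] = {"mean": ba.mean, "se": ba.se, "n_blocks": ba.n_blocks}
        except ValueError:
            # short trajectory: plain mean +/- SE of the mean, flagged
            se = float(series.std(ddof=1) / np.sqrt(len(series))) if len(series) > 1 else 0.0
            out[col] = {"mean": float(series.mean()), "se": se, "n_blocks": 0}
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis described by ``config`` and write its outputs.

    Returns the summary report (also written as JSON): block-averaged
    observables of the sample condition, of the reference condition, and
    their differences (sample minus reference).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
    }
    conditions = {}
    for label, path in (("sample", config.sample), ("reference", config.reference)):
        log.info("stage read_structure[%s]: %s", label, path)
        try:
            traj, ions = read_structure(path)
        except Exception as exc:
            raise RuntimeError(f"stage read_structure[{label}] failed: {exc}") from exc
        log.info("stage helix_profile[%s]: %d frames, %d bp", label, traj.n_frames, traj.n_bp)
        try:
            profile = helix_profile(traj)
        except Exception as exc:
            raise RuntimeError(f"stage helix_profile[{label}] failed: {exc}") from exc
        profile.to_csv(out_dir / f"profile_{label}.csv", index=False)
        series = end_to_end_twist(traj, terminal_k=config.terminal_k)
        write_twist_csv(out_dir / f"twist_{label}.csv", series)
        for method in ("bp_twist", "local_helical"):
            write_twist_csv(out_dir / f"twist_{method}_{label}.csv", twist_profile(traj, method))
        conditions[label] = _summarize(profile, traj.times_ns, config)
        if ions is not None:
            log.info("stage ion_atmosphere[%s]: %d ions", label, ions.n_ions)
            try:
                edges = np.arange(0.0, config.radial_max_A + config.radial_bin_A / 2, config.radial_bin_A)
                prof = radial_profile(ions, traj, bin_edges=edges)
                prof.to_dataframe().to_csv(out_dir / f"radial_{label}.csv", index=False)
                occ = site_occupancy(ions, traj, cutoff=config.site_cutoff_A)
                occ.to_csv(out_dir / f"occupancy_{label}.csv", index=False)
                conditions[label]["ions"] = {
                    "species": prof.species,
                    "out_of_range": prof.n_out_of_range,
                }
            except Exception as exc:
                raise RuntimeError(f"stage ion_atmosphere[{label}] failed: {exc}") from exc
    report["conditions"] = conditions
    deltas = {}
    for col, stats in conditions["sample"].items():
        if col == "ions" or col not in conditions["reference"]:
            continue
        ref = conditions["reference"][col]
        deltas[f"delta_{col}"] = {
            "value": stats["mean"] - ref["mean"],
            "se": float(np.hypot(stats["se"], ref["se"])),
        }
    report["deltas"] = deltas
    write_json(out_dir / "summary.json", report)
    log.info("pipeline done: %s", out_dir / "summary.json")
    return report
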