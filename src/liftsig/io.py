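"""On-disk contracts: raw-trial CSVs + manifest, processed-trial CSV.

A raw dataset directory contains one CSV per trial and a ``manifest.json``
with participant metadata, labels, and the generator parameters used (for
provenance).  Marker and force streams run at different rates, so each trial
CSV carries two time columns: marker rows fill the first 600-odd rows, the
force grid spans the whole file, and absent marker cells are empty.  Any
directory matching this contract — including exports of real recordings —
can be read back, so the preprocessing stage is data-source agnostic.

The processed-trials file is a single long-format CSV: one row per (trial,
channel, percent-of-movement point).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CHANNELS, N_POINTS, ProcessedTrial
from .synthgen import GenParams, RawTrial

__all__ = [
    "write_raw_dataset",
    "read_raw_dataset",
    "write_processed",
    "read_processed",
    "write_exclusions",
]

_MARKER_COLS = ["ml_ap", "ml_ml", "ml_v", "mr_ap", "mr_ml", "mr_v"]
_FORCE_COLS = ["p1_ap", "p1_ml", "p1_v", "p2_ap", "p2_ml", "p2_v"]


def _trial_filename(trial: RawTrial) -> str:
    return f"trial_{trial.key}.csv"


def write_raw_dataset(trials: list[RawTrial], outdir: str | Path,
                      params: GenParams | None = None) -> Path:
    """Write one CSV per trial plus a dataset manifest; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in trials:
        n_m = trial.marker_left.shape[0]
        n_f = trial.grf_plate1.shape[0]
        n = max(n_m, n_f)
        df = pd.DataFrame(index=range(n))
        df["time_marker_s"] = np.r_[np.arange(n_m) / trial.marker_fs,
                                    np.full(n - n_m, np.nan)]
        marker = np.hstack([trial.marker_left, trial.marker_right])
        for j, col in enumerate(_MARKER_COLS):
            df[col] = np.r_[marker[:, j], np.full(n - n_m, np.nan)]
        df["time_force_s"] = np.r_[np.arange(n_f) / trial.force_fs,
                                   np.full(n - n_f, np.nan)]
        force = np.hstack([trial.grf_plate1, trial.grf_plate2])
        for j, col in enumerate(_FORCE_COLS):
            df[col] = np.r_[force[:, j], np.full(n - n_f, np.nan)]
        fname = _trial_filename(trial)
        df.to_csv(outdir / fname, index=False, float_format="%.9g")
        entries.append({
            "file": fname,
            "participant_id": trial.participant_id,
            "condition": trial.condition,
            "trial_index": trial.trial_index,
            "body_height": trial.body_height,
            "body_mass": trial.body_mass,
            "barbell_mass": trial.barbell_mass,
            "marker_fs": trial.marker_fs,
            "force_fs": trial.force_fs,
        })
    manifest = {"trials": entries}
    if params is not None:
        d = dataclasses.asdict(params)
        d["theta_0"] = dict(d["theta_0"])
        manifest["generator_params"] = d
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_raw_dataset(indir: str | Path) -> list[RawTrial]:
    """Read a raw dataset directory written by :func:`write_raw_dataset`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    trials = []
    for entry in manifest["trials"]:
        df = pd.read_csv(indir / entry["file"])
        m_mask = df["time_marker_s"].notna().to_numpy()
        f_mask = df["time_force_s"].notna().to_numpy()
        marker = df.loc[m_mask, _MARKER_COLS].to_numpy(dtype=float)
        force = df.loc[f_mask, _FORCE_COLS].to_numpy(dtype=float)
        trials.append(RawTrial(
            marker_left=marker[:, :3], marker_right=marker[:, 3:],
            grf_plate1=force[:, :3], grf_plate2=force[:, 3:],
            marker_fs=float(entry["marker_fs"]), force_fs=float(entry["force_fs"]),
            body_height=float(entry["body_height"]),
            body_mass=float(entry["body_mass"]),
            barbell_mass=float(entry["barbell_mass"]),
            participant_id=int(entry["participant_id"]),
            condition=str(entry["condition"]),
            trial_index=int(entry["trial_index"]),
        ))
    return trials


def write_processed(trials: list[ProcessedTrial], path: str | Path) -> Path:
    """Write processed trials as one long-format CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pct = np.linspace(0, 100, N_POINTS)
    frames = []
    for trial in trials:
        for ch in CHANNELS:
            frames.append(pd.DataFrame({
                "participant_id": trial.participant_id,
                "condition": trial.condition,
                "trial_index": trial.trial_index,
                "channel": ch,
                "percent": pct,
                "value": trial.channels[ch],
                "start_time_s": trial.start_time_s,
                "catch_time_s": trial.catch_time_s,
                "peak_time_s": trial.peak_time_s,
                "body_height": trial.body_height,
                "body_mass": trial.body_mass,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.9g")
    return path


def read_processed(path: str | Path) -> list[ProcessedTrial]:
    """Read a processed-trials CSV back into :class:`ProcessedTrial` records."""
    df = pd.read_csv(path)
    trials = []
    keys = ["participant_id", "condition", "trial_index"]
    for (pid, cond, tix), grp in df.groupby(keys, sort=True):
        channels = {}
        for ch, sub in grp.groupby("channel"):
            channels[ch] = sub.sort_values("percent")["value"].to_numpy(dtype=float)
        first = grp.iloc[0]
        trials.append(ProcessedTrial(
            channels=channels, participant_id=int(pid), condition=str(cond),
            trial_index=int(tix),
            start_time_s=float(first["start_time_s"]),
            catch_time_s=float(first["catch_time_s"]),
            peak_time_s=float(first["peak_time_s"]),
            body_height=float(first["body_height"]),
            body_mass=float(first["body_mass"]),
        ))
    return trials


def write_exclusions(exclusions: list[tuple[str, str]], path: str | Path) -> Path:
    """Write the exclusions log (trial key, reason) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(exclusions, columns=["trial", "reason"]).to_csv(path, index=False)
    return path
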