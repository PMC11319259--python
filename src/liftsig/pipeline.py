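"""End-to-end orchestration: synth -> preprocess -> classify -> explain.

``run_all`` executes the whole pipeline from a :class:`RunConfig`, writing
accuracy tables (one CSV per task, rows = input combinations, column groups
= scaling x fold), per-trial predictions, relevance-profile CSVs for the
participant task, an exclusions log, the archived config, and a summary
JSON.  All randomness flows from the single config seed, so re-running with
the archived config reproduces every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .classify import run_experiment, zero_rule_accuracy
from .features import SCALINGS, combo_registry, get_combo
from .preprocess import process_dataset
from .synthgen import GenParams, generate_dataset

__all__ = ["RunConfig", "run_all", "accuracy_table"]

log = logging.getLogger(__name__)

#: Combos profiled with LRP by default: the three paired-channel inputs.
DEFAULT_LRP_COMBOS = ("Position.AP, Position.V",
                      "Velocity.AP, Velocity.V",
                      "GRF.AP, GRF.V")


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    seed: int = 0
    generator: dict = field(default_factory=dict)   # GenParams overrides
    tasks: list = field(default_factory=lambda: ["participant", "model"])
    combos: object = "all"                          # "all" or list of names
    scalings: object = "all"                        # "all" or list of kinds
    lrp_combos: list = field(default_factory=lambda: list(DEFAULT_LRP_COMBOS))
    outdir: str = "liftsig_run"
    group_map: list | None = None

    def gen_params(self) -> GenParams:
        return GenParams(seed=self.seed, **self.generator)

    def combo_names(self) -> list[str]:
        if self.combos == "all":
            return [c.name for c in combo_registry()]
        return list(self.combos)

    def scaling_kinds(self) -> tuple[str, ...]:
        if self.scalings == "all":
            return SCALINGS
        return tuple(self.scalings)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output path is excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def accuracy_table(reports) -> pd.DataFrame:
    """Flatten accuracy reports into a table mirroring the reporting layout.

    Rows = input combinations; columns = per-scaling fold accuracies and
    mean +/- SD, then the averaged accuracy over all fold x scaling values.
    """
    rows = []
    for rep in reports:
        row = {"combo": rep.combo_name}
        for s in rep.scalings:
            for lbl, acc, n_ok, n in zip(rep.fold_labels, rep.accuracies[s],
                                         rep.correct[s], rep.test_sizes):
                row[f"{s}:fold_{lbl}"] = round(float(acc), 1)
                row[f"{s}:correct_{lbl}"] = f"{int(n_ok)}/{int(n)}"
            m, sd = rep.scaling_mean_sd(s)
            row[f"{s}:mean"] = round(m, 1)
            row[f"{s}:sd"] = round(sd, 1)
        row["averaged_accuracy"] = round(rep.averaged_accuracy, 1)
        row["averaged_sd"] = round(rep.averaged_sd, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def _slug(name: str) -> str:
    return name.lower().replace(".", "").replace(",", "").replace(" ", "_")


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts under the output dir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    params = config.gen_params()
    log.info("stage=synth seed=%d participants=%d", config.seed, params.n_participants)
    raws = generate_dataset(params)
    processed, exclusions = process_dataset(raws)
    log.info("stage=preprocess in=%d retained=%d excluded=%d",
             len(raws), len(processed), len(exclusions))
    _io.write_exclusions(exclusions, outdir / "exclusions.csv")

    scalings = config.scaling_kinds()
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash,
        "n_trials_raw": len(raws),
        "n_trials_retained": len(processed),
        "n_trials_excluded": len(exclusions),
        "tasks": {},
    }
    for task in config.tasks:
        reports = []
        predictions = []
        for name in config.combo_names():
            rep, preds = run_experiment(processed, task, get_combo(name),
                                        scalings=scalings,
                                        group_map=config.group_map,
                                        collect_predictions=True)
            for s in scalings:
                for lbl, acc in zip(rep.fold_labels, rep.accuracies[s]):
                    log.info("stage=classify task=%s combo=%r scaling=%s fold=%s "
                             "accuracy=%.1f", task, name, s, lbl, acc)
            reports.append(rep)
            predictions.extend(preds)
        table = accuracy_table(reports)
        table.insert(0, "config_hash", config.config_hash)
        table.insert(0, "seed", config.seed)
        table.to_csv(outdir / f"accuracy_{task}.csv", index=False)
        (outdir / f"predictions_{task}.json").write_text(
            json.dumps({"seed": config.seed, "config_hash": config.config_hash,
                        "predictions": predictions}, indent=1))
        summary["tasks"][task] = {
            "n_configurations": len(reports) * len(scalings),
            "zero_rule_pct": round(zero_rule_accuracy(processed, task,
                                                      config.group_map), 1),
            "averaged_accuracy": {r.combo_name: round(r.averaged_accuracy, 1)
                                  for r in reports},
        }

    if "participant" in config.tasks and config.lrp_combos:
        from .lrp import profile_to_frame, relevance_profile

        for name in config.lrp_combos:
            for s in scalings:
                prof = relevance_profile(processed, get_combo(name), s,
                                         task="participant",
                                         group_map=config.group_map)
                frame = profile_to_frame(prof)
                frame.insert(0, "config_hash", config.config_hash)
                frame.insert(0, "seed", config.seed)
                frame.to_csv(outdir / f"relevance_{_slug(name)}_{s}.csv",
                             index=False, float_format="%.9g")
                log.info("stage=explain combo=%r scaling=%s trials=%d",
                         name, s, prof.n_trials)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
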