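"""End-to-end orchestration: atlas -> connectomes -> controllability -> stats.

Stages run in a fixed order; each stage logs its row counts, failures abort
with a stage-tagged error, and partial outputs already written are retained.
All outputs are flat CSV plus one JSON report with provenance (config hash,
seed, package version) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import atlas as atlas_mod
from .atlas import assign_systems, load_overlaps, load_parcellation
from .connectome import load_connectome
from .controllability import controllability_table
from .stats import ControllabilityAgeModel, demographics_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class RunConfig:
    atlas_path: str
    overlap_path: str
    cohort_csv: str
    connectome_dir: str
    out_dir: str
    fdr_q: float = 0.05
    subgroup_cutoff: float = 35.0
    rank_transform: bool = False
    log_dup: bool = False
    seed: int = 0
    log_level: str = "INFO"
    toy_atlas: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls(**yaml.safe_load(f))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate_paths(self) -> None:
        for name in ("atlas_path", "overlap_path", "cohort_csv", "connectome_dir"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise PipelineError(f"[config] {name} does not exist: {p}")
        if not (0 < self.fdr_q < 1):
            raise PipelineError(f"[config] fdr_q must be in (0, 1), got {self.fdr_q}")
        if not (16 < self.subgroup_cutoff < 60):
            raise PipelineError(
                f"[config] subgroup_cutoff must lie inside (16, 60), got {self.subgroup_cutoff}"
            )


def default_run_config(data_dir, out_dir, **overrides) -> RunConfig:
    """RunConfig pointed at a dataset directory produced by the generator."""
    data_dir = Path(data_dir)
    toy = overrides.pop("toy_atlas", False)
    return RunConfig(
        atlas_path=str(
            atlas_mod.toy_atlas_path() if toy else atlas_mod.default_atlas_path()
        ),
        overlap_path=str(
            atlas_mod.toy_overlap_path() if toy else atlas_mod.default_overlap_path()
        ),
        cohort_csv=str(data_dir / "cohort.csv"),
        connectome_dir=str(data_dir / "connectomes"),
        out_dir=str(out_dir),
        toy_atlas=toy,
        **overrides,
    )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
            logger.info("stage %-16s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        "stages": {},
    }

    @_stage("atlas")
    def s_atlas():
        parc = load_parcellation(
            config.atlas_path, expected_nodes=None if config.toy_atlas else 234
        )
        assignment = assign_systems(parc, load_overlaps(config.overlap_path))
        return parc, assignment

    parc, assignment = s_atlas()
    report["stages"]["atlas"] = {
        "n_nodes": parc.n_nodes,
        "n_subcortical": len(parc.subcortical_ids),
        "system_sizes": {s: len(m) for s, m in assignment.members.items()},
    }

    @_stage("cohort")
    def s_cohort():
        return pd.read_csv(config.cohort_csv)

    cohort = s_cohort()
    report["stages"]["cohort"] = {"n_subjects": int(len(cohort))}

    @_stage("connectomes")
    def s_connectomes():
        loaded = []
        cdir = Path(config.connectome_dir)
        for sid in cohort["subject_id"]:
            matches = sorted(
                p for ext in ("csv", "mtx") for p in cdir.glob(f"{sid}.{ext}")
            )
            if not matches:
                raise PipelineError(f"[connectomes] no connectome file for {sid} in {cdir}")
            loaded.append(load_connectome(matches[0], parc, subject_id=str(sid)))
        return loaded

    connectomes = s_connectomes()
    report["stages"]["connectomes"] = {"n_loaded": len(connectomes)}

    @_stage("controllability")
    def s_ctrl():
        table = controllability_table(connectomes, parc, assignment)
        table.to_csv(out / "controllability.csv", index=False)
        return table

    ctrl = s_ctrl()

    @_stage("statistics")
    def s_stats():
        model = ControllabilityAgeModel(
            ctrl,
            cohort,
            q=config.fdr_q,
            subgroup_cutoff=config.subgroup_cutoff,
            rank_transform=config.rank_transform,
            log_dup=config.log_dup,
        )
        return model.fit()

    results = s_stats()
    results.interactions.to_csv(out / "interactions.csv", index=False)
    results.trajectories.to_csv(out / "trajectories.csv", index=False)
    results.subgroups.to_csv(out / "subgroups.csv", index=False)
    results.clinical.to_csv(out / "clinical.csv", index=False)
    demographics_table(cohort).to_csv(out / "demographics.csv", index=False)
    (out / "summary.txt").write_text(results.summary() + "\n")

    inter = results.interactions
    for fam in ("systems", "nodes"):
        sub = inter[inter["family"] == fam]
        report["stages"][f"stats_{fam}"] = {
            "n_tests": int(len(sub)),
            "n_raw_significant": int(sub["sig_raw"].sum()),
            "n_fdr_significant": int(sub["sig_fdr"].sum()),
            "fdr_significant_targets": sorted(sub.loc[sub["sig_fdr"], "target"]),
        }
    report["stages"]["trajectories"] = results.trajectories.to_dict("records")
    report["stages"]["subgroups"] = {"n_rows": int(len(results.subgroups))}
    report["stages"]["clinical"] = {
        "n_pairs": int(len(results.clinical)),
        "n_fdr_significant": int(results.clinical["sig_fdr"].sum())
        if "sig_fdr" in results.clinical
        else 0,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def render_report(results_dir) -> str:
    """Re-render a human-readable report from a results directory."""
    results_dir = Path(results_dir)
    report = json.loads((results_dir / "report.json").read_text())
    lines = [
        f"neuroctrl run report (version {report['provenance']['version']}, "
        f"config {report['provenance']['config_hash']}, seed {report['provenance']['seed']})"
    ]
    for stage, info in report["stages"].items():
        lines.append(f"  {stage}: {json.dumps(info, sort_keys=True)}")
    return "\n".join(lines)
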