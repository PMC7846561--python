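"""Orchestration: generate -> metrics -> cluster -> stats -> simulate.

A run is described by a single config mapping (YAML on disk).  Each stage
writes CSV/JSON artifacts into the run directory; a manifest records the
config hash, package version and seeds so identical configs produce
identical runs.  Stages whose outputs already exist under the same config
hash are reused.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations_io import (
    Dataset,
    export_feature_table,
    group_reconstructions,
    read_annotations,
    write_annotations,
)
from .clustering import cluster_analysis, cohort_table, regress_ssd_vs_size
from .inferential_stats import wilcoxon_one_sample
from .spatial_metrics import normalized_distance_2d, pool_distributions
from .synthetic_data import GeneratorConfig, PlacementModel, generate_dataset, preset
from . import receptor_sim as rs

__all__ = ["RunConfig", "run", "make_report", "StageError"]

ALL_STAGES = ("generate", "metrics", "cluster", "stats", "simulate")


class StageError(RuntimeError):
    """A pipeline stage could not run; the message names the stage."""


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=lambda: ["generate", "metrics"])
    seed: int = 0
    preset: str = "uniform"
    n_synapses: int = 50
    annotations_path: str | None = None  # use existing data instead of generating
    cluster_n_maps: int = 50
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(obj) - known
        if unknown:
            raise StageError(f"config: unknown fields {sorted(unknown)}")
        return cls(**obj)

    def validate(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise StageError(f"config: unknown stage {s!r}")
        if ("metrics" in self.stages or "cluster" in self.stages or
                "stats" in self.stages):
            if "generate" not in self.stages and self.annotations_path is None:
                raise StageError(
                    "metrics/cluster/stats stages need 'generate' or annotations_path"
                )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _gold_locations(ds: Dataset):
    groups: dict[str, list] = {}
    for p in ds.profiles:
        for kind, pts, trace in (
            ("gold", p.gold, p.psd_trace),
            ("pit", p.pits, p.az_trace),
            ("vesicle", p.docked_vesicles, p.az_trace),
        ):
            key = f"{p.label}|{p.condition}|{kind}"
            for pt in pts:
                groups.setdefault(key, []).append(normalized_distance_2d(pt, trace))
    return groups


def run(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the configured stages into ``out_dir``; returns the run dir."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    manifest_path = out / "manifest.json"
    manifest = {
        "config": asdict(config),
        "config_hash": h,
        "version": __version__,
        "stages_done": [],
    }
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == h:
            manifest = old
    summary_lines = []

    def done(stage: str) -> bool:
        return stage in manifest["stages_done"]

    def mark(stage: str) -> None:
        if stage not in manifest["stages_done"]:
            manifest["stages_done"].append(stage)
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    ds = None
    if "generate" in config.stages:
        ann_path = out / "annotations.json"
        if not (done("generate") and ann_path.exists()):
            cfg = preset(config.preset, n_synapses=config.n_synapses,
                         seed=config.seed)
            ds, sidecar = generate_dataset(cfg)
            write_annotations(ds, ann_path)
            (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
            mark("generate")
        else:
            ds = read_annotations(ann_path)
        summary_lines.append(f"generate: {len(ds)} profiles ({config.preset})")
    elif config.annotations_path:
        ds = read_annotations(config.annotations_path)

    if "metrics" in config.stages:
        if ds is None:
            raise StageError("metrics: no annotations available")
        groups = _gold_locations(ds)
        summary, ecdfs = pool_distributions(groups, seed=config.seed)
        summary.to_csv(out / "metrics_summary.csv", index=False)
        for g, tab in ecdfs.items():
            safe = g.replace("|", "_")
            tab.to_csv(out / f"ecdf_{safe}.csv", index=False)
        export_feature_table(ds).to_csv(out / "feature_table.csv", index=False)
        mark("metrics")
        for _, row in summary.iterrows():
            summary_lines.append(
                f"metrics: {row['group']} n={row['n']} median={row['median']:.3f}"
            )

    if "cluster" in config.stages:
        if ds is None:
            raise StageError("cluster: no annotations available")
        if not any(p.gold for p in ds.profiles):
            raise StageError("cluster: dataset contains no gold particles")
        rng = np.random.default_rng(config.seed)
        results = []
        for syn in group_reconstructions(ds):
            results.append(
                cluster_analysis(syn, n_maps=config.cluster_n_maps,
                                 seed=rng.integers(2**31))
            )
        cohort = cohort_table(results)
        cohort.to_csv(out / "cluster_cohort.csv", index=False)
        try:
            reg = {
                "data": regress_ssd_vs_size(results, "data"),
                "randomized": regress_ssd_vs_size(results, "randomized"),
            }
            (out / "cluster_regression.json").write_text(json.dumps(reg, indent=1))
        except ValueError:
            pass  # too few synapses for regression
        mark("cluster")
        ks = cohort.loc[cohort.n_gold > 0, "k_opt"]
        if len(ks):
            summary_lines.append(
                f"cluster: {len(ks)} synapses, median k_opt={ks.median():.0f}"
            )

    if "stats" in config.stages:
        if ds is None:
            raise StageError("stats: no annotations available")
        rows = []
        for g, locs in _gold_locations(ds).items():
            vals = [l.normalized for l in locs]
            if len(vals) < 1:
                continue
            res = wilcoxon_one_sample(vals, 0.5)
            rows.append({
                "comparison": f"{g} vs 0.5",
                "n": res.n[0],
                "statistic": res.statistic,
                "p": res.p_value,
                "p_corrected": None,
                "method": res.method,
            })
        pd.DataFrame(rows).to_csv(out / "stats_wilcoxon.csv", index=False)
        mark("stats")
        summary_lines.append(f"stats: {len(rows)} one-sample comparisons")

    if "simulate" in config.stages:
        sim_cfg = dict(config.simulate)
        sim_cfg.setdefault("seed", config.seed)
        table = rs.scenario_grid(**sim_cfg)
        table.to_csv(out / "scenario_auc.csv", index=False)
        mark("simulate")
        summary_lines.append(f"simulate: {len(table)} grid rows")

    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    mark_final = manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return out


def make_report(run_dir: str | Path) -> Path:
    """Collect a run's tables into a report directory (no prose)."""
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise StageError("report: run directory has no manifest.json")
    rep = run_dir / "report"
    rep.mkdir(exist_ok=True)
    for name in ("metrics_summary.csv", "cluster_cohort.csv",
                 "stats_wilcoxon.csv", "scenario_auc.csv"):
        src = run_dir / name
        if src.exists():
            df = pd.read_csv(src)
            df.to_csv(rep / name, index=False)
    for ecdf in sorted(run_dir.glob("ecdf_*.csv")):
        df = pd.read_csv(ecdf)
        assert (df["F"].diff().dropna() >= 0).all()
        df.to_csv(rep / ecdf.name, index=False)
    return rep
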