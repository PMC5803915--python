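"""Configuration-driven end-to-end analysis runner.

Reproduces the analysis order of the study this pipeline models: build
the requested connectomes for every subject, compute global and nodal
graph metrics, test group differences (rank test and age-adjusted GLM,
FDR over regions), screen metrics against behavioural outcomes, and
write a run directory with all tables plus a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .connectome import KINDS
from .functional import (
    NuisanceSet,
    build_functional_connectome,
    preprocess_series,
    read_nuisance,
    read_time_series,
)
from .metrics import metrics_table
from .regions import functional_nodes, load_region_table, structural_nodes
from .stats import group_metric_tests, read_subjects, spearman_screen
from .structural import build_structural_connectome, read_streamlines

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run", "report"]

STRUCTURAL_KINDS = ("binary", "fa_weighted", "fd_weighted")
FUNCTIONAL_KINDS = ("func_weighted", "func_binary")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    region_table: Path
    streamline_dir: Path | None
    timeseries_dir: Path | None
    subjects_file: Path
    output_dir: Path
    kinds: tuple[str, ...] = KINDS
    band_hz: tuple[float, float] = (0.01, 0.1)
    fdr_alpha: float = 0.05
    correlation_threshold: float = 0.7
    fdr_scope: str = "per_family"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.kinds:
            raise PipelineError("at least one connectome kind must be requested")
        unknown = set(self.kinds) - set(KINDS)
        if unknown:
            raise PipelineError(f"unknown connectome kind(s): {sorted(unknown)}")
        for name in ("region_table", "streamline_dir", "timeseries_dir", "subjects_file", "output_dir"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "kinds" in raw:
            raw["kinds"] = tuple(raw["kinds"])
        if "band_hz" in raw:
            raw["band_hz"] = tuple(raw["band_hz"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "region_table": str(self.region_table),
            "streamline_dir": str(self.streamline_dir),
            "timeseries_dir": str(self.timeseries_dir),
            "subjects_file": str(self.subjects_file),
            "output_dir": str(self.output_dir),
            "kinds": list(self.kinds),
            "band_hz": list(self.band_hz),
            "fdr_alpha": self.fdr_alpha,
            "correlation_threshold": self.correlation_threshold,
            "fdr_scope": self.fdr_scope,
            "seed": self.seed,
        }


def run(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    out = config.output_dir
    (out / "connectomes").mkdir(parents=True, exist_ok=True)

    if not config.region_table.exists():
        raise PipelineError(f"region table not found: {config.region_table}")
    if not config.subjects_file.exists():
        raise PipelineError(f"subjects file not found: {config.subjects_file}")
    table = load_region_table(config.region_table)
    subjects = read_subjects(config.subjects_file)
    s_nodes = structural_nodes(table)
    f_nodes = functional_nodes(table)

    want_structural = [k for k in config.kinds if k in STRUCTURAL_KINDS]
    want_functional = [k for k in config.kinds if k in FUNCTIONAL_KINDS]

    all_metrics = []
    for subject in subjects:
        sid = subject.subject_id
        connectomes = []
        if want_structural:
            sl_path = config.streamline_dir / f"{sid}.tsv"
            if not sl_path.exists():
                raise PipelineError(f"subject {sid}: missing streamline file {sl_path}")
            try:
                records = read_streamlines(sl_path, s_nodes)
                for kind in want_structural:
                    connectomes.append(build_structural_connectome(records, table, kind, sid))
            except Exception as exc:
                raise PipelineError(f"subject {sid}, structural stage: {exc}") from exc
        if want_functional:
            ts_path = config.timeseries_dir / f"{sid}.tsv"
            if not ts_path.exists():
                raise PipelineError(f"subject {sid}: missing time-series file {ts_path}")
            try:
                ts = read_time_series(ts_path, region_labels=f_nodes.labels)
                nuis_path = config.timeseries_dir / f"{sid}_nuisance.tsv"
                nuis = read_nuisance(nuis_path) if nuis_path.exists() else NuisanceSet(regressors=[[]])
                clean = preprocess_series(ts, nuis, band_hz=config.band_hz)
                for kind in want_functional:
                    connectomes.append(build_functional_connectome(clean, f_nodes, kind, sid))
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"subject {sid}, functional stage: {exc}") from exc
        for conn in connectomes:
            conn.to_csv(out / "connectomes" / f"{sid}_{conn.kind}.csv")
            all_metrics.append(metrics_table(conn, sid))
        logger.info("subject %s: %d connectomes built", sid, len(connectomes))

    metrics = pd.concat(all_metrics, ignore_index=True)
    metrics.to_csv(out / "metrics.csv", index=False)

    stats_report = group_metric_tests(metrics, subjects, fdr_scope=config.fdr_scope)
    stats_report.to_csv(out / "stats_report.csv", index=False)

    behavior = pd.DataFrame(
        [{"subject_id": s.subject_id, **s.behavior} for s in subjects]
    )
    correlations = spearman_screen(metrics, behavior, threshold=config.correlation_threshold)
    correlations.to_csv(out / "correlations.csv", index=False)

    cfg = config.to_dict()
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "package_version": __version__,
        "n_subjects": len(subjects),
        "elapsed_seconds": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def report(run_dir: str | Path) -> str:
    """Human-readable summary of significant findings and flagged correlations."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "run_manifest.json"
    stats_path = run_dir / "stats_report.csv"
    corr_path = run_dir / "correlations.csv"
    for p in (manifest_path, stats_path, corr_path):
        if not p.exists():
            raise PipelineError(f"incomplete run: {p} is missing")
    manifest = json.loads(manifest_path.read_text())
    alpha = manifest["config"]["fdr_alpha"]
    stats_report = pd.read_csv(stats_path)
    correlations = pd.read_csv(corr_path)

    lines = ["# Analysis summary", ""]
    lines.append(f"Subjects: {manifest['n_subjects']}; FDR alpha = {alpha}; "
                 f"correlation threshold = {manifest['config']['correlation_threshold']}")
    lines.append("")

    lines.append("## Global group differences (raw p < alpha)")
    glob = stats_report[(stats_report["scope"] == "global") & (stats_report["p_raw"] < alpha)]
    if glob.empty:
        lines.append("- none")
    else:
        for _, row in glob.iterrows():
            lines.append(
                f"- {row['connectome_kind']} {row['metric']} [{row['test']}]: "
                f"p = {row['p_raw']:.4f} ({row['direction']})"
            )
    lines.append("")

    lines.append("## Regional group differences (FDR-corrected p < alpha)")
    regional = stats_report[
        (stats_report["scope"] == "node") & (stats_report["p_fdr"] < alpha)
    ]
    if regional.empty:
        lines.append("- none")
    else:
        for _, row in regional.iterrows():
            lines.append(
                f"- {row['region']}: {row['connectome_kind']} {row['metric']} "
                f"[{row['test']}] FDR p = {row['p_fdr']:.4f} ({row['direction']})"
            )
    lines.append("")

    lines.append("## Strong behaviour-network correlations (|r| > threshold)")
    flagged = correlations[correlations["flagged"]]
    if flagged.empty:
        lines.append("- none")
    else:
        for _, row in flagged.iterrows():
            lines.append(
                f"- {row['region']}: {row['connectome_kind']} {row['metric']} vs "
                f"{row['behavior_outcome']}: r = {row['spearman_r']:.4f}"
            )
    text = "\n".join(lines) + "\n"
    (run_dir / "summary.md").write_text(text)
    return text
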