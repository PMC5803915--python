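"""Synthetic two-group cohort generator with planted, recoverable effects.

No raw data accompany the study this pipeline models, so every input
kind is emulated here: a region table, per-subject streamline records,
regional BOLD time series with nuisance signals, subject metadata and
behavioural outcomes.  The defaults mirror the study conditions: 9
animals per group (transgenic AD model vs wild-type control), 76
structural / 54 functional regions, 600 fMRI volumes at TR = 2 s, and
group age-at-scan distributions of 151.11 +/- 12.06 days (control) vs
181 +/- 32.6 days (transgenic) — the transgenic animals need longer
behavioural training, so age is confounded with group by design.

Planted effects, all recorded in a ground-truth manifest:

* a multiplicative FA reduction in the transgenic group's streamlines
  (``fa_effect``), which lowers every FA-weighted network metric;
* optional regional effects that perturb one region's incident edges;
* a behaviour-network coupling: a named network metric is tied to a
  named behavioural outcome through a Gaussian copula on ranks, so the
  target Spearman correlation is controlled exactly in expectation.

Streamline geometry follows a distance-decay model: regions get random
3-D positions, connection probability decays with distance, and
streamline lengths scale with inter-region distance, so fiber-density
weights span realistic orders of magnitude.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .connectome import Connectome
from .functional import NuisanceSet, RegionalTimeSeries, bandpass_mask, write_nuisance, write_time_series
from .metrics import summarize
from .regions import RegionTable, functional_nodes, packaged_region_table, structural_nodes
from .stats import SubjectRecord, write_subjects
from .structural import StreamlineRecord, build_structural_connectome, write_streamlines

__all__ = [
    "CohortConfig",
    "CohortDataset",
    "generate_cohort",
    "generate_time_series",
    "plant_regional_effect",
    "make_synthetic_region_table",
    "random_sparse_precision",
]


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_per_group: int = 9
    n_regions_structural: int = 76
    n_regions_functional: int = 54
    seed: int = 0
    edge_density: float = 0.30          # expected fraction of connected region pairs
    fa_effect: float = 0.15             # transgenic FA multiplied by (1 - fa_effect)
    regional_effects: list[tuple[str, str, float]] = field(default_factory=list)
    # age at scan, days (control finishes testing earlier than transgenic)
    age_mean_control: float = 151.11
    age_sd_control: float = 12.06
    age_mean_transgenic: float = 181.0
    age_sd_transgenic: float = 32.6
    # behaviour-network coupling: (connectome kind, metric name) at global
    # scope tied to one behavioural outcome at a signed Spearman target
    behavior_coupling: float = -0.72
    coupled_metric: tuple[str, str] = ("fd_weighted", "avg_strength")
    coupled_region: str | None = None   # couple a nodal metric of this region instead
    coupled_outcome: str = "training_sessions_total"
    # fMRI dimensions
    T: int = 600
    tr_seconds: float = 2.0
    # streamline model
    streamline_mean: float = 6.0        # extra streamlines per connected pair (Poisson)
    fa_base_range: tuple[float, float] = (0.30, 0.60)
    # which data kinds to generate
    modalities: tuple[str, ...] = ("structural", "functional")

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if abs(self.behavior_coupling) >= 1:
            raise ValueError(
                f"behaviour coupling |r| must be < 1, got {self.behavior_coupling}"
            )
        if self.n_regions_functional > self.n_regions_structural:
            raise ValueError("functional region count cannot exceed structural")


@dataclass
class CohortDataset:
    """In-memory cohort plus a ground-truth manifest of planted effects."""

    config: CohortConfig
    region_table: RegionTable
    subjects: list[SubjectRecord]
    streamlines: dict[str, list[StreamlineRecord]]
    time_series: dict[str, RegionalTimeSeries]
    nuisance: dict[str, NuisanceSet]
    manifest: dict

    def write(self, out_dir: str | Path) -> Path:
        """Emit the cohort in the file formats the pipeline readers expect."""
        out_dir = Path(out_dir)
        (out_dir / "streamlines").mkdir(parents=True, exist_ok=True)
        (out_dir / "timeseries").mkdir(parents=True, exist_ok=True)
        nodes = structural_nodes(self.region_table)

        table_path = out_dir / "regions.tsv"
        df = self.region_table.frame.copy()
        df.to_csv(table_path, sep="\t", index=False)
        write_subjects(out_dir / "subjects.csv", self.subjects)
        for sid, records in self.streamlines.items():
            write_streamlines(out_dir / "streamlines" / f"{sid}.tsv", records, nodes, sid)
        for sid, ts in self.time_series.items():
            write_time_series(out_dir / "timeseries" / f"{sid}.tsv", ts, sid)
            write_nuisance(out_dir / "timeseries" / f"{sid}_nuisance.tsv", self.nuisance[sid])
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return out_dir


def make_synthetic_region_table(
    n_structural: int, n_functional: int, seed: int = 0
) -> RegionTable:
    """A synthetic region table for scaled-down cohorts.

    The first ``n_functional`` structural parcels double as functional
    (GM) nodes; the remainder are white-matter parcels.  Volumes are
    synthetic (uniform 4-45 mm^3), as in the packaged fixture.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n_structural + 1):
        is_gm = i <= n_functional
        rows.append(
            {
                "region_name": f"Region {i:03d}",
                "hemisphere": "right" if i % 2 else "left",
                "structural_index": i,
                "functional_index": i if is_gm else pd.NA,
                "tissue_class": "GM" if is_gm else "WM",
                "volume_mm3": round(float(rng.uniform(4.0, 45.0)), 2),
            }
        )
    frame = pd.DataFrame(rows)
    frame["structural_index"] = frame["structural_index"].astype("Int64")
    frame["functional_index"] = frame["functional_index"].astype("Int64")
    return RegionTable(frame)


def random_sparse_precision(
    n: int, seed: int = 0, density: float = 0.08, strength: float = 0.3
) -> np.ndarray:
    """Random sparse symmetric positive-definite precision matrix.

    Off-diagonal entries are placed on a random ``density`` fraction of
    pairs with magnitude up to ``strength``; diagonal dominance keeps
    the matrix positive definite.
    """
    rng = np.random.default_rng(seed)
    P = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(iu[0].size) < density
    vals = rng.uniform(-strength, strength, iu[0].size) * mask
    P[iu] = vals
    P = P + P.T
    # enforce strict diagonal dominance
    np.fill_diagonal(P, np.abs(P).sum(axis=1) + 1.0)
    d = np.sqrt(np.diagonal(P))
    return P / np.outer(d, d)


def generate_time_series(
    cov_spec: np.ndarray,
    T: int,
    tr: float = 2.0,
    seed: int = 0,
    band_hz: tuple[float, float] | None = (0.01, 0.1),
    spec_is_precision: bool = True,
) -> RegionalTimeSeries:
    """Band-limited Gaussian series with a planted precision structure.

    Samples white Gaussian noise with covariance ``inv(cov_spec)`` (or
    ``cov_spec`` itself if ``spec_is_precision=False``) and applies a
    common band-pass; a filter shared by all channels preserves the
    cross-channel correlation structure, so sample partial correlations
    converge to the planted values as T grows.
    """
    spec = np.asarray(cov_spec, dtype=float)
    if T < 3:
        raise ValueError(f"cannot estimate correlations from T = {T} samples")
    eigvals = np.linalg.eigvalsh(spec)
    if eigvals.min() <= 0:
        raise ValueError("planted covariance/precision structure must be positive definite")
    cov = np.linalg.inv(spec) if spec_is_precision else spec
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov)
    data = L @ rng.standard_normal((spec.shape[0], T))
    if band_hz is not None:
        data = bandpass_mask(data, tr, band_hz)
    return RegionalTimeSeries(data=data, tr_seconds=tr, band_hz=band_hz, provenance=["synthetic"])


# ------------------------------------------------------------------ cohort


def _region_positions(n: int, rng: np.random.Generator) -> np.ndarray:
    # rat-brain-sized box, mm
    return rng.uniform([0, 0, 0], [18, 14, 10], size=(n, 3))


def _connection_probabilities(
    positions: np.ndarray, edge_density: float, decay_mm: float = 6.0
) -> tuple[np.ndarray, np.ndarray]:
    dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    p = np.exp(-dist / decay_mm)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices(len(positions), k=1)
    p = p * (edge_density / p[iu].mean())
    return np.clip(p, 0.0, 1.0), dist


def _subject_streamlines(
    rng: np.random.Generator,
    p_conn: np.ndarray,
    dist: np.ndarray,
    fa_base: np.ndarray,
    streamline_mean: float,
    fa_scale: float,
) -> list[StreamlineRecord]:
    n = p_conn.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    connected = rng.random(iu.size) < p_conn[iu, ju]
    counts = np.where(connected, 1 + rng.poisson(streamline_mean, iu.size), 0)
    records: list[StreamlineRecord] = []
    for a, b, c in zip(iu[connected], ju[connected], counts[connected]):
        base_len = max(dist[a, b], 0.5)
        lengths = base_len * rng.lognormal(0.0, 0.15, c)
        fas = np.clip(rng.normal(fa_base[a, b] * fa_scale, 0.04, c), 0.01, 0.99)
        records.extend(
            StreamlineRecord(int(a), int(b), float(l), float(f))
            for l, f in zip(lengths, fas)
        )
    return records


def _apply_regional_effect(
    records: list[StreamlineRecord],
    region_id: int,
    parameter: str,
    delta: float,
) -> list[StreamlineRecord]:
    out = []
    for s in records:
        if s.start_region == region_id or s.end_region == region_id:
            if parameter == "fa":
                s = replace(s, mean_fa=float(np.clip(s.mean_fa * (1.0 + delta), 0.0, 1.0)))
            elif parameter == "length":
                s = replace(s, length_mm=float(max(s.length_mm * (1.0 + delta), 1e-6)))
            else:
                raise ValueError(f"unknown regional parameter {parameter!r} (use 'fa' or 'length')")
        out.append(s)
    return out


def _generate_behavior(
    rng: np.random.Generator,
    subjects: list[SubjectRecord],
    metric_values: np.ndarray | None,
    coupling: float,
    coupled_outcome: str,
) -> None:
    """Fill SubjectRecord.behavior in place.

    The coupled outcome follows a Gaussian copula on the ranks of the
    coupled metric (Pearson latent rho = 2 sin(pi * rho_s / 6) so the
    Spearman target is exact in expectation); other outcomes follow
    per-group count models.
    """
    n = len(subjects)
    is_tg = np.array([s.group == "transgenic" for s in subjects])

    def counts(mean_c, sd_c, mean_t, sd_t):
        vals = np.where(
            is_tg,
            rng.normal(mean_t, sd_t, n),
            rng.normal(mean_c, sd_c, n),
        )
        return np.maximum(np.round(vals), 0.0)

    behavior = {
        "training_sessions_stage5": counts(18, 5, 26, 8),
        "training_sessions_total": counts(55, 10, 70, 16),
        "dnms_trials_total": counts(950, 100, 760, 120),
        "pct_correct_total": np.clip(rng.normal(81, 4, n), 0, 100),
        "pct_correct_short": np.clip(rng.normal(84, 4, n), 0, 100),
        "pct_correct_long": np.clip(rng.normal(76, 5, n), 0, 100),
    }
    short = np.round(behavior["dnms_trials_total"] * rng.uniform(0.52, 0.58, n))
    behavior["dnms_trials_short"] = short
    behavior["dnms_trials_long"] = behavior["dnms_trials_total"] - short

    if metric_values is not None and coupling != 0.0:
        rho_latent = 2.0 * np.sin(np.pi * coupling / 6.0)
        ranks = sp_stats.rankdata(metric_values)
        z_m = sp_stats.norm.ppf((ranks - 0.5) / n)
        z_b = rho_latent * z_m + np.sqrt(1.0 - rho_latent**2) * rng.standard_normal(n)
        # monotone map of the latent score onto a count scale
        base = behavior[coupled_outcome]
        mu, sd = float(np.mean(base)), max(float(np.std(base)), 1.0)
        behavior[coupled_outcome] = np.maximum(np.round(mu + sd * z_b), 0.0)

    for i, s in enumerate(subjects):
        s.behavior = {k: float(v[i]) for k, v in behavior.items()}


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Generate a full two-group cohort; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    if (config.n_regions_structural, config.n_regions_functional) == (76, 54):
        table = packaged_region_table()
    else:
        table = make_synthetic_region_table(
            config.n_regions_structural, config.n_regions_functional, seed=config.seed
        )
    s_nodes = structural_nodes(table)
    f_nodes = functional_nodes(table)
    ns = len(s_nodes)

    # cohort-level generative structure (shared by every subject)
    positions = _region_positions(ns, rng)
    p_conn, dist = _connection_probabilities(positions, config.edge_density)
    fa_base = rng.uniform(*config.fa_base_range, size=(ns, ns))
    fa_base = (fa_base + fa_base.T) / 2.0
    precision = random_sparse_precision(len(f_nodes), seed=config.seed + 1)
    cov = np.linalg.inv(precision)
    L_cov = np.linalg.cholesky(cov)

    regional_ids = []
    for region_name, parameter, delta in config.regional_effects:
        matches = [n.node_id for n in s_nodes if n.label == region_name or n.region_name == region_name]
        if not matches:
            raise ValueError(f"regional effect names unknown region {region_name!r}")
        regional_ids.append((matches, parameter, delta))

    subjects: list[SubjectRecord] = []
    streamlines: dict[str, list[StreamlineRecord]] = {}
    time_series: dict[str, RegionalTimeSeries] = {}
    nuisance: dict[str, NuisanceSet] = {}

    groups = ["control"] * config.n_per_group + ["transgenic"] * config.n_per_group
    for i, group in enumerate(groups):
        sid = f"{'ctl' if group == 'control' else 'tg'}{i % config.n_per_group + 1:02d}"
        if group == "control":
            age = rng.normal(config.age_mean_control, config.age_sd_control)
        else:
            age = rng.normal(config.age_mean_transgenic, config.age_sd_transgenic)
        subjects.append(SubjectRecord(sid, group, float(max(age, 40.0)), {}))

        if "structural" in config.modalities:
            fa_scale = (1.0 - config.fa_effect) if group == "transgenic" else 1.0
            records = _subject_streamlines(
                rng, p_conn, dist, fa_base, config.streamline_mean, fa_scale
            )
            if group == "transgenic":
                for ids, parameter, delta in regional_ids:
                    for rid in ids:
                        records = _apply_regional_effect(records, rid, parameter, delta)
            streamlines[sid] = records

        if "functional" in config.modalities:
            clean = L_cov @ rng.standard_normal((len(f_nodes), config.T))
            t = np.arange(config.T)
            # nuisance: 6 motion random walks + WM and CSF mean signals
            motion = np.cumsum(rng.normal(0, 0.02, (config.T, 6)), axis=0)
            wm_csf = rng.standard_normal((config.T, 2))
            wm_csf = bandpass_mask(wm_csf.T, config.tr_seconds, (0.005, 0.08)).T
            regs = np.column_stack([motion, wm_csf])
            loadings = rng.normal(0, 0.3, (len(f_nodes), regs.shape[1]))
            trend = rng.normal(0, 0.002, len(f_nodes))[:, None] * t[None, :]
            raw = clean + loadings @ regs.T + trend
            time_series[sid] = RegionalTimeSeries(
                data=raw, tr_seconds=config.tr_seconds, provenance=["synthetic_raw"]
            )
            nuisance[sid] = NuisanceSet(
                regressors=regs,
                names=[f"motion{k}" for k in range(6)] + ["wm_mean", "csf_mean"],
            )

    metric_values = None
    if "structural" in config.modalities and config.behavior_coupling != 0.0:
        kind, metric_name = config.coupled_metric
        region_id = None
        if config.coupled_region is not None:
            matches = [
                n.node_id
                for n in s_nodes
                if n.label == config.coupled_region or n.region_name == config.coupled_region
            ]
            if not matches:
                raise ValueError(f"coupled_region {config.coupled_region!r} is not a known region")
            region_id = matches[0]
        vals = []
        for s in subjects:
            conn = build_structural_connectome(streamlines[s.subject_id], table, kind, s.subject_id)
            nodal, glob = summarize(conn)
            if region_id is None:
                vals.append(glob.as_dict()[metric_name])
            else:
                vals.append(float(getattr(nodal, metric_name)[region_id]))
        metric_values = np.asarray(vals)

    _generate_behavior(
        rng, subjects, metric_values, config.behavior_coupling, config.coupled_outcome
    )

    manifest = {
        "seed": config.seed,
        "n_per_group": config.n_per_group,
        "n_regions_structural": config.n_regions_structural,
        "n_regions_functional": config.n_regions_functional,
        "planted_effects": {
            "fa_effect": config.fa_effect,
            "regional_effects": [list(e) for e in config.regional_effects],
            "behavior_coupling": {
                "metric": list(config.coupled_metric),
                "region": config.coupled_region,
                "outcome": config.coupled_outcome,
                "spearman_target": config.behavior_coupling,
            },
            "age_model": {
                "control": [config.age_mean_control, config.age_sd_control],
                "transgenic": [config.age_mean_transgenic, config.age_sd_transgenic],
            },
        },
    }
    return CohortDataset(
        config=config,
        region_table=table,
        subjects=subjects,
        streamlines=streamlines,
        time_series=time_series,
        nuisance=nuisance,
        manifest=manifest,
    )


def plant_regional_effect(
    dataset: CohortDataset, region: str, parameter: str, delta: float
) -> CohortDataset:
    """Perturb one region's incident streamlines in the transgenic group.

    Returns a new dataset; ``delta = 0`` leaves the data unchanged apart
    from the manifest entry.  Effects on different regions commute.
    """
    nodes = structural_nodes(dataset.region_table)
    matches = [n.node_id for n in nodes if n.label == region or n.region_name == region]
    if not matches:
        raise ValueError(f"unknown region {region!r}")
    by_id = {s.subject_id: s.group for s in dataset.subjects}
    new_streamlines = {}
    for sid, records in dataset.streamlines.items():
        if by_id[sid] == "transgenic":
            for rid in matches:
                records = _apply_regional_effect(records, rid, parameter, delta)
        new_streamlines[sid] = records
    manifest = copy.deepcopy(dataset.manifest)
    manifest["planted_effects"]["regional_effects"].append([region, parameter, delta])
    return CohortDataset(
        config=dataset.config,
        region_table=dataset.region_table,
        subjects=dataset.subjects,
        streamlines=new_streamlines,
        time_series=dataset.time_series,
        nuisance=dataset.nuisance,
        manifest=manifest,
    )
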