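"""Group statistics and behaviour-correlation screening for network metrics.

Two-group differences in each metric are tested twice: a Kruskal-Wallis
rank test (distribution-free) and a Gaussian generalized linear model
``metric ~ group + age`` that adjusts for age at scan — in this cohort
design the transgenic animals finish behavioural testing later, so age
is confounded with group and must be covaried.  Regional p-values are
corrected per metric family with the Benjamini-Hochberg false discovery
rate.  The behaviour screen reports Spearman rank correlations between
each metric and each behavioural outcome, flagging |r| above a
threshold (0.7 by default) without multiplicity correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord",
    "kruskal_wallis",
    "glm_group_age",
    "fdr_adjust",
    "spearman_screen",
    "group_metric_tests",
    "read_subjects",
    "write_subjects",
]

GROUPS = ("control", "transgenic")

BEHAVIOR_FIELDS = (
    "training_sessions_stage5",
    "training_sessions_total",
    "dnms_trials_total",
    "dnms_trials_short",
    "dnms_trials_long",
    "pct_correct_total",
    "pct_correct_short",
    "pct_correct_long",
)


@dataclass
class SubjectRecord:
    """Per-animal metadata and behavioural outcomes."""

    subject_id: str
    group: str
    age_days: float
    behavior: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not self.age_days > 0:
            raise ValueError(f"age_days must be positive, got {self.age_days}")
        for key, value in self.behavior.items():
            if key.startswith("pct_") and not 0 <= value <= 100:
                raise ValueError(f"{key} must be a percentage in [0, 100], got {value}")
            if not key.startswith("pct_") and value < 0:
                raise ValueError(f"{key} must be a non-negative count, got {value}")


def kruskal_wallis(a, b, exact: bool = False) -> tuple[float, float]:
    """Two-group Kruskal-Wallis test (midranks, tie-corrected).

    Returns ``(H, p)``.  The p-value uses the chi-square reference with
    1 degree of freedom; with ``exact=True`` (feasible for <= 8 per
    group) the exact permutation distribution of H is enumerated
    instead.  Identical pooled values give ``H = 0, p = 1``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample must have at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h = _kw_statistic(a, b)
    if exact:
        n, na = pooled.size, a.size
        if math.comb(n, na) > 200_000:
            raise ValueError("exact mode is only feasible for small samples")
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            h_perm = _kw_statistic(pooled[mask], pooled[~mask])
            count += h_perm >= h - 1e-12
            total += 1
        return float(h), count / total
    return float(h), float(sp_stats.chi2.sf(h, df=1))


def _kw_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = sp_stats.rankdata(pooled)
    n = pooled.size
    ra, rb = ranks[: a.size], ranks[a.size :]
    h = 12.0 / (n * (n + 1)) * (ra.sum() ** 2 / a.size + rb.sum() ** 2 / b.size) - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def glm_group_age(values, subjects: list[SubjectRecord]) -> tuple[float, float]:
    """Age-adjusted group effect from a Gaussian GLM with identity link.

    Fits ``value ~ intercept + group + age_days`` and returns the group
    coefficient (transgenic minus control) and its two-sided p-value.
    """
    values = np.asarray(values, dtype=float)
    if values.size != len(subjects):
        raise ValueError("one value per subject is required")
    group = np.array([1.0 if s.group == "transgenic" else 0.0 for s in subjects])
    age = np.array([s.age_days for s in subjects])
    if len(set(group)) < 2:
        raise ValueError("both groups must be represented")
    if np.ptp(age) == 0:
        # constant age carries no information; the model reduces to the
        # two-sample comparison value ~ group
        X = sm.add_constant(group[:, None])
    else:
        X = sm.add_constant(np.column_stack([group, age]))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "rank-deficient design: group is perfectly collinear with age; "
                "the group effect is not identifiable"
            )
    model = sm.GLM(values, X, family=sm.families.Gaussian())
    fit = model.fit()
    # Gaussian GLM ~ OLS: use the t reference with n - 3 df for finite samples
    df_resid = values.size - X.shape[1]
    tval = fit.params[1] / fit.bse[1]
    p = 2 * sp_stats.t.sf(abs(tval), df_resid)
    return float(fit.params[1]), float(p)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1) | np.isnan(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return pvals.copy()
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    return adjusted


def spearman_screen(
    metrics: pd.DataFrame,
    behavior: pd.DataFrame,
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Spearman correlation of every metric column against every outcome.

    ``metrics`` columns: subject_id, connectome_kind, scope, node_label,
    metric_name, value (tidy, as written by :func:`metrics.metrics_table`).
    ``behavior``: one row per subject_id, one column per outcome.
    Returns one row per (metric, outcome) pair with ``spearman_r`` and a
    ``flagged`` column true iff ``|r|`` strictly exceeds the threshold.
    Constant vectors make r undefined; those pairs are skipped with a
    logged warning.
    """
    rows = []
    outcome_cols = [c for c in behavior.columns if c != "subject_id"]
    grouped = metrics.groupby(["connectome_kind", "scope", "node_label", "metric_name"])
    for (kind, scope, node_label, metric_name), sub in grouped:
        merged = sub.merge(behavior, on="subject_id", how="inner")
        if len(merged) < 3:
            continue
        for outcome in outcome_cols:
            x = merged["value"].to_numpy(dtype=float)
            y = merged[outcome].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning(
                    "skipping %s/%s/%s vs %s: constant vector, Spearman r undefined",
                    kind, node_label or "global", metric_name, outcome,
                )
                continue
            r = float(sp_stats.spearmanr(x, y).statistic)
            rows.append(
                {
                    "metric": metric_name,
                    "region": node_label or "global",
                    "connectome_kind": kind,
                    "behavior_outcome": outcome,
                    "spearman_r": r,
                    "flagged": abs(r) > threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "metric", "region", "connectome_kind", "behavior_outcome", "spearman_r", "flagged",
        ],
    )


def group_metric_tests(
    metrics: pd.DataFrame,
    subjects: list[SubjectRecord],
    fdr_scope: str = "per_family",
) -> pd.DataFrame:
    """Kruskal-Wallis and age-adjusted GLM per metric, FDR over regions.

    Global metrics are tested without correction (one test per metric);
    regional (nodal) p-values are BH-adjusted within each
    (connectome_kind, metric_name) family by default, or across all
    regional tests at once with ``fdr_scope="pooled"``.
    """
    by_id = {s.subject_id: s for s in subjects}
    rows = []
    grouped = metrics.groupby(["connectome_kind", "scope", "node_label", "metric_name"])
    for (kind, scope, node_label, metric_name), sub in grouped:
        subs = [by_id[sid] for sid in sub["subject_id"] if sid in by_id]
        if len(subs) != len(sub):
            raise ValueError("metrics table contains subject_ids without metadata")
        values = sub["value"].to_numpy(dtype=float)
        groups = np.array([s.group for s in subs])
        a = values[groups == "control"]
        b = values[groups == "transgenic"]
        h, p_kw = kruskal_wallis(a, b) if (a.size >= 2 and b.size >= 2) else (np.nan, np.nan)
        try:
            effect, p_glm = glm_group_age(values, subs)
        except ValueError:
            effect, p_glm = np.nan, np.nan
        direction = "control>transgenic" if a.mean() > b.mean() else "transgenic>control"
        rows.append(
            {
                "family": f"{kind}/{metric_name}",
                "metric": metric_name,
                "region": node_label or "global",
                "connectome_kind": kind,
                "scope": scope,
                "test": "kruskal_wallis",
                "statistic": h,
                "p_raw": p_kw,
                "direction": direction,
            }
        )
        rows.append(
            {
                "family": f"{kind}/{metric_name}",
                "metric": metric_name,
                "region": node_label or "global",
                "connectome_kind": kind,
                "scope": scope,
                "test": "glm_group_age",
                "statistic": effect,
                "p_raw": p_glm,
                "direction": direction,
            }
        )
    report = pd.DataFrame(rows)
    if report.empty:
        report["p_fdr"] = []
        return report
    report["p_fdr"] = report["p_raw"]
    regional = (report["scope"] == "node") & report["p_raw"].notna()
    if fdr_scope == "pooled":
        fam_keys = [("all", t) for t in ("kruskal_wallis", "glm_group_age")]
        groups_iter = [
            (key, report.index[regional & (report["test"] == key[1])]) for key in fam_keys
        ]
    else:
        groups_iter = [
            (key, idx)
            for key, idx in report[regional].groupby(["family", "test"]).groups.items()
        ]
    for _, idx in groups_iter:
        if len(idx):
            report.loc[idx, "p_fdr"] = fdr_adjust(report.loc[idx, "p_raw"].to_numpy())
    return report


# ---------------------------------------------------------------------- I/O


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age_days"}
    if not required <= set(df.columns):
        raise ValueError(f"subjects file must contain columns {sorted(required)}")
    behavior_cols = [c for c in df.columns if c not in required]
    return [
        SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            age_days=float(row["age_days"]),
            behavior={c: float(row[c]) for c in behavior_cols if pd.notna(row[c])},
        )
        for _, row in df.iterrows()
    ]


def write_subjects(path: str | Path, subjects: list[SubjectRecord]) -> None:
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "group": s.group, "age_days": s.age_days}
        row.update(s.behavior)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
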