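"""Functional connectome: BOLD time-series preprocessing and partial-correlation networks.

The regional BOLD series (regions x time, TR-sampled) are cleaned in the
order: linear detrend, band-pass (default 0.01-0.1 Hz, applied as a hard
frequency-domain mask so the operation is reproducible bit-for-bit),
nuisance regression (motion parameters plus mean white-matter and CSF
signals, residualised by ordinary least squares) and finally z-scoring.

The edge weight between two regions is the partial correlation of their
series conditioned on all other regions — obtained from the inverse
sample correlation matrix P as  -P_ij / sqrt(P_ii * P_jj)  — mapped
through Fisher's z-transform (arctanh).  Negative partial correlations
are excluded (set to zero); the binary functional connectome marks the
strictly positive entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .connectome import Connectome, ConnectomeError
from .regions import NodeSet

__all__ = [
    "RegionalTimeSeries",
    "NuisanceSet",
    "PreprocessingError",
    "preprocess_series",
    "partial_correlation_matrix",
    "fisher_z",
    "build_functional_connectome",
    "average_voxels_to_regions",
    "read_time_series",
    "write_time_series",
    "read_nuisance",
    "write_nuisance",
]


class PreprocessingError(ValueError):
    pass


@dataclass
class RegionalTimeSeries:
    """Regions x time matrix with sampling interval and processing provenance."""

    data: np.ndarray  # (n_regions, T)
    tr_seconds: float = 2.0
    band_hz: tuple[float, float] | None = None
    provenance: list[str] = field(default_factory=list)
    region_labels: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise PreprocessingError(
                f"time-series matrix must be (regions x T) with T >= 2, got shape {self.data.shape}"
            )
        if np.isnan(self.data).any():
            raise PreprocessingError("time series contain missing values")
        if not self.tr_seconds > 0:
            raise PreprocessingError("TR must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds


@dataclass
class NuisanceSet:
    """T x K matrix of nuisance regressors (motion, WM mean, CSF mean)."""

    regressors: np.ndarray
    names: list[str] | None = None

    def __post_init__(self):
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.size and self.regressors.ndim != 2:
            raise PreprocessingError("nuisance regressors must form a T x K matrix")

    @property
    def k(self) -> int:
        return 0 if self.regressors.size == 0 else self.regressors.shape[1]


def _check_constant_rows(data: np.ndarray, stage: str, labels: list[str] | None) -> None:
    sd = data.std(axis=1)
    flat = np.flatnonzero(sd < 1e-12)
    if flat.size:
        names = [labels[i] if labels else f"region {i}" for i in flat]
        raise PreprocessingError(
            f"constant (zero-variance) series after {stage}: {names}"
        )


def bandpass_mask(x: np.ndarray, tr_seconds: float, band_hz: tuple[float, float]) -> np.ndarray:
    """Hard frequency-domain band-pass: zero all rFFT bins outside the band."""
    low, high = band_hz
    freqs = np.fft.rfftfreq(x.shape[-1], d=tr_seconds)
    keep = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=x.shape[-1], axis=-1)


def preprocess_series(
    ts: RegionalTimeSeries,
    nuisance: NuisanceSet | None = None,
    band_hz: tuple[float, float] = (0.01, 0.1),
) -> RegionalTimeSeries:
    """Detrend, band-pass, regress out nuisance signals, and z-score.

    Raises :class:`PreprocessingError` if a region's series becomes
    constant (e.g. a pure linear ramp, or a series fully explained by a
    nuisance regressor) — such a region cannot enter a correlation.
    """
    low, high = band_hz
    if not (0.0 < low < high < ts.nyquist_hz):
        raise PreprocessingError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist "
            f"({ts.nyquist_hz:.4g} Hz at TR = {ts.tr_seconds} s)"
        )
    data = sp_signal.detrend(ts.data, axis=1, type="linear")
    _check_constant_rows(data, "detrending", ts.region_labels)

    data = bandpass_mask(data, ts.tr_seconds, band_hz)
    _check_constant_rows(data, "band-pass filtering", ts.region_labels)

    if nuisance is not None and nuisance.k > 0:
        X = nuisance.regressors
        if X.shape[0] != ts.n_samples:
            raise PreprocessingError(
                f"nuisance regressors have {X.shape[0]} rows but the series has "
                f"{ts.n_samples} samples"
            )
        # filter the regressors like the data, so regression cannot
        # reintroduce out-of-band signal
        X = sp_signal.detrend(X, axis=0, type="linear")
        X = bandpass_mask(X.T, ts.tr_seconds, band_hz).T
        X = np.column_stack([np.ones(X.shape[0]), X])
        beta, *_ = np.linalg.lstsq(X, data.T, rcond=None)
        data = data - (X @ beta).T
        _check_constant_rows(data, "nuisance regression", ts.region_labels)

    data = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, keepdims=True)
    steps = ["detrend", f"bandpass({low},{high})"]
    if nuisance is not None and nuisance.k > 0:
        steps.append(f"nuisance_regression(k={nuisance.k})")
    steps.append("zscore")
    return RegionalTimeSeries(
        data=data,
        tr_seconds=ts.tr_seconds,
        band_hz=band_hz,
        provenance=ts.provenance + steps,
        region_labels=ts.region_labels,
    )


def partial_correlation_matrix(
    ts: RegionalTimeSeries | np.ndarray,
    ridge: float | None = None,
    max_condition: float = 1e10,
) -> np.ndarray:
    """Partial correlations of each pair conditioned on all other regions.

    Computed from the inverse of the sample correlation matrix R:
    ``pcorr[i, j] = -P[i, j] / sqrt(P[i, i] * P[j, j])`` with ``P = R^-1``.
    If R is ill-conditioned (condition number above ``max_condition``) a
    ridge term ``lambda * I`` with ``lambda = 1e-6 * trace(R) / N`` is
    added before inversion; pass ``ridge=0`` to forbid regularisation.
    """
    data = ts.data if isinstance(ts, RegionalTimeSeries) else np.asarray(ts, dtype=float)
    n, t = data.shape
    if t < 3:
        raise PreprocessingError(f"need at least 3 time samples to estimate correlations, got {t}")
    sd = data.std(axis=1)
    if np.any(sd < 1e-12):
        raise PreprocessingError(
            f"constant series at region(s) {list(np.flatnonzero(sd < 1e-12))}"
        )
    corr = np.corrcoef(data)
    cond = np.linalg.cond(corr)
    if cond > max_condition:
        if ridge == 0:
            raise PreprocessingError(
                f"correlation matrix is ill-conditioned (cond = {cond:.3g}) and "
                "regularisation is disabled"
            )
        lam = ridge if ridge is not None else 1e-6 * np.trace(corr) / n
        corr = corr + lam * np.eye(n)
    precision = np.linalg.inv(corr)
    d = np.sqrt(np.diagonal(precision))
    pcorr = -precision / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    pcorr = np.clip((pcorr + pcorr.T) / 2.0, -1.0, 1.0)
    return pcorr


def fisher_z(r):
    """Fisher z-transform (arctanh) of a correlation; requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("Fisher z-transform requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def build_functional_connectome(
    ts: RegionalTimeSeries,
    nodes: NodeSet,
    kind: str = "func_weighted",
    subject_id: str | None = None,
) -> Connectome:
    """Weighted (Fisher-z of positive partial correlations) or binary network.

    Negative partial correlations are excluded (zero weight); the binary
    kind is the indicator of a strictly positive weight.
    """
    if kind not in ("func_weighted", "func_binary"):
        raise ConnectomeError(f"unknown functional connectome kind {kind!r}")
    if ts.n_regions != len(nodes):
        raise ConnectomeError(
            f"time series has {ts.n_regions} regions but node set has {len(nodes)}"
        )
    pcorr = partial_correlation_matrix(ts)
    np.fill_diagonal(pcorr, 0.0)
    positive = pcorr > 0
    weights = np.zeros_like(pcorr)
    weights[positive] = np.arctanh(pcorr[positive])
    if kind == "func_binary":
        weights = (weights > 0).astype(float)
    return Connectome(nodes, weights, kind, subject_id)


def average_voxels_to_regions(
    voxel_data: np.ndarray, voxel_to_region: np.ndarray, n_regions: int
) -> np.ndarray:
    """Average a voxels x time matrix into regions x time given a voxel->region map.

    ``voxel_to_region[v]`` is the 0-based region of voxel ``v``; -1 marks
    voxels outside every region.
    """
    voxel_data = np.asarray(voxel_data, dtype=float)
    labels = np.asarray(voxel_to_region)
    out = np.zeros((n_regions, voxel_data.shape[1]))
    for r in range(n_regions):
        mask = labels == r
        if not mask.any():
            raise PreprocessingError(f"region {r} has no voxels")
        out[r] = voxel_data[mask].mean(axis=0)
    return out


# ---------------------------------------------------------------------- I/O


def write_time_series(path: str | Path, ts: RegionalTimeSeries, subject_id: str) -> None:
    """TSV with rows = regions (functional node order), columns = samples."""
    path = Path(path)
    pd.DataFrame(ts.data).to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
    sidecar = {"tr_seconds": ts.tr_seconds, "subject_id": subject_id}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_time_series(path: str | Path, region_labels: list[str] | None = None) -> RegionalTimeSeries:
    path = Path(path)
    data = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    tr = 2.0
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        tr = float(json.loads(sidecar_path.read_text())["tr_seconds"])
    return RegionalTimeSeries(data=data, tr_seconds=tr, region_labels=region_labels)


def write_nuisance(path: str | Path, nuisance: NuisanceSet) -> None:
    names = nuisance.names or [f"reg{i}" for i in range(nuisance.k)]
    pd.DataFrame(nuisance.regressors, columns=names).to_csv(path, sep="\t", index=False)


def read_nuisance(path: str | Path) -> NuisanceSet:
    df = pd.read_csv(path, sep="\t")
    return NuisanceSet(regressors=df.to_numpy(dtype=float), names=list(df.columns))
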