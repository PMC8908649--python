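"""Temporal cleaning of ROI time series.

The canonical order is discard -> detrend -> bandpass -> nuisance
regression; each step returns a new :class:`RoiTimeSeries` with the same
column count, labels and TR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "RoiTimeSeries",
    "ConfoundSet",
    "discard_initial",
    "detrend_linear",
    "bandpass",
    "regress_nuisance",
    "preprocess_timeseries",
]


@dataclass(frozen=True)
class RoiTimeSeries:
    """A T x N matrix of regional signals sampled every ``tr_seconds``."""

    data: np.ndarray
    tr_seconds: float
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"time series must be 2-D, got shape {data.shape}")
        if not np.isfinite(data).all():
            raise ValueError("time series contains missing or non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        labels = tuple(self.node_labels) or tuple(f"ROI_{i + 1:03d}" for i in range(data.shape[1]))
        if len(labels) != data.shape[1]:
            raise ValueError(
                f"{len(labels)} node labels for {data.shape[1]} columns"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ConfoundSet:
    """Named nuisance regressors (motion parameters, tissue signals, ...)."""

    regressors: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        reg = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        names = tuple(self.names)
        if reg.shape[1] != len(names):
            raise ValueError(f"{reg.shape[1]} regressor columns but {len(names)} names")
        if not np.isfinite(reg).all():
            raise ValueError("confound matrix contains non-finite values")
        object.__setattr__(self, "regressors", reg)
        object.__setattr__(self, "names", names)

    @property
    def n_timepoints(self) -> int:
        return self.regressors.shape[0]


def discard_initial(ts: RoiTimeSeries, n_discard: int = 10) -> RoiTimeSeries:
    """Drop the first ``n_discard`` time points (equilibration volumes)."""
    if n_discard < 0:
        raise ValueError(f"n_discard must be >= 0, got {n_discard}")
    if ts.n_timepoints <= n_discard:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_timepoints} time points"
        )
    if n_discard == 0:
        return ts
    return replace(ts, data=ts.data[n_discard:])


def detrend_linear(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Remove the least-squares line (intercept + slope * t) from each column."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points to detrend")
    t = np.arange(ts.n_timepoints, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return replace(ts, data=ts.data - design @ beta)


def bandpass(ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08, order: int = 4) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass applied column-wise.

    Uses forward-backward filtering so correlations between columns are not
    distorted by phase shifts.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} Hz is at or above Nyquist {nyquist:g} Hz for TR={ts.tr_seconds} s"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    return replace(ts, data=filtered)


def _collinear_names(design: np.ndarray, names: list[str]) -> list[str]:
    # A column is redundant if dropping it does not reduce the design rank.
    full_rank = np.linalg.matrix_rank(design)
    redundant = []
    for k in range(design.shape[1]):
        reduced = np.delete(design, k, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            redundant.append(names[k])
    return redundant


def regress_nuisance(ts: RoiTimeSeries, confounds: ConfoundSet | None = None) -> RoiTimeSeries:
    """OLS residuals of every column on an intercept plus the confounds.

    With no confounds this reduces to mean-centering each column.
    """
    t_pts = ts.n_timepoints
    if confounds is None or confounds.regressors.shape[1] == 0:
        return replace(ts, data=ts.data - ts.data.mean(axis=0))
    if confounds.n_timepoints != t_pts:
        raise ValueError(
            f"confounds have {confounds.n_timepoints} rows but time series has {t_pts}"
        )
    k = confounds.regressors.shape[1]
    if t_pts <= k + 1:
        raise ValueError(f"T={t_pts} too short for {k} confounds plus intercept")
    design = np.column_stack([np.ones(t_pts), confounds.regressors])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_names(design, ["intercept", *confounds.names])
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return replace(ts, data=ts.data - design @ beta)


def preprocess_timeseries(
    ts: RoiTimeSeries,
    *,
    discard_n: int = 10,
    detrend: bool = True,
    band_low_hz: float | None = 0.01,
    band_high_hz: float | None = 0.08,
    confounds: ConfoundSet | None = None,
) -> RoiTimeSeries:
    """Run the full temporal pipeline: discard, detrend, bandpass, regress.

    Confounds supplied at the original length are trimmed alongside the data.
    """
    out = discard_initial(ts, discard_n) if discard_n else ts
    if confounds is not None and discard_n and confounds.n_timepoints == ts.n_timepoints:
        confounds = ConfoundSet(confounds.regressors[discard_n:], confounds.names)
    if detrend:
        out = detrend_linear(out)
    if band_low_hz is not None and band_high_hz is not None:
        out = bandpass(out, band_low_hz, band_high_hz)
    out = regress_nuisance(out, confounds)
    return out
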