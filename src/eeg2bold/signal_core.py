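"""Shared time-series primitives: z-normalization, linear detrending, and
previous-value outlier replacement.

These three operations are applied identically to EEG band-power series and
to region-averaged BOLD series; only the outlier threshold differs between
the two modalities (4 SD for band powers, 3 SD for BOLD). All operations act
column-wise on a :class:`SeriesMatrix`, whose columns are "units" — either
channel-band pairs or cortical regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SeriesMatrix",
    "OutlierReport",
    "zscore_normalize",
    "replace_outliers_with_previous",
    "remove_drift",
]


@dataclass
class SeriesMatrix:
    """A time × unit matrix of real-valued series.

    Parameters
    ----------
    values
        2-D array, rows are time points (fMRI scans / EEG segments), columns
        are units (channel-band pairs or regions).
    time_step_s
        Seconds between consecutive rows (the TR for scan-aligned data).
    unit_labels
        One unique label per column.
    degenerate
        Boolean flag per column marking constant columns zeroed out by
        normalization. ``None`` until :func:`zscore_normalize` sets it.
    """

    values: np.ndarray
    time_step_s: float
    unit_labels: list[str]
    degenerate: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D time × unit matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite with no missing entries")
        if self.time_step_s <= 0:
            raise ValueError("time_step_s must be positive")
        self.unit_labels = [str(u) for u in self.unit_labels]
        if len(self.unit_labels) != self.values.shape[1]:
            raise ValueError("unit_labels length must match the column count")
        if len(set(self.unit_labels)) != len(self.unit_labels):
            raise ValueError("unit_labels must be unique")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray, degenerate: np.ndarray | None = None) -> "SeriesMatrix":
        return SeriesMatrix(values, self.time_step_s, list(self.unit_labels),
                            degenerate if degenerate is not None else self.degenerate)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.unit_labels)
        frame.index.name = "scan"
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, time_step_s: float) -> "SeriesMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame.to_numpy(float), time_step_s, list(frame.columns))


@dataclass
class OutlierReport:
    """Bookkeeping for previous-value outlier replacement."""

    flags: np.ndarray  # boolean, time × unit, computed on the input values
    proportion_per_unit: np.ndarray
    threshold_std: float
    unit_labels: list[str]

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        self.proportion_per_unit = np.asarray(self.proportion_per_unit, dtype=float)
        if not np.allclose(self.proportion_per_unit, self.flags.mean(axis=0)):
            raise ValueError("proportion_per_unit must equal the column means of flags")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold_std": self.threshold_std,
            "proportion_per_unit": dict(zip(self.unit_labels, self.proportion_per_unit.tolist())),
            "n_flagged": int(self.flags.sum()),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def flags_to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.flags.astype(int), columns=self.unit_labels)
        frame.index.name = "scan"
        frame.to_csv(path, sep="\t")


def zscore_normalize(x: SeriesMatrix, ddof: int = 0) -> SeriesMatrix:
    """Center and scale each column to mean 0, SD 1.

    Population SD (``ddof=0``) by default. A constant column cannot be
    scaled; it is set to all zeros and flagged degenerate so downstream
    stages can ignore it.
    """
    if x.n_time < 2:
        raise ValueError("zscore_normalize needs at least 2 time points")
    mean = x.values.mean(axis=0)
    sd = x.values.std(axis=0, ddof=ddof)
    # relative tolerance: residuals at machine-epsilon scale (e.g. after an
    # exact detrend) count as constant, not as signal to be amplified
    scale = np.maximum(1.0, np.abs(x.values).max(axis=0))
    degenerate = sd <= 1e-12 * scale
    safe_sd = np.where(degenerate, 1.0, sd)
    out = (x.values - mean) / safe_sd
    out[:, degenerate] = 0.0
    return x.copy_with(out, degenerate=degenerate)


def replace_outliers_with_previous(
    x: SeriesMatrix, threshold_std: float
) -> tuple[SeriesMatrix, OutlierReport]:
    """Replace entries with |value| above ``threshold_std`` by the previous
    time point's (possibly already replaced) value.

    Flags are computed once, on the input values; replacement then sweeps
    left to right, so a run of consecutive outliers collapses onto the last
    clean value before the run. A flagged first time point has no previous
    value and is left unchanged (it stays flagged in the report). The input
    is expected to be z-normalized already, so the threshold is in SD units.
    """
    if threshold_std <= 0:
        raise ValueError("threshold_std must be positive")
    flags = np.abs(x.values) > threshold_std
    out = x.values.copy()
    n_time = x.n_time
    for t in range(1, n_time):
        row = flags[t]
        if row.any():
            out[t, row] = out[t - 1, row]
    report = OutlierReport(flags, flags.mean(axis=0), float(threshold_std), list(x.unit_labels))
    return x.copy_with(out), report


def remove_drift(x: SeriesMatrix) -> SeriesMatrix:
    """Subtract the per-column least-squares straight line over time.

    BOLD signal drifts slowly over a session; a linear fit absorbs the bulk
    of it. The residual is exactly orthogonal to the constant and linear
    regressors.
    """
    if x.n_time < 3:
        raise ValueError("remove_drift needs at least 3 time points")
    t = np.arange(x.n_time, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, x.values, rcond=None)
    return x.copy_with(x.values - design @ coef)
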