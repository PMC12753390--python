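"""Supervised-set construction: lagged band-power features and the
direction / value targets, aligned per subject, condition, and region.

The feature vector at scan t concatenates the normalized band powers at
scans t−5 … t (time-step-major, then channel, then band); at TR = 2 s the
window spans 10 s, long enough to cover the hemodynamic response peak. The
classification target at scan t is whether the normalized BOLD signal rose
or fell from scan t−1 to scan t; the regression target is the normalized
BOLD value at scan t itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg_prep import BandPowerTensor
from .fmri_prep import RegionTimeSeries

__all__ = [
    "LABEL_INCREASE",
    "LABEL_DECREASE",
    "SupervisedSet",
    "build_features",
    "build_targets",
    "build_raw_segments",
    "build_supervised_set",
]

LABEL_INCREASE = "increase"
LABEL_DECREASE = "decrease"
DEFAULT_N_LAGS = 5


@dataclass
class SupervisedSet:
    """Aligned features and targets for one (subject, condition, region)."""

    X: np.ndarray  # samples × features
    y_class: np.ndarray  # strings: increase / decrease
    y_reg: np.ndarray  # normalized BOLD values
    index: pd.DataFrame  # columns: subject, condition, region, scan

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y_class) == len(self.y_reg) == len(self.index) == n):
            raise ValueError("X, y_class, y_reg, and index must align")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def to_tsv(self, features_path: str | Path, targets_path: str | Path) -> None:
        pd.DataFrame(self.X).rename_axis("sample").to_csv(features_path, sep="\t")
        targets = self.index.copy()
        targets["y_class"] = self.y_class
        targets["y_reg"] = self.y_reg
        targets.to_csv(targets_path, sep="\t", index=False)


def build_features(values: np.ndarray | BandPowerTensor,
                   n_lags: int = DEFAULT_N_LAGS) -> tuple[np.ndarray, np.ndarray]:
    """Lagged feature matrix from a scans × channels × bands tensor.

    Sample for scan t (t = n_lags … T−1) is the concatenation of the band
    powers at scans t−n_lags … t, flattened in (time step, channel, band)
    order. Returns the matrix and the scan index of each sample. The first
    n_lags scans yield no sample (no zero-padding).
    """
    tensor = values.values if isinstance(values, BandPowerTensor) else np.asarray(values, float)
    n_scans = tensor.shape[0]
    if n_scans <= n_lags:
        raise ValueError(f"need more than n_lags={n_lags} scans, got {n_scans}")
    flat = tensor.reshape(n_scans, -1)
    windows = [flat[step:n_scans - n_lags + step] for step in range(n_lags + 1)]
    X = np.concatenate(windows, axis=1)
    scans = np.arange(n_lags, n_scans)
    return X, scans


def build_targets(bold: RegionTimeSeries | np.ndarray,
                  region: str | int) -> tuple[np.ndarray, np.ndarray]:
    """Direction labels and value targets for one region.

    The label at scan t (t ≥ 1) is ``increase`` when the normalized BOLD
    value did not fall between scans t−1 and t (ties count as increase);
    the regression target at scan t is the value itself. Index 0 of both
    outputs corresponds to scan 1.
    """
    if isinstance(bold, RegionTimeSeries):
        if isinstance(region, str):
            if region not in bold.region_names:
                raise ValueError(f"unknown region label {region!r}")
            column = bold.values[:, bold.region_names.index(region)]
        else:
            column = bold.values[:, region]
    else:
        column = np.asarray(bold, dtype=float)
        if column.ndim == 2:
            column = column[:, int(region)]
    if len(column) < 2:
        raise ValueError("need at least 2 scans to define a direction")
    diff = np.diff(column)
    y_class = np.where(diff >= 0, LABEL_INCREASE, LABEL_DECREASE)
    y_reg = column[1:]
    return y_class, y_reg


def build_raw_segments(segments: list[np.ndarray],
                       n_lags: int = DEFAULT_N_LAGS) -> tuple[np.ndarray, np.ndarray]:
    """Stacked raw-EEG windows for the 1-D convolutional path.

    ``segments`` are the scan-aligned channels × samples arrays. The sample
    for scan t concatenates segments t−n_lags … t along time, keeping
    channels as the leading axis (the network's input channels). Returns a
    samples × channels × (window·samples-per-scan) tensor plus scan indices.
    """
    n_scans = len(segments)
    if n_scans <= n_lags:
        raise ValueError(f"need more than n_lags={n_lags} scans, got {n_scans}")
    stacked = [
        np.concatenate(segments[t - n_lags:t + 1], axis=-1)
        for t in range(n_lags, n_scans)
    ]
    return np.stack(stacked), np.arange(n_lags, n_scans)


def build_supervised_set(
    band_powers: BandPowerTensor | np.ndarray,
    bold: RegionTimeSeries,
    region: str,
    subject: int | str,
    condition: str,
    n_lags: int = DEFAULT_N_LAGS,
) -> SupervisedSet:
    """Align lagged features with one region's targets.

    Keeps scans t ≥ n_lags, for which both the full lag window and the
    direction label (needing scan t−1) exist.
    """
    X, scans = build_features(band_powers, n_lags=n_lags)
    y_class, y_reg = build_targets(bold, region)
    # targets start at scan 1; keep scans >= n_lags
    y_class = y_class[scans - 1]
    y_reg = y_reg[scans - 1]
    index = pd.DataFrame({
        "subject": subject,
        "condition": condition,
        "region": region,
        "scan": scans,
    })
    return SupervisedSet(X, y_class, y_reg, index)
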