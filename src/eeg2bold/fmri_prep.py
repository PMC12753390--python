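"""fMRI preparation: ROI averaging on a maximum-probability label map,
then linear detrending, z-normalization, and 3-SD outlier replacement.

Consumes BOLD that has already been motion-corrected, coregistered, and
spatially normalized upstream (or the synthetic generator's region series),
together with an integer label volume in which voxel value r > 0 assigns
the voxel to region r of a non-overlapping cortical parcellation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import signal_core
from .signal_core import OutlierReport, SeriesMatrix

__all__ = [
    "LabelMap",
    "RegionTimeSeries",
    "roi_average",
    "preprocess_bold",
    "load_nifti_pair",
    "region_series_to_volume",
]

BOLD_OUTLIER_THRESHOLD_STD = 3.0
EMPTY_REGION_SENTINEL = np.nan


@dataclass
class LabelMap:
    """Integer label volume (0 = background) with region names for 1..R."""

    labels: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer volume")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.labels.max() > len(self.region_names):
            raise ValueError("voxel label exceeds the number of region names")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


@dataclass
class RegionTimeSeries:
    """Scans × regions BOLD with preprocessing provenance."""

    values: np.ndarray
    region_names: list[str]
    tr_s: float
    outliers: OutlierReport | None = None
    degenerate: np.ndarray | None = None

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, columns=self.region_names)
        frame.index.name = "scan"
        frame.to_csv(path, sep="\t")
        sidecar = {
            "tr_s": self.tr_s,
            "processing": ["remove_drift", "zscore_normalize",
                           f"replace_outliers_with_previous(threshold_std="
                           f"{None if self.outliers is None else self.outliers.threshold_std})"],
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def roi_average(bold_4d: np.ndarray, label_map: LabelMap) -> np.ndarray:
    """Average BOLD over the voxels of each region, per scan.

    ``bold_4d`` is (x, y, z, scans); entry (t, r) of the result is the
    unweighted mean over voxels labeled r + 1 at scan t. Background voxels
    (label 0) are excluded. A region with no voxels yields a NaN sentinel
    column and a warning, so partial-coverage volumes still run.
    """
    bold_4d = np.asarray(bold_4d, dtype=float)
    if bold_4d.shape[:-1] != label_map.labels.shape:
        raise ValueError(
            f"spatial shape {bold_4d.shape[:-1]} does not match label volume "
            f"{label_map.labels.shape}")
    n_scans = bold_4d.shape[-1]
    n_regions = label_map.n_regions
    flat_labels = label_map.labels.reshape(-1)
    flat_bold = bold_4d.reshape(-1, n_scans)
    counts = np.bincount(flat_labels, minlength=n_regions + 1)[1:]
    out = np.full((n_scans, n_regions), EMPTY_REGION_SENTINEL)
    sums = np.zeros((n_regions + 1, n_scans))
    np.add.at(sums, flat_labels, flat_bold)
    nonempty = counts > 0
    out[:, nonempty] = (sums[1:][nonempty] / counts[nonempty, None]).T
    for r in np.nonzero(~nonempty)[0]:
        warnings.warn(f"region '{label_map.region_names[r]}' has no voxels; "
                      f"column filled with sentinel", stacklevel=2)
    return out


def preprocess_bold(
    matrix: np.ndarray,
    region_names: list[str] | None = None,
    tr_s: float = 2.0,
    threshold_std: float = BOLD_OUTLIER_THRESHOLD_STD,
) -> RegionTimeSeries:
    """Detrend, z-normalize, and outlier-correct region series, in that
    fixed order.

    Drift removal first (so the linear trend does not inflate the SD), then
    per-region z-scoring, then replacement of |z| > 3 entries by the
    previous scan's value.
    """
    matrix = np.asarray(matrix, dtype=float)
    if region_names is None:
        region_names = [f"region_{i:02d}" for i in range(matrix.shape[1])]
    series = SeriesMatrix(matrix, tr_s, region_names)
    detrended = signal_core.remove_drift(series)
    normalized = signal_core.zscore_normalize(detrended)
    replaced, report = signal_core.replace_outliers_with_previous(normalized, threshold_std)
    return RegionTimeSeries(replaced.values, list(region_names), tr_s,
                            outliers=report, degenerate=normalized.degenerate)


def region_series_to_volume(
    matrix: np.ndarray, region_names: list[str] | None = None
) -> tuple[np.ndarray, LabelMap]:
    """Realize scans × regions series as a one-voxel-per-region 4D volume.

    Useful for exercising the ROI-averaging path (and NIfTI round-trips)
    with synthetic region series: voxel r of the (R, 1, 1) volume carries
    region r + 1's series, so ``roi_average`` inverts this exactly.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_scans, n_regions = matrix.shape
    if region_names is None:
        region_names = [f"region_{i:02d}" for i in range(n_regions)]
    bold_4d = matrix.T.reshape(n_regions, 1, 1, n_scans)
    labels = np.arange(1, n_regions + 1).reshape(n_regions, 1, 1)
    return bold_4d, LabelMap(labels, list(region_names))


def load_nifti_pair(bold_path: str | Path, labels_path: str | Path,
                    region_names: list[str]) -> tuple[np.ndarray, LabelMap]:
    """Read a 4D BOLD NIfTI and an integer label NIfTI via nibabel."""
    import nibabel as nib

    bold = np.asarray(nib.load(str(bold_path)).dataobj, dtype=float)
    labels = np.asarray(nib.load(str(labels_path)).dataobj)
    labels = np.rint(labels).astype(int)
    return bold, LabelMap(labels, region_names)
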