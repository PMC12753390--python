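"""EEG preparation: scan-aligned segmentation, Welch band powers, and
normalization with previous-segment outlier replacement.

The EEG stream is cut into TR-long segments aligned with the fMRI scans
(TR = 2 s here). For each segment and channel, power spectral density is
estimated by Welch's method (1-s Hamming windows, 50% overlap) and
integrated over six canonical bands: delta 1–4, theta 4–8, alpha 8–12,
sigma 12–16, beta 16–30, gamma 30–40 Hz. Band powers are then z-scored per
channel-band series across scans and outliers beyond 4 SD are replaced by
the previous segment's value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from . import signal_core
from .signal_core import OutlierReport, SeriesMatrix

__all__ = [
    "EEGRecording",
    "BandDefinition",
    "DEFAULT_BANDS",
    "BandPowerTensor",
    "segment_to_scans",
    "compute_band_powers",
    "normalize_band_powers",
    "load_recording",
]

EEG_OUTLIER_THRESHOLD_STD = 4.0


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band; intervals are half-open [low, high)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")

    @property
    def label(self) -> str:
        """Human-readable label, e.g. ``"Beta (16–30 Hz)"``."""
        low = int(self.low_hz) if float(self.low_hz).is_integer() else self.low_hz
        high = int(self.high_hz) if float(self.high_hz).is_integer() else self.high_hz
        return f"{self.name.capitalize()} ({low}–{high} Hz)"


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("sigma", 12.0, 16.0),
    BandDefinition("beta", 16.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)


@dataclass
class EEGRecording:
    """Multichannel EEG in µV with 10-20-system channel labels."""

    signal: np.ndarray  # channels × samples
    sfreq_hz: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.sfreq_hz <= 0:
            raise ValueError("sfreq_hz must be positive")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("channel_labels must match the channel count")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class BandPowerTensor:
    """Scan-aligned, normalized band powers with outlier bookkeeping."""

    values: np.ndarray  # scans × channels × bands
    channel_labels: list[str]
    bands: tuple[BandDefinition, ...]
    normalized: bool
    outliers: OutlierReport | None = None
    degenerate: np.ndarray | None = None  # channels × bands

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        n, c, b = self.values.shape
        frame = pd.DataFrame({
            "scan": np.repeat(np.arange(n), c * b),
            "channel": np.tile(np.repeat(self.channel_labels, b), n),
            "band": np.tile([band.name for band in self.bands], n * c),
            "value": self.values.reshape(-1),
        })
        frame.to_csv(path, sep="\t", index=False)
        sidecar = {
            "bands": [{"name": band.name, "low_hz": band.low_hz, "high_hz": band.high_hz}
                      for band in self.bands],
            "normalized": self.normalized,
            "outlier_threshold_std": None if self.outliers is None else self.outliers.threshold_std,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def segment_to_scans(rec: EEGRecording, tr_s: float, n_scans: int) -> list[np.ndarray]:
    """Cut the recording into ``n_scans`` TR-long scan-aligned segments.

    Segment t covers samples in [t·tr_s, (t+1)·tr_s); trailing samples
    beyond the last requested scan are dropped.
    """
    seg_len = int(round(tr_s * rec.sfreq_hz))
    needed = n_scans * seg_len
    if rec.n_samples < needed:
        raise ValueError(
            f"recording too short: {rec.n_samples} samples, need {needed} "
            f"({needed - rec.n_samples} short) for {n_scans} scans of {tr_s} s")
    return [rec.signal[:, t * seg_len:(t + 1) * seg_len] for t in range(n_scans)]


def compute_band_powers(
    segments: list[np.ndarray],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    sfreq_hz: float = 200.0,
    welch_window_s: float = 1.0,
) -> np.ndarray:
    """Absolute band powers (µV²) per segment, channel, and band.

    Welch PSD with Hamming windows of ``welch_window_s`` seconds at 50%
    overlap; band power is the trapezoid-rule integral of the density over
    the band. With contiguous bands each shared edge frequency contributes
    half its density to each neighbor, so no energy is double-counted.
    """
    nyquist = sfreq_hz / 2.0
    for band in bands:
        if band.high_hz > nyquist:
            raise ValueError(f"band {band.name} upper edge {band.high_hz} Hz "
                             f"exceeds Nyquist {nyquist} Hz")
    nperseg = int(round(welch_window_s * sfreq_hz))
    seg_len = segments[0].shape[-1]
    if seg_len < nperseg:
        raise ValueError("segment shorter than the Welch analysis window")
    stack = np.stack([np.atleast_2d(seg) for seg in segments])  # scans × ch × samples
    freqs, psd = _signal.welch(stack, fs=sfreq_hz, window="hamming",
                               nperseg=nperseg, noverlap=nperseg // 2, axis=-1)
    powers = np.empty(stack.shape[:2] + (len(bands),))
    for bi, band in enumerate(bands):
        mask = (freqs >= band.low_hz) & (freqs <= band.high_hz)
        powers[..., bi] = np.trapezoid(psd[..., mask], freqs[mask], axis=-1)
    return powers


def normalize_band_powers(
    tensor: np.ndarray,
    channel_labels: list[str] | None = None,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    threshold_std: float = EEG_OUTLIER_THRESHOLD_STD,
    tr_s: float = 2.0,
) -> BandPowerTensor:
    """Z-score each channel-band series across scans, then replace outliers
    beyond ``threshold_std`` with the previous segment's value.

    Normalization is per channel-band pair (not pooled across the bands of
    a channel); this keeps every band on its own scale and is configurable
    upstream by reshaping.
    """
    tensor = np.asarray(tensor, dtype=float)
    n, c, b = tensor.shape
    if channel_labels is None:
        channel_labels = [f"ch_{i:02d}" for i in range(c)]
    labels = [f"{ch}:{band.name}" for ch in channel_labels for band in bands]
    matrix = SeriesMatrix(tensor.reshape(n, c * b), tr_s, labels)
    normalized = signal_core.zscore_normalize(matrix)
    replaced, report = signal_core.replace_outliers_with_previous(normalized, threshold_std)
    return BandPowerTensor(
        values=replaced.values.reshape(n, c, b),
        channel_labels=list(channel_labels),
        bands=tuple(bands),
        normalized=True,
        outliers=report,
        degenerate=None if normalized.degenerate is None
        else normalized.degenerate.reshape(c, b),
    )


def load_recording(path: str | Path) -> EEGRecording:
    """Read a raw EEG file (EDF/BrainVision/FIF) via MNE into µV arrays."""
    import mne  # optional dependency, only needed for real recordings

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    return EEGRecording(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                        list(raw.ch_names))
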