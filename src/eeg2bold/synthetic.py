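"""Synthetic multi-subject EEG-fMRI study generator.

Emulates the structure of a simultaneous EEG-fMRI neurofeedback study:
9 subjects × 3 conditions (eegfmriNF, eegNF, fmriNF), TR = 2 s, 64-channel
EEG at 200 Hz, 49 cortical regions, alternating rest/task blocks. The EEG
side is generated as latent band-power series (AR(1) noise plus a block
design); the BOLD side is the hemodynamically delayed, coupling-weighted sum
of those latents plus slow linear drift and white noise. Because the
coupling weights and HRF are known, every downstream stage — preprocessing,
feature building, model fitting, statistics — can be tested for recovery of
the planted structure, and a zero-coupling study provides an exact null.

Seed discipline: one master seed; every (subject, condition, stage) draws
from its own `numpy` SeedSequence substream, so adding subjects or
conditions never perturbs the data of earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .eeg_prep import DEFAULT_BANDS, BandDefinition

__all__ = [
    "SyntheticConfig",
    "HRFParams",
    "CouplingSpec",
    "SessionData",
    "SyntheticStudy",
    "make_hrf",
    "simulate_band_power_latents",
    "simulate_bold",
    "generate_study",
    "write_study",
    "load_study",
]

DEFAULT_CONDITIONS = ("eegfmriNF", "eegNF", "fmriNF")

# substream codes keyed by generation stage
_STAGE_LATENTS = 0
_STAGE_BOLD = 1
_STAGE_RAW = 2
_STAGE_COUPLING = 1_000_003


@dataclass
class HRFParams:
    """Double-gamma hemodynamic response parameterization (seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_disp_s: float = 1.0
    undershoot_disp_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_delay_s", "undershoot_delay_s", "peak_disp_s",
                     "undershoot_disp_s", "undershoot_ratio", "duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticConfig:
    """Study-level generation settings.

    The defaults mirror the emulated acquisition: 9 subjects (one of the 10
    recorded subjects lacks a condition and is dropped), 3 neurofeedback
    conditions, 49 cortical regions, 64 EEG channels at 200 Hz, TR 2 s, and
    alternating rest/task blocks.
    """

    n_subjects: int = 9
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_regions: int = 49
    n_channels: int = 64
    tr_s: float = 2.0
    sfreq_hz: float = 200.0
    n_scans: int = 200
    block_len_scans: int = 20
    coupling_gain: float = 1.0
    pairs_per_region: int = 3
    ar_coef: float = 0.5
    block_amplitude: float = 1.0
    modulated_fraction: float = 0.25
    noise_sd: float = 1.0
    drift_slope_sd: float = 0.002
    outlier_rate: float = 0.0005
    outlier_scale: float = 6.0
    include_raw_eeg: bool = False
    raw_power_offset: float = 4.0
    raw_noise_sd: float = 0.1
    bands: tuple[BandDefinition, ...] = field(default_factory=lambda: tuple(DEFAULT_BANDS))
    hrf: HRFParams = field(default_factory=HRFParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) == 0 or len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be non-empty and unique")
        for name in ("n_subjects", "n_regions", "n_channels", "n_scans", "block_len_scans"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_scans % self.block_len_scans != 0:
            raise ValueError("n_scans must be divisible by block_len_scans")
        if self.coupling_gain < 0:
            raise ValueError("coupling_gain must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.drift_slope_sd < 0:
            raise ValueError("drift_slope_sd must be >= 0")
        if not (0 <= self.outlier_rate < 1):
            raise ValueError("outlier_rate must be in [0, 1)")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def block_design(self) -> np.ndarray:
        """0/1 vector per scan; blocks alternate rest (0) then task (1)."""
        n_blocks = self.n_scans // self.block_len_scans
        pattern = np.arange(n_blocks) % 2
        return np.repeat(pattern, self.block_len_scans).astype(float)

    def region_names(self) -> list[str]:
        return [f"region_{i:02d}" for i in range(self.n_regions)]

    def channel_names(self) -> list[str]:
        return [f"ch_{i:02d}" for i in range(self.n_channels)]


@dataclass
class CouplingSpec:
    """Ground-truth EEG→BOLD coupling: weights region × channel × band."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise ValueError("weights must be region × channel × band")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


@dataclass
class SessionData:
    band_powers: np.ndarray  # scans × channels × bands
    bold: np.ndarray  # scans × regions
    raw_eeg: np.ndarray | None = None  # channels × samples


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    sessions: dict[tuple[int, str], SessionData]
    coupling: CouplingSpec
    hrf_kernel: np.ndarray
    block_design: np.ndarray

    def session(self, subject: int, condition: str) -> SessionData:
        return self.sessions[(subject, condition)]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, *key]))


def make_hrf(params: HRFParams, tr_s: float) -> np.ndarray:
    """Double-gamma HRF sampled every ``tr_s`` seconds on [0, duration].

    Gamma-density difference (peak minus weighted undershoot), normalized so
    the sampled kernel has unit peak; the value at t = 0 is exactly 0.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    t = np.arange(0.0, params.duration_s + 1e-9, tr_s)
    peak = _stats.gamma.pdf(t, a=params.peak_delay_s / params.peak_disp_s,
                            scale=params.peak_disp_s)
    under = _stats.gamma.pdf(t, a=params.undershoot_delay_s / params.undershoot_disp_s,
                             scale=params.undershoot_disp_s)
    kernel = peak - params.undershoot_ratio * under
    peak_value = kernel.max()
    if peak_value <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return kernel / peak_value


def simulate_band_power_latents(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent band-power series: stationary AR(1) plus a block-design shift.

    Each channel-band pair follows AR(1) with coefficient ``cfg.ar_coef`` and
    unit stationary variance. The first ``modulated_fraction`` of channel-band
    pairs additionally gain ``block_amplitude`` during task blocks.
    """
    n, c, b = cfg.n_scans, cfg.n_channels, cfg.n_bands
    phi = cfg.ar_coef
    innov_sd = np.sqrt(1.0 - phi ** 2)
    latents = np.empty((n, c, b))
    latents[0] = rng.normal(0.0, 1.0, size=(c, b))
    eps = rng.normal(0.0, innov_sd, size=(n - 1, c, b))
    for t in range(1, n):
        latents[t] = phi * latents[t - 1] + eps[t - 1]
    design = cfg.block_design()
    n_mod = int(round(cfg.modulated_fraction * c * b))
    if n_mod > 0 and cfg.block_amplitude != 0:
        flat = latents.reshape(n, c * b)
        flat[:, :n_mod] += cfg.block_amplitude * design[:, None]
    return latents


def simulate_bold(
    latents: np.ndarray,
    coupling: CouplingSpec,
    hrf: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """BOLD = causal HRF convolution of coupled latents + drift + noise.

    The neural drive of region r is the coupling-weighted sum over
    channel-band latents; its convolution with the HRF is truncated at the
    session start (no pre-session history). Drift is linear in time with a
    per-region random slope (units of z per second).
    """
    n, c, b = latents.shape
    if coupling.weights.shape != (cfg.n_regions, c, b):
        raise ValueError(
            f"coupling weights shape {coupling.weights.shape} does not match "
            f"(n_regions={cfg.n_regions}, channels={c}, bands={b})")
    drive = np.einsum("tcb,rcb->tr", latents, coupling.weights)
    bold = np.empty((n, cfg.n_regions))
    for r in range(cfg.n_regions):
        bold[:, r] = np.convolve(drive[:, r], hrf)[:n]
    t_s = np.arange(n) * cfg.tr_s
    slopes = rng.normal(0.0, cfg.drift_slope_sd, size=cfg.n_regions)
    bold += slopes[None, :] * t_s[:, None]
    bold += rng.normal(0.0, cfg.noise_sd, size=bold.shape)
    if cfg.outlier_rate > 0:
        mask = rng.random(bold.shape) < cfg.outlier_rate
        bold[mask] += rng.choice([-1.0, 1.0], size=int(mask.sum())) * cfg.outlier_scale * cfg.noise_sd
    return bold


def _draw_coupling(cfg: SyntheticConfig) -> CouplingSpec:
    rng = _rng(cfg.seed, _STAGE_COUPLING)
    weights = np.zeros((cfg.n_regions, cfg.n_channels, cfg.n_bands))
    n_pairs = cfg.n_channels * cfg.n_bands
    k = min(cfg.pairs_per_region, n_pairs)
    for r in range(cfg.n_regions):
        idx = rng.choice(n_pairs, size=k, replace=False)
        signs = rng.choice([-1.0, 1.0], size=k)
        flat = weights[r].reshape(-1)
        flat[idx] = signs * cfg.coupling_gain
    return CouplingSpec(weights)


def _band_centers(cfg: SyntheticConfig) -> np.ndarray:
    return np.array([(band.low_hz + band.high_hz) / 2.0 for band in cfg.bands])


def _synthesize_raw_eeg(cfg: SyntheticConfig, latents: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Raw EEG as per-scan sums of band-limited sinusoids plus noise.

    Within each scan-aligned segment, channel c carries one sinusoid per
    band at the band's center frequency, with squared amplitude matching
    twice the (offset, rectified) latent band power so that the integrated
    PSD of the segment reproduces the latent power.
    """
    n, c, _ = latents.shape
    seg_len = int(round(cfg.tr_s * cfg.sfreq_hz))
    freqs = _band_centers(cfg)
    tau = np.arange(seg_len) / cfg.sfreq_hz
    signal = np.zeros((c, n * seg_len))
    power = np.clip(latents + cfg.raw_power_offset, 0.0, None)
    amplitude = np.sqrt(2.0 * power)  # band power a^2/2 = latent power
    phases = rng.uniform(0.0, 2.0 * np.pi, size=latents.shape)
    for t in range(n):
        sl = slice(t * seg_len, (t + 1) * seg_len)
        # (channels × bands × samples) summed over bands
        waves = amplitude[t][:, :, None] * np.sin(
            2.0 * np.pi * freqs[None, :, None] * tau[None, None, :]
            + phases[t][:, :, None])
        signal[:, sl] = waves.sum(axis=1)
    signal += rng.normal(0.0, cfg.raw_noise_sd, size=signal.shape)
    return signal


def generate_study(cfg: SyntheticConfig) -> SyntheticStudy:
    """Generate all subject × condition sessions with shared ground truth."""
    coupling = _draw_coupling(cfg)
    hrf = make_hrf(cfg.hrf, cfg.tr_s)
    sessions: dict[tuple[int, str], SessionData] = {}
    for s in range(cfg.n_subjects):
        for ci, cond in enumerate(cfg.conditions):
            latents = simulate_band_power_latents(cfg, _rng(cfg.seed, s, ci, _STAGE_LATENTS))
            bold = simulate_bold(latents, coupling, hrf, cfg, _rng(cfg.seed, s, ci, _STAGE_BOLD))
            band_powers = latents.copy()
            if cfg.outlier_rate > 0:
                rng_out = _rng(cfg.seed, s, ci, _STAGE_BOLD + 10)
                mask = rng_out.random(band_powers.shape) < cfg.outlier_rate
                band_powers[mask] += rng_out.choice([-1.0, 1.0], size=int(mask.sum())) * cfg.outlier_scale
            raw = None
            if cfg.include_raw_eeg:
                raw = _synthesize_raw_eeg(cfg, latents, _rng(cfg.seed, s, ci, _STAGE_RAW))
            sessions[(s, cond)] = SessionData(band_powers, bold, raw)
    return SyntheticStudy(cfg, sessions, coupling, hrf, cfg.block_design())


# ---------------------------------------------------------------------------
# plain-text study serialization (BIDS-inspired layout)

def write_study(study: SyntheticStudy, out_dir: str | Path) -> Path:
    """Write a study as TSV/JSON under ``out_dir``.

    Layout: ``sub-XX/cond-<name>/bold.tsv`` (scans × regions),
    ``band_powers.tsv`` (long format: scan, channel, band, value),
    ``truth.json`` and ``config.json`` at the root.
    """
    out = Path(out_dir)
    cfg = study.config
    out.mkdir(parents=True, exist_ok=True)
    band_names = [band.name for band in cfg.bands]
    for (s, cond), sess in study.sessions.items():
        d = out / f"sub-{s:02d}" / f"cond-{cond}"
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(sess.bold, columns=cfg.region_names()).rename_axis("scan").to_csv(
            d / "bold.tsv", sep="\t")
        n, c, b = sess.band_powers.shape
        long = pd.DataFrame({
            "scan": np.repeat(np.arange(n), c * b),
            "channel": np.tile(np.repeat(cfg.channel_names(), b), n),
            "band": np.tile(band_names, n * c),
            "value": sess.band_powers.reshape(-1),
        })
        long.to_csv(d / "band_powers.tsv", sep="\t", index=False)
    cfg_dict = asdict(cfg)
    cfg_dict["bands"] = [asdict(band) for band in cfg.bands]
    (out / "config.json").write_text(json.dumps(cfg_dict, indent=2))
    truth = {
        "coupling_weights": study.coupling.weights.tolist(),
        "hrf_kernel": study.hrf_kernel.tolist(),
        "block_design": study.block_design.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(truth))
    return out


def load_study(in_dir: str | Path) -> SyntheticStudy:
    """Read back a study written by :func:`write_study`."""
    root = Path(in_dir)
    cfg_dict = json.loads((root / "config.json").read_text())
    cfg_dict["bands"] = tuple(BandDefinition(**band) for band in cfg_dict["bands"])
    cfg_dict["hrf"] = HRFParams(**cfg_dict["hrf"])
    cfg_dict["conditions"] = tuple(cfg_dict["conditions"])
    cfg = SyntheticConfig(**cfg_dict)
    truth = json.loads((root / "truth.json").read_text())
    band_names = [band.name for band in cfg.bands]
    sessions: dict[tuple[int, str], SessionData] = {}
    for s in range(cfg.n_subjects):
        for cond in cfg.conditions:
            d = root / f"sub-{s:02d}" / f"cond-{cond}"
            bold = pd.read_csv(d / "bold.tsv", sep="\t", index_col=0).to_numpy(float)
            long = pd.read_csv(d / "band_powers.tsv", sep="\t")
            bp = np.empty((cfg.n_scans, cfg.n_channels, cfg.n_bands))
            channel_order = {name: i for i, name in enumerate(cfg.channel_names())}
            band_order = {name: i for i, name in enumerate(band_names)}
            bp[long["scan"].to_numpy(),
               long["channel"].map(channel_order).to_numpy(),
               long["band"].map(band_order).to_numpy()] = long["value"].to_numpy(float)
            sessions[(s, cond)] = SessionData(bp, bold)
    return SyntheticStudy(cfg, sessions,
                          CouplingSpec(np.array(truth["coupling_weights"])),
                          np.array(truth["hrf_kernel"]),
                          np.array(truth["block_design"]))
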