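"""Foundation-model branch: deterministic prompt builders, a strict
response parser, and a pluggable text-generation backend with mocks.

Each cortical region is associated with one EEG channel (or five, in the
extended mode) that serves as its predictor; prompts present the channel's
windowed, normalized band powers as a dictionary-like structure and ask
whether the region's BOLD signal is increasing or decreasing. A response
counts as a prediction only when exactly one of the keyword stems
``increas-`` / ``decreas-`` appears; otherwise it is invalid and excluded
from scoring (with its proportion reported). Real language-model inference
is behind a one-method backend contract; the shipped backends are
deterministic mocks, so the whole branch is testable offline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg_prep import DEFAULT_BANDS, BandDefinition
from .evaluation import (McNemarSummary, ResampledBaselineConfig,
                         mcnemar_vs_resampled_baseline,
                         wilcoxon_vs_resampled_baseline)
from .features import LABEL_DECREASE, LABEL_INCREASE

__all__ = [
    "RegionChannelMap", "DEFAULT_REGION_CHANNEL_MAP",
    "PromptBundle", "ParsedPrediction", "build_prompt", "parse_response",
    "TextBackend", "OracleBackend", "ConstantBackend", "ScriptedBackend",
    "InvalidInjectionBackend", "FoundationEvalResult", "run_foundation_eval",
]

PROMPT_MODES = ("single_channel", "cot_step1", "cot_step2", "multimodal",
                "five_channel")

_TEMPLATE_SINGLE = (
    "A human subject participated in a neuroscience experiment where EEG "
    "data and fMRI data were recorded simultaneously. The EEG band powers "
    "were measured every two seconds at electrode {channel}, with the "
    "following results: {results}. The fMRI BOLD signal was measured in the "
    "{region} during the last two seconds. Given the EEG data, is the fMRI "
    "signal in this brain region likely increasing or decreasing during "
    "these last two seconds? Base your answer on your general knowledge in "
    "neuroscience, EEG research, and fMRI research. Since this is a time "
    "series, you might need to take into account the hemodynamic response "
    "function (HRF), and the fact that after an event, the fMRI response is "
    "delayed compared to the EEG response. Please answer with only one "
    "word: Increasing or Decreasing. Just give your best prediction, "
    "without any explanation."
)

_TEMPLATE_COT1 = (
    "A human subject participated in a neuroscience experiment where EEG "
    "data and fMRI data were recorded simultaneously. The EEG band powers "
    "were measured every two seconds at electrode {channel}, with the "
    "following results: {results}. Given the EEG data, which cognitive "
    "functions is the subject likely engaging in? Base your answer on your "
    "general knowledge in neuroscience and EEG research. Please answer with "
    "only a list of cognitive functions. Just give your best prediction, "
    "without any explanation."
)

_TEMPLATE_COT2 = (
    "A human subject participated in a neuroscience experiment where EEG "
    "data and fMRI data were recorded simultaneously. This subject "
    "experienced the following cognitive functions: {functions}. The fMRI "
    "BOLD signal was measured in the {region}. Given the cognitive "
    "functions, is the fMRI signal in this brain region likely increasing "
    "or decreasing? Base your answer on your general knowledge in "
    "neuroscience and fMRI research. Please answer with only one word: "
    "Increasing or Decreasing. Just give your best prediction, without any "
    "explanation."
)

_TEMPLATE_MULTIMODAL = (
    "A human subject participated in a neuroscience experiment where EEG "
    "data and fMRI data were recorded simultaneously. This EEG topographic "
    "map shows the brain activity pattern observed for the band power "
    "{band}. The fMRI BOLD signal was measured in the {region} four seconds "
    "after that. Given the EEG data, is the fMRI signal in this brain "
    "region likely increasing or decreasing? Base your answer on your "
    "general knowledge in neuroscience, EEG research, and fMRI research. "
    "Please answer with only one word: Increasing or Decreasing. Just give "
    "your best prediction, without any explanation."
)

_TEMPLATE_FIVE = (
    "A human subject participated in a neuroscience experiment where EEG "
    "data and fMRI data were recorded simultaneously. The EEG band powers "
    "were measured every two seconds at electrodes {channels}, with the "
    "following results: {results}. The fMRI BOLD signal was measured in the "
    "{region} during the last two seconds. Given the EEG data, is the fMRI "
    "signal in this brain region likely increasing or decreasing during "
    "these last two seconds? Base your answer on your general knowledge in "
    "neuroscience, EEG research, and fMRI research. Since this is a time "
    "series, you might need to take into account the hemodynamic response "
    "function (HRF), and the fact that after an event, the fMRI response is "
    "delayed compared to the EEG response. Please answer with only one "
    "word: Increasing or Decreasing. Just give your best prediction, "
    "without any explanation."
)


@dataclass
class RegionChannelMap:
    """Region → ordered EEG channels (1 for single mode, 5 for extended)."""

    entries: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.entries = {region: list(chs) for region, chs in self.entries.items()}

    def channels_for(self, region: str, n: int) -> list[str]:
        if region not in self.entries:
            raise ValueError(f"region {region!r} is not in the region-channel map")
        channels = self.entries[region][:n]
        if len(channels) < n:
            raise ValueError(f"region {region!r} maps to {len(channels)} "
                             f"channels, mode needs {n}")
        return channels

    def to_tsv(self, path: str | Path) -> None:
        width = max(len(chs) for chs in self.entries.values())
        rows = [{"region": region,
                 **{f"channel{i + 1}": (chs[i] if i < len(chs) else "")
                    for i in range(width)}}
                for region, chs in self.entries.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionChannelMap":
        frame = pd.read_csv(path, sep="\t").fillna("")
        entries = {}
        channel_cols = [col for col in frame.columns if col.startswith("channel")]
        for _, row in frame.iterrows():
            entries[row["region"]] = [row[col] for col in channel_cols if row[col]]
        return cls(entries)


# Proximity-based default mapping for a documented subset of the
# Harvard-Oxford cortical regions (first channel = single-channel mode;
# all five = extended mode). Replace wholesale via RegionChannelMap.from_tsv.
DEFAULT_REGION_CHANNEL_MAP = RegionChannelMap({
    "Frontal Pole": ["Fpz", "Fp1", "Fp2", "AFz", "AF3"],
    "Superior Frontal Gyrus": ["Fz", "F1", "F2", "FCz", "AFz"],
    "Middle Frontal Gyrus": ["F3", "F5", "F1", "FC3", "AF3"],
    "Precentral Gyrus": ["C3", "C1", "C5", "FC3", "CP3"],
    "Postcentral Gyrus": ["CP3", "CP1", "CP5", "C3", "P3"],
    "Superior Parietal Lobule": ["Pz", "P1", "P2", "POz", "CPz"],
    "Superior Temporal Gyrus, anterior division": ["T7", "FT7", "TP7", "C5", "CP5"],
    "Insular Cortex": ["C5", "T7", "CP5", "FC5", "C3"],
    "Lateral Occipital Cortex, inferior division": ["PO7", "O1", "PO3", "P7", "P5"],
    "Cuneal Cortex": ["POz", "Oz", "PO3", "PO4", "Pz"],
    "Occipital Pole": ["Oz", "O1", "O2", "POz", "PO7"],
})


@dataclass
class PromptBundle:
    mode: str
    text: str
    attachments: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)  # subject, condition, region, scans

    def __post_init__(self) -> None:
        if self.mode not in PROMPT_MODES:
            raise ValueError(f"unknown prompt mode {self.mode!r}")
        if not self.text:
            raise ValueError("prompt text must be non-empty")
        if self.mode == "multimodal" and len(self.attachments) != 1:
            raise ValueError("multimodal mode requires exactly one attachment")


@dataclass
class ParsedPrediction:
    label: str  # increase | decrease | invalid
    matched_spans: list[tuple[int, int]]
    raw_response: str


def _format_results(values: np.ndarray, bands: tuple[BandDefinition, ...],
                    decimals: int) -> str:
    """Dictionary-like band → bracketed comma-separated values string."""
    values = np.atleast_2d(np.asarray(values, float))  # steps × bands
    parts = []
    for bi, band in enumerate(bands):
        nums = ", ".join(f"{v:.{decimals}f}" for v in values[:, bi])
        parts.append(f'"{band.label}": [{nums}]')
    return "{" + ", ".join(parts) + "}"


def build_prompt(
    mode: str,
    mapping: RegionChannelMap,
    band_values: np.ndarray | None,
    region: str,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    decimals: int = 2,
    cognitive_functions: str | None = None,
    band_label: str | None = None,
    attachment: str | None = None,
    provenance: dict | None = None,
) -> PromptBundle:
    """Fill the template for ``mode`` and return a deterministic bundle.

    ``band_values``: steps × bands for the single-channel modes, or
    channels × steps × bands (5 channels, mapping order) for the extended
    mode; values are rendered with ``decimals`` decimal places.
    """
    if mode not in PROMPT_MODES:
        raise ValueError(f"unknown prompt mode {mode!r}")
    provenance = dict(provenance or {})
    provenance.setdefault("region", region)
    attachments: list[str] = []

    if mode in ("single_channel", "cot_step1"):
        channel = mapping.channels_for(region, 1)[0]
        values = np.atleast_2d(np.asarray(band_values, float))
        if values.ndim != 2 or values.shape[1] != len(bands):
            raise ValueError("single-channel modes need steps × bands values")
        results = _format_results(values, bands, decimals)
        template = _TEMPLATE_SINGLE if mode == "single_channel" else _TEMPLATE_COT1
        text = template.format(channel=channel, results=results, region=region)
    elif mode == "cot_step2":
        if not cognitive_functions:
            raise ValueError("cot_step2 requires the predicted cognitive functions")
        text = _TEMPLATE_COT2.format(functions=cognitive_functions, region=region)
    elif mode == "multimodal":
        if band_label is None:
            band_label = next(b.label for b in bands if b.name == "beta")
        if attachment is None:
            raise ValueError("multimodal mode requires an attachment reference")
        attachments = [attachment]
        text = _TEMPLATE_MULTIMODAL.format(band=band_label, region=region)
    else:  # five_channel
        channels = mapping.channels_for(region, 5)
        values = np.asarray(band_values, float)
        if values.ndim != 3 or values.shape[0] != 5 or values.shape[2] != len(bands):
            raise ValueError("five_channel mode needs 5 × steps × bands values")
        nested = ", ".join(
            f'"{ch}": {_format_results(values[i], bands, decimals)}'
            for i, ch in enumerate(channels))
        text = _TEMPLATE_FIVE.format(channels=", ".join(channels),
                                     results="{" + nested + "}", region=region)
    return PromptBundle(mode, text, attachments, provenance)


_KEYWORD_RE = re.compile(r"(increas|decreas)", re.IGNORECASE)


def parse_response(raw: str) -> ParsedPrediction:
    """Total parser: exactly one keyword family present → that label;
    zero or both → invalid. Never raises."""
    raw = "" if raw is None else str(raw)
    spans: list[tuple[int, int]] = []
    families = set()
    for match in _KEYWORD_RE.finditer(raw):
        spans.append(match.span())
        families.add(match.group(1).lower())
    if families == {"increas"}:
        label = LABEL_INCREASE
    elif families == {"decreas"}:
        label = LABEL_DECREASE
    else:
        label = "invalid"
    return ParsedPrediction(label, spans, raw)


# ---------------------------------------------------------------------------
# backends

class TextBackend:
    """Text-in/text-out generation contract.

    Real language-model adapters implement :meth:`generate`; the shipped
    mock backends are fully deterministic given their seed.
    """

    deterministic: bool = True

    def generate(self, prompt: str) -> str:  # pragma: no cover - interface
        raise NotImplementedError


class OracleBackend(TextBackend):
    """Answers from a provenance-key → truth-label lookup (upper bound)."""

    def __init__(self, answers: dict[str, str]):
        self.answers = answers

    def generate(self, prompt: str) -> str:
        raise NotImplementedError("OracleBackend is queried per bundle")

    def generate_for(self, bundle: PromptBundle) -> str:
        label = self.answers[_bundle_key(bundle)]
        return "Increasing." if label == LABEL_INCREASE else "Decreasing."


class ConstantBackend(TextBackend):
    def __init__(self, text: str = "Increasing."):
        self.text = text

    def generate(self, prompt: str) -> str:
        return self.text


class ScriptedBackend(TextBackend):
    """Replays a fixed list of responses in order."""

    def __init__(self, responses: list[str]):
        self.responses = list(responses)
        self._cursor = 0

    def generate(self, prompt: str) -> str:
        response = self.responses[self._cursor % len(self.responses)]
        self._cursor += 1
        return response


class InvalidInjectionBackend(TextBackend):
    """Wraps a backend, replacing a fraction of responses with keyword-free
    text to exercise the invalid-prediction path."""

    def __init__(self, inner: TextBackend, invalid_rate: float, seed: int = 0,
                 invalid_text: str = "banana"):
        self.inner = inner
        self.invalid_rate = invalid_rate
        self.invalid_text = invalid_text
        self._rng = np.random.default_rng(seed)

    def generate(self, prompt: str) -> str:
        if self._rng.random() < self.invalid_rate:
            return self.invalid_text
        return self.inner.generate(prompt)


def _bundle_key(bundle: PromptBundle) -> str:
    prov = bundle.provenance
    return "|".join(str(prov.get(k, "")) for k in
                    ("subject", "condition", "region", "scan"))


# ---------------------------------------------------------------------------
# evaluation harness

@dataclass
class FoundationEvalResult:
    n_bundles: int
    n_invalid: int
    accuracy: float
    mcnemar: McNemarSummary
    wilcoxon: McNemarSummary | None
    predictions: np.ndarray
    truths: np.ndarray
    responses: list[str]

    @property
    def invalid_proportion(self) -> float:
        return self.n_invalid / self.n_bundles if self.n_bundles else 0.0

    @property
    def n_evaluated(self) -> int:
        return self.n_bundles - self.n_invalid


def run_foundation_eval(
    bundles: list[PromptBundle],
    backend: TextBackend,
    truths: np.ndarray,
    cfg: ResampledBaselineConfig,
    log_path: str | Path | None = None,
) -> FoundationEvalResult:
    """Query the backend per bundle, parse, exclude invalids, then run the
    resampled-baseline McNemar (pooled) and, when per-pair grouping allows,
    the resampled-baseline Wilcoxon path.

    Backend failures are recorded as invalid predictions, never raised.
    """
    truths = np.asarray(truths)
    if len(bundles) != len(truths):
        raise ValueError("bundles and truths must align")
    responses: list[str] = []
    labels: list[str] = []
    for bundle in bundles:
        try:
            if isinstance(backend, OracleBackend):
                raw = backend.generate_for(bundle)
            else:
                raw = backend.generate(bundle.text)
        except Exception as err:  # failure => invalid, not a crash
            raw = f"<backend error: {err}>"
        responses.append(raw)
        labels.append(parse_response(raw).label)
    labels_arr = np.array(labels, dtype=object)
    valid = labels_arr != "invalid"
    n_invalid = int((~valid).sum())
    predictions = labels_arr[valid].astype(str)
    kept_truths = truths[valid].astype(str)
    if predictions.size == 0:
        raise ValueError("empty prediction set after exclusions")
    accuracy = float(np.mean(predictions == kept_truths))
    mcnemar = mcnemar_vs_resampled_baseline(predictions, kept_truths, cfg)
    pair_ids = np.array([
        f'{b.provenance.get("subject", "")}|{b.provenance.get("region", "")}'
        for b, keep in zip(bundles, valid) if keep])
    wilcoxon = None
    if len(np.unique(pair_ids)) >= 5:
        wilcoxon = wilcoxon_vs_resampled_baseline(predictions, kept_truths,
                                                  pair_ids, cfg)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for bundle, raw, label in zip(bundles, responses, labels):
                fh.write(json.dumps({"provenance": bundle.provenance,
                                     "prompt": bundle.text,
                                     "response": raw, "label": label}) + "\n")
    return FoundationEvalResult(len(bundles), n_invalid, accuracy, mcnemar,
                                wilcoxon, predictions, kept_truths, responses)
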