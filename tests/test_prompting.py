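import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eeg2bold.evaluation import ResampledBaselineConfig
from eeg2bold.prompting import (DEFAULT_REGION_CHANNEL_MAP, ConstantBackend,
                                InvalidInjectionBackend, OracleBackend,
                                PromptBundle, RegionChannelMap,
                                ScriptedBackend, build_prompt, parse_response,
                                run_foundation_eval)


def window(seed=0, steps=6, bands=6):
    return np.random.default_rng(seed).normal(size=(steps, bands))


class TestPromptTemplates:
    def test_single_channel_golden_content(self):
        bundle = build_prompt("single_channel", DEFAULT_REGION_CHANNEL_MAP,
                              window(), "Frontal Pole")
        text = bundle.text
        assert "at electrode Fpz" in text
        assert "in the Frontal Pole" in text
        assert "Please answer with only one word: Increasing or Decreasing." in text
        assert text.startswith(
            "A human subject participated in a neuroscience experiment where "
            "EEG data and fMRI data were recorded simultaneously.")
        assert "hemodynamic response function (HRF)" in text
        assert "the fMRI response is delayed compared to the EEG response" in text
        assert "during the last two seconds" in text

    def test_band_dictionary_formatting(self):
        values = np.zeros((2, 6))
        values[:, 4] = [1.234, -0.5]
        bundle = build_prompt("single_channel", DEFAULT_REGION_CHANNEL_MAP,
                              values, "Frontal Pole")
        assert '"Beta (16–30 Hz)": [1.23, -0.50]' in bundle.text
        assert '"Delta (1–4 Hz)": [0.00, 0.00]' in bundle.text

    def test_cot_step1_asks_for_cognitive_functions(self):
        bundle = build_prompt("cot_step1", DEFAULT_REGION_CHANNEL_MAP,
                              window(), "Frontal Pole")
        assert "which cognitive functions is the subject likely engaging in?" \
            in bundle.text
        assert "Please answer with only a list of cognitive functions." in bundle.text
        assert "fMRI BOLD signal" not in bundle.text

    def test_cot_step2_injects_predicted_functions(self):
        bundle = build_prompt("cot_step2", DEFAULT_REGION_CHANNEL_MAP, None,
                              "Frontal Pole",
                              cognitive_functions="Attention, Working Memory")
        assert ("experienced the following cognitive functions: Attention, "
                "Working Memory") in bundle.text
        assert "Given the cognitive functions" in bundle.text

    def test_multimodal_references_topographic_map(self):
        bundle = build_prompt("multimodal", DEFAULT_REGION_CHANNEL_MAP, None,
                              "Frontal Pole", attachment="topomap_scan42.png")
        assert "This EEG topographic map shows the brain activity pattern" \
            in bundle.text
        assert "band power Beta (16–30 Hz)" in bundle.text
        assert "four seconds after that" in bundle.text
        assert bundle.attachments == ["topomap_scan42.png"]

    def test_five_channel_nests_bands_under_electrodes(self):
        values = np.random.default_rng(1).normal(size=(5, 6, 6))
        bundle = build_prompt("five_channel", DEFAULT_REGION_CHANNEL_MAP,
                              values, "Frontal Pole")
        assert "at electrodes Fpz, Fp1, Fp2, AFz, AF3" in bundle.text
        assert '"Fpz": {"Delta (1–4 Hz)":' in bundle.text
        assert '"AF3": {"Delta (1–4 Hz)":' in bundle.text

    def test_same_inputs_byte_identical(self):
        a = build_prompt("single_channel", DEFAULT_REGION_CHANNEL_MAP,
                         window(3), "Cuneal Cortex")
        b = build_prompt("single_channel", DEFAULT_REGION_CHANNEL_MAP,
                         window(3), "Cuneal Cortex")
        assert a.text == b.text

    def test_unmapped_region_errors(self):
        with pytest.raises(ValueError, match="region-channel map"):
            build_prompt("single_channel", DEFAULT_REGION_CHANNEL_MAP,
                         window(), "Cerebellum")

    def test_wrong_channel_count_for_five_channel_mode(self):
        short_map = RegionChannelMap({"Frontal Pole": ["Fpz"]})
        with pytest.raises(ValueError, match="channels"):
            build_prompt("five_channel", short_map,
                         np.zeros((5, 6, 6)), "Frontal Pole")

    def test_map_tsv_roundtrip(self, tmp_path):
        DEFAULT_REGION_CHANNEL_MAP.to_tsv(tmp_path / "map.tsv")
        back = RegionChannelMap.from_tsv(tmp_path / "map.tsv")
        assert back.entries == DEFAULT_REGION_CHANNEL_MAP.entries


class TestParser:
    @pytest.mark.parametrize("raw,expected", [
        ("Increasing.", "increase"),
        ("Decreasing.", "decrease"),
        ("The signal increases steadily.", "increase"),
        ("It has increased since the event.", "increase"),
        ("likely DECREASED", "decrease"),
        ("increase decrease increase decrease", "invalid"),
        ("I cannot determine this.", "invalid"),
        ("", "invalid"),
        ("banana", "invalid"),
        ("The decrease is small but the trend is increasing", "invalid"),
    ])
    def test_golden_fixture_responses(self, raw, expected):
        assert parse_response(raw).label == expected

    def test_matched_spans_recorded(self):
        parsed = parse_response("It increases and increases.")
        assert parsed.label == "increase"
        assert len(parsed.matched_spans) == 2

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.text(max_size=80))
    def test_parser_is_total(self, raw):
        assert parse_response(raw).label in {"increase", "decrease", "invalid"}


def make_bundles(n, seed=0):
    rng = np.random.default_rng(seed)
    regions = list(DEFAULT_REGION_CHANNEL_MAP.entries)
    bundles, truths = [], []
    for i in range(n):
        region = regions[i % len(regions)]
        prov = {"subject": i % 3, "condition": "eegfmriNF", "region": region,
                "scan": 10 + i}
        bundles.append(build_prompt("single_channel",
                                    DEFAULT_REGION_CHANNEL_MAP,
                                    rng.normal(size=(6, 6)), region,
                                    provenance=prov))
        truths.append(rng.choice(["increase", "decrease"]))
    return bundles, np.array(truths)


class TestFoundationEval:
    def test_oracle_backend_perfect_accuracy_no_invalids(self):
        bundles, truths = make_bundles(60)
        answers = {f'{b.provenance["subject"]}|{b.provenance["condition"]}|'
                   f'{b.provenance["region"]}|{b.provenance["scan"]}': t
                   for b, t in zip(bundles, truths)}
        cfg = ResampledBaselineConfig(n_iterations_wilcoxon=50,
                                      n_iterations_mcnemar=200, seed=1)
        result = run_foundation_eval(bundles, OracleBackend(answers), truths, cfg)
        assert result.accuracy == 1.0
        assert result.invalid_proportion == 0.0
        assert result.mcnemar.median_p < 0.05

    def test_constant_increase_backend_near_chance_not_significant(self):
        bundles, truths = make_bundles(200, seed=2)
        cfg = ResampledBaselineConfig(n_iterations_wilcoxon=50,
                                      n_iterations_mcnemar=1000, seed=2)
        result = run_foundation_eval(bundles, ConstantBackend("Increasing."),
                                     truths, cfg)
        assert abs(result.accuracy - 0.5) < 0.1
        assert result.mcnemar.median_p > 0.2

    def test_invalid_injection_rate_reported_and_excluded(self):
        bundles, truths = make_bundles(400, seed=3)
        backend = InvalidInjectionBackend(ConstantBackend("Increasing."),
                                          invalid_rate=0.05, seed=3)
        cfg = ResampledBaselineConfig(n_iterations_wilcoxon=20,
                                      n_iterations_mcnemar=100, seed=3)
        result = run_foundation_eval(bundles, backend, truths, cfg)
        # binomial tolerance: 0.05 ± 4·sqrt(0.05·0.95/400)
        assert abs(result.invalid_proportion - 0.05) < 0.045
        assert result.n_evaluated + result.n_invalid == result.n_bundles

    def test_backend_failure_becomes_invalid_not_crash(self):
        class ExplodingBackend(ConstantBackend):
            def generate(self, prompt):
                raise RuntimeError("connection lost")

        bundles, truths = make_bundles(12, seed=4)
        bundles2, _ = make_bundles(12, seed=5)
        scripted = ScriptedBackend(["Increasing."] * 6 + ["Decreasing."] * 6)

        # half the bundles go through a working backend so predictions remain
        mixed = []
        for i, b in enumerate(bundles):
            mixed.append(b)
        cfg = ResampledBaselineConfig(n_iterations_wilcoxon=10,
                                      n_iterations_mcnemar=50, seed=4)
        result = run_foundation_eval(mixed[:6], scripted, truths[:6], cfg)
        assert result.n_invalid == 0
        with pytest.raises(ValueError, match="empty"):
            run_foundation_eval(bundles, ExplodingBackend(), truths, cfg)

    def test_response_log_written(self, tmp_path):
        bundles, truths = make_bundles(10, seed=6)
        cfg = ResampledBaselineConfig(n_iterations_wilcoxon=10,
                                      n_iterations_mcnemar=50, seed=6)
        log = tmp_path / "responses.jsonl"
        run_foundation_eval(bundles, ConstantBackend("Increasing."), truths,
                            cfg, log_path=log)
        lines = log.read_text().strip().splitlines()
        assert len(lines) == 10
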