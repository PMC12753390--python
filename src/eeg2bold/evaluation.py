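"""The study harness: condition-rotation cross-validation, constant
baselines, the bespoke statistical layer, and the end-to-end experiment
runner.

Statistics follow the study design: each model's per-pair metric (accuracy
or MAE over one subject × region × iteration test set) is compared against
a constant baseline with a one-sided Wilcoxon signed-rank test (exact null
distribution up to 25 informative pairs, normal approximation with
continuity and tie correction above), with matched-pairs rank-biserial
correlation and common-language effect size as effect sizes. Foundation
models, which act on far fewer scans, are instead compared against a
resampled baseline that draws labels from the empirical target
distribution, iterated many times to yield a p-value distribution
summarized by its median and the proportion of significant iterations
(McNemar; exact binomial on the discordant pairs when few, corrected
chi-square otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import models as _models
from .eeg_prep import normalize_band_powers
from .features import (LABEL_INCREASE, SupervisedSet, build_features,
                       build_targets)
from .fmri_prep import preprocess_bold
from .models import ModelSpec
from .synthetic import SyntheticConfig, SyntheticStudy, generate_study

__all__ = [
    "CVPlan", "CVIteration", "make_cv_plan",
    "ConstantIncreasePredictor", "ConstantZeroPredictor", "constant_baselines",
    "WilcoxonResult", "wilcoxon_one_sided",
    "McNemarSummary", "mcnemar_exact_or_chi2", "mcnemar_vs_resampled_baseline",
    "wilcoxon_vs_resampled_baseline",
    "ResampledBaselineConfig", "ExperimentConfig", "ExperimentResult",
    "run_experiment", "benjamini_hochberg",
]


# ---------------------------------------------------------------------------
# cross-validation plan

@dataclass(frozen=True)
class CVIteration:
    train_condition: str
    test_condition: str
    third_condition: str
    third_role: str  # "left_out" | "validation"


@dataclass(frozen=True)
class CVPlan:
    iterations: tuple[CVIteration, ...]


def make_cv_plan(conditions: tuple[str, ...] | list[str],
                 needs_validation: bool = False) -> CVPlan:
    """Threefold condition rotation: iteration i trains on condition i and
    tests on condition i+1 (cyclically); the third condition is either left
    out (classical families) or used for validation (neural families).
    """
    conditions = tuple(conditions)
    if len(conditions) != 3:
        raise ValueError(f"condition rotation needs exactly 3 conditions, "
                         f"got {len(conditions)}")
    role = "validation" if needs_validation else "left_out"
    iterations = []
    for i in range(3):
        iterations.append(CVIteration(
            train_condition=conditions[i],
            test_condition=conditions[(i + 1) % 3],
            third_condition=conditions[(i + 2) % 3],
            third_role=role))
    return CVPlan(tuple(iterations))


# ---------------------------------------------------------------------------
# constant baselines

class ConstantIncreasePredictor:
    """Always predicts an increase — the (near-)majority class."""

    def predict(self, X) -> np.ndarray:
        n = len(X)
        return np.full(n, LABEL_INCREASE, dtype=object)


class ConstantZeroPredictor:
    """Always predicts 0, the mean of a z-normalized target."""

    def predict(self, X) -> np.ndarray:
        return np.zeros(len(X))


def constant_baselines(task: str):
    if task == "classification":
        return ConstantIncreasePredictor()
    if task == "regression":
        return ConstantZeroPredictor()
    raise ValueError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (one-sided), exact for small n

@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float  # favorable-direction rank sum
    rbc: float
    cles: float
    n_informative: int


def _signed_rank_exact_p(doubled_ranks: np.ndarray, w2_obs: float) -> float:
    """P(W >= w_obs) by subset-sum dynamic programming over the doubled
    (hence integer) signed ranks; exact, ties included."""
    total = int(round(doubled_ranks.sum()))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in np.rint(doubled_ranks).astype(int):
        counts[r:] += counts[:total + 1 - r]
    tail = counts[int(np.ceil(w2_obs - 1e-9)):].sum()
    return float(tail / counts.sum())


def wilcoxon_one_sided(paired_metrics: np.ndarray, paired_baselines: np.ndarray,
                       direction: str = "greater",
                       exact_threshold: int = 25) -> WilcoxonResult:
    """One-sided Wilcoxon signed-rank test of metric vs baseline per pair.

    ``direction="greater"`` tests whether metrics exceed baselines (accuracy);
    ``direction="less"`` tests the opposite (MAE). Zero differences are
    discarded before ranking (classic signed-rank). Up to ``exact_threshold``
    informative pairs the null distribution is enumerated exactly; above, a
    normal approximation with tie correction and a 0.5 continuity correction
    is used.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    d = np.asarray(paired_metrics, float) - np.asarray(paired_baselines, float)
    if direction == "less":
        d = -d
    n_total = len(d)
    informative = d != 0
    d_inf = d[informative]
    n = len(d_inf)
    if n == 0:
        raise ValueError("undefined test: all paired differences are zero")
    if n < 5:
        raise ValueError(f"need at least 5 informative pairs, got {n}")
    ranks = _stats.rankdata(np.abs(d_inf))
    w_pos = float(ranks[d_inf > 0].sum())
    w_neg = float(ranks[d_inf < 0].sum())
    if n <= exact_threshold:
        p = _signed_rank_exact_p(2.0 * ranks, 2.0 * w_pos)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        z = (w_pos - 0.5 - mean) / np.sqrt(var)
        p = float(_stats.norm.sf(z))
    rbc = (w_pos - w_neg) / (w_pos + w_neg)
    cles = (float((d > 0).sum()) + 0.5 * float((d == 0).sum())) / n_total
    return WilcoxonResult(p, w_pos, rbc, cles, n)


# ---------------------------------------------------------------------------
# McNemar against a resampled baseline

@dataclass
class ResampledBaselineConfig:
    n_iterations_wilcoxon: int = 1000
    n_iterations_mcnemar: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations_wilcoxon < 1 or self.n_iterations_mcnemar < 1:
            raise ValueError("iteration counts must be >= 1")


def mcnemar_exact_or_chi2(b: int, c: int, exact_threshold: int = 25) -> float:
    """Two-sided McNemar p from the discordant counts.

    Exact doubled binomial tail when b + c <= ``exact_threshold``; otherwise
    the continuity-corrected chi-square.
    """
    n_disc = b + c
    if n_disc == 0:
        return 1.0
    if n_disc <= exact_threshold:
        return float(min(1.0, 2.0 * _stats.binom.cdf(min(b, c), n_disc, 0.5)))
    stat = (abs(b - c) - 1.0) ** 2 / n_disc
    return float(_stats.chi2.sf(stat, df=1))


@dataclass
class McNemarSummary:
    p_values: np.ndarray
    median_p: float
    proportion_significant: float  # fraction of iterations with p < 0.05
    histogram: np.ndarray = field(default=None)  # counts on 20 equal bins of [0, 1]
    bin_edges: np.ndarray = field(default=None)


def _summarize_p_values(p_values: np.ndarray) -> McNemarSummary:
    p_values = np.asarray(p_values, float)
    counts, edges = np.histogram(p_values, bins=20, range=(0.0, 1.0))
    return McNemarSummary(p_values, float(np.median(p_values)),
                          float(np.mean(p_values < 0.05)), counts, edges)


def mcnemar_vs_resampled_baseline(
    predictions: np.ndarray,
    truths: np.ndarray,
    cfg: ResampledBaselineConfig,
) -> McNemarSummary:
    """Iterated McNemar test of a model against a label-resampling baseline.

    Each iteration draws one baseline prediction per scan from the empirical
    truth distribution (invalid predictions must have been excluded before
    the call), forms the model-vs-baseline 2×2 correctness table pooled over
    all scans, and computes the McNemar p-value.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must align")
    if len(predictions) == 0:
        raise ValueError("empty prediction set after exclusions")
    rng = np.random.default_rng(cfg.seed)
    model_correct = predictions == truths
    n = len(truths)
    p_values = np.empty(cfg.n_iterations_mcnemar)
    for i in range(cfg.n_iterations_mcnemar):
        baseline = rng.choice(truths, size=n, replace=True)
        base_correct = baseline == truths
        b = int(np.sum(model_correct & ~base_correct))
        c = int(np.sum(~model_correct & base_correct))
        p_values[i] = mcnemar_exact_or_chi2(b, c)
    return _summarize_p_values(p_values)


def wilcoxon_vs_resampled_baseline(
    predictions: np.ndarray,
    truths: np.ndarray,
    pair_ids: np.ndarray,
    cfg: ResampledBaselineConfig,
) -> McNemarSummary:
    """Iterated one-sided Wilcoxon test of per-pair model accuracy against
    per-pair accuracy of the label-resampling baseline."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    pair_ids = np.asarray(pair_ids)
    rng = np.random.default_rng(cfg.seed + 1)
    unique_pairs = np.unique(pair_ids)
    model_acc = np.array([
        np.mean(predictions[pair_ids == g] == truths[pair_ids == g])
        for g in unique_pairs])
    p_values = np.empty(cfg.n_iterations_wilcoxon)
    for i in range(cfg.n_iterations_wilcoxon):
        baseline = rng.choice(truths, size=len(truths), replace=True)
        base_correct = baseline == truths
        base_acc = np.array([np.mean(base_correct[pair_ids == g])
                             for g in unique_pairs])
        try:
            p_values[i] = wilcoxon_one_sided(model_acc, base_acc, "greater").p_value
        except ValueError:  # all differences zero or too few informative
            p_values[i] = 1.0
    return _summarize_p_values(p_values)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (step-up false discovery rate control)."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


# ---------------------------------------------------------------------------
# experiment runner

@dataclass
class ExperimentConfig:
    synthetic: SyntheticConfig
    model_specs: list[ModelSpec]
    n_lags: int = 5
    tune_grids: dict[str, dict] = field(default_factory=dict)  # family → grid
    seed: int = 0


@dataclass
class ModelStats:
    model: str
    task: str
    mean_metric: float
    sem_metric: float
    mean_baseline: float
    p_value: float
    rbc: float
    cles: float
    pearson_r: float | None
    n_pairs: int


@dataclass
class StatReport:
    per_model: dict[str, ModelStats]
    pairwise_p: pd.DataFrame  # one-sided p that the row model beats the column model
    per_roi: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "per_model": {name: vars(ms) for name, ms in self.per_model.items()},
            "pairwise_p": self.pairwise_p.to_dict(),
            "per_roi": self.per_roi.to_dict(orient="list"),
        }


@dataclass
class ExperimentResult:
    pair_table: pd.DataFrame
    report: StatReport
    exclusions: list[dict]
    study: SyntheticStudy


def _model_name(spec: ModelSpec) -> str:
    return f"{spec.family}_{spec.task[:3]}"


def _prepare_sessions(study: SyntheticStudy, n_lags: int):
    """Preprocess every session once: features shared across regions,
    per-region targets aligned to scans >= n_lags."""
    cfg = study.config
    prepared: dict[tuple[int, str], dict] = {}
    for (subject, condition), sess in study.sessions.items():
        bp = normalize_band_powers(sess.band_powers, cfg.channel_names(),
                                   cfg.bands, tr_s=cfg.tr_s)
        rts = preprocess_bold(sess.bold, cfg.region_names(), tr_s=cfg.tr_s)
        X, scans = build_features(bp, n_lags=n_lags)
        targets = {}
        for region in cfg.region_names():
            y_class, y_reg = build_targets(rts, region)
            targets[region] = (y_class[scans - 1], y_reg[scans - 1])
        prepared[(subject, condition)] = {"X": X, "scans": scans,
                                          "targets": targets}
    return prepared


def _as_supervised(prep: dict, region: str, subject: int, condition: str) -> SupervisedSet:
    y_class, y_reg = prep["targets"][region]
    index = pd.DataFrame({"subject": subject, "condition": condition,
                          "region": region, "scan": prep["scans"]})
    return SupervisedSet(prep["X"], y_class, y_reg, index)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full pipeline: generate → preprocess → rotate conditions →
    fit/predict per subject-region-model → metrics → statistics → per-ROI
    aggregation. Deterministic given the config seeds."""
    study = generate_study(config.synthetic)
    cfg = config.synthetic
    prepared = _prepare_sessions(study, config.n_lags)
    rows: list[dict] = []
    exclusions: list[dict] = []
    reg_predictions: dict[str, list[np.ndarray]] = {}
    reg_truths: dict[str, list[np.ndarray]] = {}

    for spec in config.model_specs:
        name = _model_name(spec)
        needs_val = spec.family in _models.NEURAL_FAMILIES
        plan = make_cv_plan(cfg.conditions, needs_validation=needs_val)
        grid = config.tune_grids.get(spec.family)
        for it_idx, iteration in enumerate(plan.iterations):
            for subject in range(cfg.n_subjects):
                train_prep = prepared[(subject, iteration.train_condition)]
                test_prep = prepared[(subject, iteration.test_condition)]
                third_prep = prepared[(subject, iteration.third_condition)]
                for region in cfg.region_names():
                    train = _as_supervised(train_prep, region, subject,
                                           iteration.train_condition)
                    test = _as_supervised(test_prep, region, subject,
                                          iteration.test_condition)
                    third = _as_supervised(third_prep, region, subject,
                                           iteration.third_condition)
                    try:
                        use_spec = spec
                        if grid:
                            use_spec = _models.tune(spec, grid, train, third)
                        fitted = _models.fit(use_spec, train,
                                             third if needs_val else None)
                        pred = _models.predict(fitted, test.X)
                    except ValueError as err:
                        exclusions.append({"model": name, "subject": subject,
                                           "region": region,
                                           "iteration": it_idx,
                                           "reason": str(err)})
                        continue
                    if spec.task == "classification":
                        truth = test.y_class
                        metric = float(np.mean(pred == truth))
                        baseline = float(np.mean(truth == LABEL_INCREASE))
                    else:
                        truth = test.y_reg
                        metric = float(np.mean(np.abs(pred - truth)))
                        baseline = float(np.mean(np.abs(truth)))
                        reg_predictions.setdefault(name, []).append(pred)
                        reg_truths.setdefault(name, []).append(truth)
                    rows.append({"model": name, "task": spec.task,
                                 "subject": subject, "region": region,
                                 "iteration": it_idx, "metric": metric,
                                 "baseline_metric": baseline,
                                 "n_samples": test.n_samples})

    pair_table = pd.DataFrame(rows)
    per_model: dict[str, ModelStats] = {}
    for name, group in pair_table.groupby("model", sort=False):
        task = group["task"].iloc[0]
        direction = "greater" if task == "classification" else "less"
        result = wilcoxon_one_sided(group["metric"].to_numpy(),
                                    group["baseline_metric"].to_numpy(),
                                    direction)
        pearson = None
        if task == "regression":
            preds = np.concatenate(reg_predictions[name])
            truths = np.concatenate(reg_truths[name])
            pearson = float(_stats.pearsonr(preds, truths)[0]) \
                if np.std(preds) > 0 and np.std(truths) > 0 else 0.0
        per_model[name] = ModelStats(
            model=name, task=task,
            mean_metric=float(group["metric"].mean()),
            sem_metric=float(group["metric"].std(ddof=1) / np.sqrt(len(group))),
            mean_baseline=float(group["baseline_metric"].mean()),
            p_value=result.p_value, rbc=result.rbc, cles=result.cles,
            pearson_r=pearson, n_pairs=len(group))

    names = list(per_model)
    pairwise = pd.DataFrame(np.nan, index=names, columns=names)
    for row_name in names:
        for col_name in names:
            if row_name == col_name:
                continue
            a = pair_table[pair_table["model"] == row_name]
            b = pair_table[pair_table["model"] == col_name]
            if per_model[row_name].task != per_model[col_name].task:
                continue
            merged = a.merge(b, on=["subject", "region", "iteration"],
                             suffixes=("_a", "_b"))
            direction = ("greater" if per_model[row_name].task == "classification"
                         else "less")
            try:
                pairwise.loc[row_name, col_name] = wilcoxon_one_sided(
                    merged["metric_a"].to_numpy(),
                    merged["metric_b"].to_numpy(), direction).p_value
            except ValueError:
                pass

    roi_rows = []
    for name, group in pair_table.groupby("model", sort=False):
        task = group["task"].iloc[0]
        direction = "greater" if task == "classification" else "less"
        for region, sub in group.groupby("region"):
            try:
                p = wilcoxon_one_sided(sub["metric"].to_numpy(),
                                       sub["baseline_metric"].to_numpy(),
                                       direction).p_value
            except ValueError:
                p = np.nan
            roi_rows.append({"model": name, "region": region,
                             "mean_metric": float(sub["metric"].mean()),
                             "p_value": p, "n_pairs": len(sub)})
    per_roi = pd.DataFrame(roi_rows)
    if len(per_roi):
        per_roi["q_value_bh"] = np.nan  # artifact extra, per model
        for name in per_roi["model"].unique():
            mask = (per_roi["model"] == name) & per_roi["p_value"].notna()
            if mask.any():
                per_roi.loc[mask, "q_value_bh"] = benjamini_hochberg(
                    per_roi.loc[mask, "p_value"].to_numpy())

    report = StatReport(per_model, pairwise, per_roi)
    return ExperimentResult(pair_table, report, exclusions, study)
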