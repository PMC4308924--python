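"""Cross-validated performance: stratified splits, ROC and prior-adjusted PPV.

Goodness of fit is assessed by repeatedly (default 100 times) splitting
the labelled variants into training and test sets, with each test set
holding 1/10 of the pathogenic and 1/10 of the benign variants, refitting
the model on each training set and pooling the test-set predictions.
ROC curves and threshold metrics are computed on the pooled predictions,
overall and per gene / variant class.

The positive predictive value is adjusted to the intended referral
population through the gene-level prior odds rather than the test-set
class ratio:

    PPV = (prior odds x TPR) / (prior odds x TPR + FPR)

with TPR the sensitivity and FPR = 1 - specificity at the chosen
probability threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from cardiobayes.annotations import VariantRecord
from cardiobayes.inference import fit, summarise
from cardiobayes.model_network import ModelConfig, build_model, training_domains_of
from cardiobayes.prediction import predict

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class SplitPlan:
    """Stratified random re-splits: disjoint, covering (train, test) pairs."""

    splits: list[tuple[np.ndarray, np.ndarray]]
    test_fraction: float
    seed: int

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)


def make_splits(
    labels: list[str],
    n_splits: int = 100,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> SplitPlan:
    """Independent stratified re-splits with floor-rule test sizes.

    Each test set holds ``floor(test_fraction * n_pathogenic)`` pathogenic
    and ``floor(test_fraction * n_benign)`` benign variants, sampled
    without replacement independently for every split.
    """
    labels = list(labels)
    idx_path = np.array([i for i, l in enumerate(labels) if l == "pathogenic"])
    idx_ben = np.array([i for i, l in enumerate(labels) if l == "benign"])
    if len(idx_path) == 0 or len(idx_ben) == 0:
        raise EvaluationError("both pathogenic and benign labels are required")
    n_test_path = int(np.floor(test_fraction * len(idx_path)))
    n_test_ben = int(np.floor(test_fraction * len(idx_ben)))
    if n_test_path < 1 or n_test_ben < 1:
        raise EvaluationError(
            "a class is too small for the requested test fraction "
            f"(pathogenic={len(idx_path)}, benign={len(idx_ben)}, "
            f"fraction={test_fraction})"
        )
    rng = np.random.default_rng(seed)
    all_idx = np.arange(len(labels))
    splits = []
    for _ in range(n_splits):
        test = np.concatenate(
            [
                rng.choice(idx_path, size=n_test_path, replace=False),
                rng.choice(idx_ben, size=n_test_ben, replace=False),
            ]
        )
        test.sort()
        train = np.setdiff1d(all_idx, test)
        splits.append((train, test))
    return SplitPlan(splits=splits, test_fraction=test_fraction, seed=seed)


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    area: float


def roc(scores: list[tuple[float, str]]) -> ROCResult:
    """Threshold-sweep ROC with ties grouped; area by the trapezoid rule."""
    if not scores:
        raise EvaluationError("no scores supplied")
    probs = np.array([s for s, _ in scores], dtype=float)
    y = np.array([1 if l == "pathogenic" else 0 for _, l in scores])
    if len(set(y)) < 2:
        raise EvaluationError("ROC requires both pathogenic and benign examples")
    fpr, tpr, thr = _sk_roc_curve(y, probs)
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, area=float(_trapezoid_auc(fpr, tpr)))


def ppv_adjusted(prior_odds: float, tpr: float, fpr: float) -> float:
    """Prior-adjusted positive predictive value."""
    if prior_odds <= 0:
        raise EvaluationError("prior_odds must be positive")
    if not 0.0 <= tpr <= 1.0 or not 0.0 <= fpr <= 1.0:
        raise EvaluationError("tpr and fpr must lie in [0, 1]")
    denom = prior_odds * tpr + fpr
    if denom == 0.0:
        raise EvaluationError("prior_odds * tpr + fpr must be positive")
    return prior_odds * tpr / denom


@dataclass
class PerformanceReport:
    """Pooled cross-validation predictions with ROC and threshold metrics.

    ``predictions`` has one row per pooled test prediction (split,
    variant_id, gene, syndrome, variant_class, probability, label).
    ``metrics`` has one row per (stratum, threshold) with sensitivity,
    specificity, FPR and prior-adjusted PPV; ``auc`` maps stratum to ROC
    area (NaN where a stratum is single-class).
    """

    predictions: pd.DataFrame
    metrics: pd.DataFrame
    auc: dict[str, float]
    roc_points: dict[str, ROCResult] = field(default_factory=dict)


def _threshold_metrics(sub: pd.DataFrame, threshold: float, prior_odds: float | None):
    y = (sub["label"] == "pathogenic").to_numpy()
    pos = (sub["probability"].to_numpy() >= threshold)
    tp = int((pos & y).sum())
    fn = int((~pos & y).sum())
    fp = int((pos & ~y).sum())
    tn = int((~pos & ~y).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    fpr = 1.0 - spec if spec == spec else np.nan
    if prior_odds is not None and sens == sens and fpr == fpr and prior_odds * sens + fpr > 0:
        ppv = ppv_adjusted(prior_odds, sens, fpr)
    else:
        ppv = np.nan
    return sens, spec, fpr, ppv


def evaluate_cv(
    config: ModelConfig,
    variants: list[VariantRecord],
    priors,
    splits: SplitPlan,
    thresholds: tuple[float, ...] = (0.9,),
    prior_odds_by_syndrome: dict[str, float] | None = None,
    n_chains: int = 2,
    n_iter: int = 2_000,
    burn_fraction: float = 0.2,
    seed: int = 0,
) -> PerformanceReport:
    """Refit on every training split, pool test predictions, report metrics.

    PPV at each threshold uses the syndrome-level prior odds supplied in
    ``prior_odds_by_syndrome`` (an explicit modelling input, not the
    test-set class ratio); strata without a supplied prior get NaN PPV.
    """
    rows = []
    for split_no, (train_idx, test_idx) in enumerate(splits):
        train = [variants[i] for i in train_idx]
        test = [variants[i] for i in test_idx]
        try:
            graph = build_model(config, priors, training_domains_of(train))
            chains = fit(
                graph,
                train,
                n_chains=n_chains,
                n_iter=n_iter,
                burn_fraction=burn_fraction,
                seed=seed + split_no,
            )
            summary = summarise(chains)
        except Exception as exc:  # pragma: no cover - propagate with context
            raise EvaluationError(f"model fit failed on split {split_no}: {exc}") from exc
        for v in test:
            pred = predict(v, summary, priors, graph)
            rows.append(
                {
                    "split": split_no,
                    "variant_id": v.variant_id,
                    "gene": v.gene,
                    "syndrome": v.syndrome,
                    "variant_class": v.variant_class,
                    "probability": pred.probability,
                    "label": v.label,
                }
            )
    predictions = pd.DataFrame(rows).sort_values(
        ["split", "variant_id"], kind="stable"
    ).reset_index(drop=True)

    strata: dict[str, pd.DataFrame] = {"combined": predictions}
    for gene, sub in predictions.groupby("gene"):
        strata[f"gene:{gene}"] = sub
    for cls, sub in predictions.groupby("variant_class"):
        strata[f"class:{cls}"] = sub

    auc_by_stratum: dict[str, float] = {}
    roc_points: dict[str, ROCResult] = {}
    metric_rows = []
    prior_odds_by_syndrome = prior_odds_by_syndrome or {}
    for name, sub in strata.items():
        pairs = list(zip(sub["probability"], sub["label"]))
        try:
            r = roc(pairs)
            auc_by_stratum[name] = r.area
            roc_points[name] = r
        except EvaluationError:
            auc_by_stratum[name] = float("nan")
        syndromes = sub["syndrome"].unique()
        odds = (
            prior_odds_by_syndrome.get(syndromes[0]) if len(syndromes) == 1 else None
        )
        if odds is None and len(syndromes) > 1:
            logger.debug("stratum %s spans syndromes; PPV left NaN", name)
        for threshold in thresholds:
            sens, spec, fpr, ppv = _threshold_metrics(sub, threshold, odds)
            metric_rows.append(
                {
                    "stratum": name,
                    "threshold": threshold,
                    "sensitivity": sens,
                    "specificity": spec,
                    "fpr": fpr,
                    "ppv": ppv,
                    "n": len(sub),
                }
            )
    metrics = pd.DataFrame(metric_rows)
    return PerformanceReport(
        predictions=predictions, metrics=metrics, auc=auc_by_stratum, roc_points=roc_points
    )
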