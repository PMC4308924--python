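"""Scoring novel variants: P(pathogenic), segregation evidence, banding.

A fitted model scores a variant by plugging the posterior parameter
medians into its class-specific linear predictor; the probability of
pathogenicity is the logistic transform of that logit.  Independent
familial segregation evidence, quantified as a LOD score (log10
likelihood ratio from linkage), multiplies the posterior odds:

    posterior odds' = posterior odds x 10^LOD

Probabilities may optionally be partitioned into reporting bands; the
default cut points (0.1, 0.9) give likely-benign / uncertain / pathogenic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from cardiobayes.annotations import VariantRecord, build_design_vector
from cardiobayes.inference import PosteriorSummary
from cardiobayes.model_network import ParameterGraph, linear_predictor

DEFAULT_BANDS = ((0.1, "likely_benign"), (0.9, "uncertain"), (None, "pathogenic"))
DEFAULT_THRESHOLDS = (0.1, 0.9)
DEFAULT_BAND_LABELS = ("likely_benign", "uncertain", "pathogenic")


@dataclass
class Prediction:
    """A scored variant; ``probability = logistic(logit)`` exactly."""

    variant_id: str
    gene: str
    syndrome: str
    variant_class: str
    logit: float
    probability: float
    band_label: str | None = None
    lod_applied: float = 0.0


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def predict(
    variant: VariantRecord,
    summary: PosteriorSummary,
    priors,
    graph: ParameterGraph,
    average_draws=None,
) -> Prediction:
    """Plug-in probability of pathogenicity at the posterior medians.

    ``average_draws`` may be a :class:`~cardiobayes.inference.ChainSet`;
    then the probability is instead averaged over posterior draws (the
    full posterior-predictive alternative to the plug-in rule) and the
    logit is the logit of that averaged probability.
    """
    design = build_design_vector(variant, priors)
    params = graph.parameter_set(summary.values(), variant.syndrome)
    eta = linear_predictor(params, design)
    if average_draws is not None:
        row = graph.design_row(design)
        import numpy as np

        mat = np.stack(
            [average_draws.pooled(name) for name in graph.param_names], axis=1
        )
        etas = mat @ row
        prob = float((1.0 / (1.0 + np.exp(-etas))).mean())
        eta = math.log(prob / (1.0 - prob)) if 0.0 < prob < 1.0 else math.inf * (1 if prob else -1)
    else:
        prob = _logistic(eta)
    return Prediction(
        variant_id=variant.variant_id,
        gene=variant.gene,
        syndrome=variant.syndrome,
        variant_class=variant.variant_class,
        logit=eta,
        probability=prob,
    )


def predict_with_params(variant: VariantRecord, params, priors) -> Prediction:
    """Score a variant directly from a :class:`ParameterSet` (CLI path)."""
    design = build_design_vector(variant, priors)
    eta = linear_predictor(params, design)
    return Prediction(
        variant_id=variant.variant_id,
        gene=variant.gene,
        syndrome=variant.syndrome,
        variant_class=variant.variant_class,
        logit=eta,
        probability=_logistic(eta),
    )


def parameter_set_from_summary(
    summary: PosteriorSummary, syndrome: str, no_domain_genes=None
):
    """Rebuild one syndrome's ParameterSet from a persisted median table.

    Understands plain role names, syndrome-suffixed names from joint fits
    (``beta_freq[LQTS]``) and domain-effect names ``delta[gene:domain]`` /
    ``delta[syndrome:gene:domain]``.
    """
    from cardiobayes.model_network import (
        DEFAULT_NO_DOMAIN_GENES,
        ParameterSet,
        SCALAR_ROLES,
    )

    values = summary.values()
    kwargs: dict[str, float] = {}
    for role in SCALAR_ROLES:
        if f"{role}[{syndrome}]" in values:
            kwargs[role] = values[f"{role}[{syndrome}]"]
        elif role in values:
            kwargs[role] = values[role]
    deltas: dict[tuple[str, str], float] = {}
    for name, value in values.items():
        if not (name.startswith("delta[") and name.endswith("]")):
            continue
        parts = name[len("delta["):-1].split(":")
        if len(parts) == 2:
            deltas[(parts[0], parts[1])] = value
        elif len(parts) == 3 and parts[0] == syndrome:
            deltas[(parts[1], parts[2])] = value
    return ParameterSet(
        **kwargs,
        domain_effects=deltas,
        sigma2_dom=values.get("sigma2_dom", 1.0),
        no_domain_genes=(
            DEFAULT_NO_DOMAIN_GENES if no_domain_genes is None else no_domain_genes
        ),
    )


def combine_segregation(pred: Prediction, lod: float) -> Prediction:
    """Multiply the posterior odds by the segregation likelihood ratio 10^LOD."""
    if not math.isfinite(lod):
        raise ValueError("LOD score must be finite")
    new_logit = pred.logit + lod * math.log(10.0)
    return replace(
        pred,
        logit=new_logit,
        probability=_logistic(new_logit),
        lod_applied=pred.lod_applied + lod,
    )


def band(
    pred: Prediction,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    labels: tuple[str, ...] = DEFAULT_BAND_LABELS,
) -> str:
    """Assign a reporting band from ordered probability cut points.

    Bands are half-open ``[lo, hi)``: a probability equal to a threshold
    falls in the upper band.
    """
    if len(labels) != len(thresholds) + 1:
        raise ValueError("need exactly one more label than thresholds")
    if any(not 0.0 < t < 1.0 for t in thresholds) or list(thresholds) != sorted(
        set(thresholds)
    ):
        raise ValueError("thresholds must be strictly increasing and inside (0, 1)")
    for t, label in zip(thresholds, labels):
        if pred.probability < t:
            return label
    return labels[-1]
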