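"""The network of interrelated logistic regressions and its parameter graph.

One syndrome contributes three linear predictors on the logit scale, one
per variant class, with extensive parameter sharing:

* radical:   ``alpha_rad + lambda_rad * log(prior_odds_radical) + beta_freq * f``
* inframe:   ``alpha_nr + alpha_if + lambda_nr * log(prior_odds_nonrad)
  + delta_D + beta_freq * f``
* missense:  ``alpha_nr + lambda_nr * log(prior_odds_nonrad) + delta_D
  + beta_freq * f + beta_sift * (1-SIFT) + beta_poly1 * p + beta_poly2 * p^2
  + beta_gran1 * g + beta_gran2 * g^2 + beta_cons_prim * c1 + beta_cons_all * c2``

Gene effects enter as a fitted scale parameter times the log prior odds
for the variant's class group.  Domain effects ``delta_D`` are zero-mean
normal random effects whose variance carries an inverse-gamma hyperprior;
genes whose domains are too sparsely represented in training data carry
no domain term.  All other coefficients and intercepts have N(0, 10)
priors (variance 10 by default, configurable).

Joint multi-syndrome fits tie parameters across syndromes:

* LQTS + BrS ties the domain variance, the gene-prior scales, all class
  intercepts and every predictor coefficient; only the gene/domain random
  effects stay syndrome-specific.
* LQTS + HCM ties only the domain variance and the score coefficients
  (SIFT, PolyPhen, Grantham, conservation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from cardiobayes.annotations import DesignVector, VariantRecord, build_design_vector

logger = logging.getLogger(__name__)

_warned_domains: set[tuple[str, str]] = set()


def _warn_novel_domain(gene: str, domain: str) -> None:
    # novel domains are routine during cross-validation; warn once per pair
    key = (gene, domain)
    if key not in _warned_domains:
        _warned_domains.add(key)
        logger.warning("novel domain %s in gene %s: using delta = 0", domain, gene)

#: Genes whose protein domains are too sparsely covered by training data
#: to support a domain random effect.
DEFAULT_NO_DOMAIN_GENES = frozenset(
    {
        "KCNJ2",
        "CAV3",
        "SCN4B",
        "AKAP9",
        "SNTA1",
        "KCNJ5",
        "CACNA2D1",
        "CACNB2",
        "GPD1L",
        "SCN1B",
        "MYBPC3",
        "TNNT2",
    }
)

#: Scalar (non-random-effect) roles in canonical order.
SCALAR_ROLES = (
    "alpha_rad",
    "alpha_nr",
    "alpha_if",
    "lambda_nr",
    "lambda_rad",
    "beta_freq",
    "beta_sift",
    "beta_poly1",
    "beta_poly2",
    "beta_gran1",
    "beta_gran2",
    "beta_cons_prim",
    "beta_cons_all",
)

_SCORE_ROLES = (
    "beta_sift",
    "beta_poly1",
    "beta_poly2",
    "beta_gran1",
    "beta_gran2",
    "beta_cons_prim",
    "beta_cons_all",
)

ABLATIONS = (
    "full",
    "low_res_domain",
    "gene_only",
    "genome_wide",
    "prior_sift",
    "prior_only",
    "sift_only",
)

_ABLATION_ALIASES = {"gene": "gene_only", "prior_plus_sift": "prior_sift"}

#: Scalar roles present under each ablation.
_ABLATION_ROLES: dict[str, tuple[str, ...]] = {
    "full": SCALAR_ROLES,
    "low_res_domain": SCALAR_ROLES,
    "gene_only": SCALAR_ROLES,
    "genome_wide": tuple(r for r in SCALAR_ROLES if not r.startswith("lambda")),
    "prior_sift": ("alpha_rad", "alpha_nr", "alpha_if", "lambda_nr", "lambda_rad", "beta_sift"),
    "prior_only": ("alpha_rad", "alpha_nr", "alpha_if", "lambda_nr", "lambda_rad"),
    "sift_only": ("alpha_rad", "alpha_nr", "alpha_if", "beta_sift"),
}

_DOMAIN_ABLATIONS = ("full", "low_res_domain")

JOIN_PLANS = ("none", "lqts_brs", "lqts_hcm")

#: Roles tied across syndromes under each joint-fitting plan.
_TIED_ROLES = {
    "lqts_brs": set(SCALAR_ROLES),
    "lqts_hcm": set(_SCORE_ROLES),
}


class ModelConfigError(ValueError):
    pass


@dataclass
class Hyperparameters:
    """Hyperpriors: N(0, variance) coefficients, inverse-gamma domain variance.

    The coefficient prior is read as mean 0, *variance* 10.  The
    inverse-gamma shape/rate for the domain-effect variance are weakly
    informative defaults (mode near typical logit effect sizes) and are
    configurable.
    """

    coeff_prior_mean: float = 0.0
    coeff_prior_variance: float = 10.0
    domain_variance_shape: float = 2.0
    domain_variance_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.coeff_prior_variance <= 0:
            raise ModelConfigError("coefficient prior variance must be positive")
        if self.domain_variance_shape <= 0 or self.domain_variance_rate <= 0:
            raise ModelConfigError("inverse-gamma shape and rate must be positive")


@dataclass
class ModelConfig:
    """Which syndromes are fitted, what is shared, and which ablation applies."""

    syndromes: tuple[str, ...] = ("LQTS",)
    ablation: str = "full"
    join: str = "none"
    domain_merge_map: dict[str, str] | None = None
    no_domain_genes: frozenset[str] = DEFAULT_NO_DOMAIN_GENES
    hyper: Hyperparameters = field(default_factory=Hyperparameters)

    def __post_init__(self) -> None:
        self.ablation = _ABLATION_ALIASES.get(self.ablation, self.ablation)
        if self.ablation not in ABLATIONS:
            raise ModelConfigError(
                f"unknown ablation {self.ablation!r}; expected one of {ABLATIONS}"
            )
        if self.join not in JOIN_PLANS:
            raise ModelConfigError(f"unknown join plan {self.join!r}")
        self.syndromes = tuple(self.syndromes)
        if self.join == "lqts_brs" and set(self.syndromes) != {"LQTS", "BrS"}:
            raise ModelConfigError("join plan lqts_brs requires syndromes LQTS and BrS")
        if self.join == "lqts_hcm" and set(self.syndromes) != {"LQTS", "HCM"}:
            raise ModelConfigError("join plan lqts_hcm requires syndromes LQTS and HCM")
        if self.ablation == "low_res_domain" and self.domain_merge_map is None:
            raise ModelConfigError("low_res_domain ablation requires a domain merge map")

    @property
    def scalar_roles(self) -> tuple[str, ...]:
        return _ABLATION_ROLES[self.ablation]

    @property
    def has_domains(self) -> bool:
        return self.ablation in _DOMAIN_ABLATIONS


@dataclass
class ParameterSet:
    """Concrete parameter values for one syndrome's three predictors."""

    alpha_rad: float = 0.0
    alpha_nr: float = 0.0
    alpha_if: float = 0.0
    lambda_nr: float = 0.0
    lambda_rad: float = 0.0
    beta_freq: float = 0.0
    beta_sift: float = 0.0
    beta_poly1: float = 0.0
    beta_poly2: float = 0.0
    beta_gran1: float = 0.0
    beta_gran2: float = 0.0
    beta_cons_prim: float = 0.0
    beta_cons_all: float = 0.0
    domain_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    sigma2_dom: float = 1.0
    no_domain_genes: frozenset[str] = DEFAULT_NO_DOMAIN_GENES

    def domain_effect(self, gene: str, domain: str | None) -> float:
        """delta for a (gene, domain); 0 for no-domain genes and novel domains."""
        if gene in self.no_domain_genes or domain is None:
            return 0.0
        key = (gene, domain)
        if key not in self.domain_effects:
            _warn_novel_domain(gene, domain)
            return 0.0
        return self.domain_effects[key]


def linear_predictor(params: ParameterSet, design: DesignVector) -> float:
    """Evaluate the class-specific linear predictor on the logit scale."""
    f = design.freq_indicator
    if design.variant_class == "radical":
        eta = params.alpha_rad + params.lambda_rad * design.log_prior_odds + params.beta_freq * f
    elif design.variant_class == "inframe":
        eta = (
            params.alpha_nr
            + params.alpha_if
            + params.lambda_nr * design.log_prior_odds
            + params.domain_effect(design.gene, design.domain)
            + params.beta_freq * f
        )
    else:
        eta = (
            params.alpha_nr
            + params.lambda_nr * design.log_prior_odds
            + params.domain_effect(design.gene, design.domain)
            + params.beta_freq * f
            + params.beta_sift * design.sift_t
            + params.beta_poly1 * design.polyphen
            + params.beta_poly2 * design.polyphen_sq
            + params.beta_gran1 * design.grantham_t
            + params.beta_gran2 * design.grantham_t_sq
            + params.beta_cons_prim * design.cons_primates
            + params.beta_cons_all * design.cons_all
        )
    if not math.isfinite(eta):
        raise ValueError("non-finite linear predictor")
    return eta


def _covariate(role: str, design: DesignVector) -> float:
    """Value multiplying the parameter with the given role for this design."""
    cls = design.variant_class
    if role == "alpha_rad":
        return 1.0 if cls == "radical" else 0.0
    if role == "alpha_nr":
        return 1.0 if cls in ("inframe", "missense") else 0.0
    if role == "alpha_if":
        return 1.0 if cls == "inframe" else 0.0
    if role == "lambda_rad":
        return design.log_prior_odds if cls == "radical" else 0.0
    if role == "lambda_nr":
        return design.log_prior_odds if cls != "radical" else 0.0
    if role == "beta_freq":
        return float(design.freq_indicator)
    if cls != "missense":
        return 0.0
    return {
        "beta_sift": design.sift_t,
        "beta_poly1": design.polyphen,
        "beta_poly2": design.polyphen_sq,
        "beta_gran1": design.grantham_t,
        "beta_gran2": design.grantham_t_sq,
        "beta_cons_prim": float(design.cons_primates),
        "beta_cons_all": float(design.cons_all),
    }[role]


@dataclass
class ParameterGraph:
    """Free parameters of a (possibly joint) fit, their priors and tying.

    ``param_names`` lists every sampled scalar (coefficients, intercepts,
    scales and domain effects); tied parameters appear once.  ``prior_var``
    gives the N(0, v) prior variance of each non-hierarchical parameter;
    domain effects instead belong to ``sigma_groups`` and share the
    inverse-gamma-distributed variance ``sigma2_dom``.
    """

    config: ModelConfig
    priors: object  # PriorOddsTable
    param_names: list[str]
    prior_var: dict[str, float]
    role_map: dict[tuple[str, str], str]  # (syndrome, role) -> param name
    delta_map: dict[tuple[str, str, str], str]  # (syndrome, gene, domain) -> name
    sigma_groups: dict[str, list[str]]  # sigma2 name -> delta names
    _index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self._index = {name: i for i, name in enumerate(self.param_names)}

    # -- structure ---------------------------------------------------------

    @property
    def n_params(self) -> int:
        return len(self.param_names) + len(self.sigma_groups)

    def index(self, name: str) -> int:
        return self._index[name]

    def _merged_domain(self, domain: str | None) -> str | None:
        if domain is None:
            return None
        merge = self.config.domain_merge_map
        if merge is None:
            return domain
        if domain not in merge:
            raise ModelConfigError(f"domain merge map is missing domain {domain!r}")
        return merge[domain]

    # -- encoding ----------------------------------------------------------

    def design_row(self, design: DesignVector) -> np.ndarray:
        """Sparse-by-construction covariate row over ``param_names``."""
        row = np.zeros(len(self.param_names))
        syndrome = design.syndrome
        if syndrome not in self.config.syndromes:
            raise ModelConfigError(
                f"variant syndrome {syndrome!r} not covered by this model "
                f"({self.config.syndromes})"
            )
        for role in self.config.scalar_roles:
            value = _covariate(role, design)
            if value != 0.0:
                row[self._index[self.role_map[(syndrome, role)]]] = value
        if (
            self.config.has_domains
            and design.variant_class in ("inframe", "missense")
            and design.gene not in self.config.no_domain_genes
            and design.domain is not None
        ):
            key = (syndrome, design.gene, self._merged_domain(design.domain))
            name = self.delta_map.get(key)
            if name is None:
                _warn_novel_domain(design.gene, design.domain)
            else:
                row[self._index[name]] = 1.0
        return row

    def encode(
        self, variants: list[VariantRecord], require_labels: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Design matrix over free parameters and (optionally) label vector."""
        rows, ys = [], []
        for v in variants:
            design = build_design_vector(v, self.priors)
            rows.append(self.design_row(design))
            if require_labels:
                if v.label is None:
                    raise ModelConfigError(f"{v.variant_id}: training variant lacks a label")
                ys.append(1.0 if v.label == "pathogenic" else 0.0)
        X = np.array(rows) if rows else np.zeros((0, len(self.param_names)))
        y = np.array(ys) if require_labels else np.zeros(0)
        return X, y

    # -- conversion --------------------------------------------------------

    def parameter_set(self, values: dict[str, float], syndrome: str) -> ParameterSet:
        """Materialise one syndrome's :class:`ParameterSet` from fitted values.

        Roles absent under the ablation contribute zero.
        """
        kwargs: dict[str, float] = {}
        for role in SCALAR_ROLES:
            name = self.role_map.get((syndrome, role))
            kwargs[role] = values.get(name, 0.0) if name else 0.0
        deltas = {
            (gene, domain): values[name]
            for (syn, gene, domain), name in self.delta_map.items()
            if syn == syndrome and name in values
        }
        sigma2 = values.get("sigma2_dom", 1.0)
        return ParameterSet(
            **kwargs,
            domain_effects=deltas,
            sigma2_dom=sigma2,
            no_domain_genes=self.config.no_domain_genes,
        )


def build_model(
    config: ModelConfig,
    priors,
    training_domains: list[tuple[str, str, str]],
) -> ParameterGraph:
    """Construct the parameter graph for a configuration.

    ``training_domains`` lists the (syndrome, gene, domain) triples present
    in the training data; one domain effect is created per triple for
    domain-bearing genes (after any merge map).  Under joint plans, tied
    parameters are created once and shared; untied parameters are suffixed
    with their syndrome.
    """
    tied = _TIED_ROLES.get(config.join, set())
    joint = len(config.syndromes) > 1

    names: list[str] = []
    prior_var: dict[str, float] = {}
    role_map: dict[tuple[str, str], str] = {}
    v = config.hyper.coeff_prior_variance
    for role in config.scalar_roles:
        if joint and role not in tied:
            for syndrome in config.syndromes:
                name = f"{role}[{syndrome}]"
                names.append(name)
                prior_var[name] = v
                role_map[(syndrome, role)] = name
        else:
            names.append(role)
            prior_var[role] = v
            for syndrome in config.syndromes:
                role_map[(syndrome, role)] = role

    delta_map: dict[tuple[str, str, str], str] = {}
    sigma_groups: dict[str, list[str]] = {}
    if config.has_domains:
        deltas: list[str] = []
        seen: set[tuple[str, str, str]] = set()
        for syndrome, gene, domain in training_domains:
            if syndrome not in config.syndromes or gene in config.no_domain_genes:
                continue
            if domain is None:
                continue
            if config.domain_merge_map is not None:
                if domain not in config.domain_merge_map:
                    raise ModelConfigError(
                        f"domain merge map is missing training domain {domain!r}"
                    )
                domain = config.domain_merge_map[domain]
            key = (syndrome, gene, domain)
            if key in seen:
                continue
            seen.add(key)
            name = (
                f"delta[{gene}:{domain}]"
                if not joint
                else f"delta[{syndrome}:{gene}:{domain}]"
            )
            names.append(name)
            deltas.append(name)
            delta_map[key] = name
        if deltas:
            # one shared domain variance, also across joint syndromes
            sigma_groups["sigma2_dom"] = deltas

    return ParameterGraph(
        config=config,
        priors=priors,
        param_names=names,
        prior_var=prior_var,
        role_map=role_map,
        delta_map=delta_map,
        sigma_groups=sigma_groups,
    )


def training_domains_of(variants: list[VariantRecord]) -> list[tuple[str, str, str]]:
    """The (syndrome, gene, domain) triples annotated in a training set."""
    out = []
    seen = set()
    for v in variants:
        if v.variant_class in ("inframe", "missense") and v.domain is not None:
            key = (v.syndrome, v.gene, v.domain)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out
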