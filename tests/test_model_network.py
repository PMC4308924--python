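"""Linear predictors, parameter sharing and ablations."""

import math

import numpy as np
import pytest

from cardiobayes.annotations import DesignVector, VariantRecord, build_design_vector
from cardiobayes.model_network import (
    ModelConfig,
    ModelConfigError,
    ParameterSet,
    SCALAR_ROLES,
    build_model,
    linear_predictor,
    training_domains_of,
)
from cardiobayes.priors import PriorOddsEntry, PriorOddsTable
from cardiobayes.synthetic import GeneratorSpec, generate_from_model


def _design(**overrides):
    base = dict(
        variant_class="missense",
        gene="GENE1",
        syndrome="LQTS",
        freq_indicator=0,
        log_prior_odds=0.0,
        domain="TM",
        sift_t=0.0,
        grantham_t=0.0,
        grantham_t_sq=0.0,
        polyphen=0.0,
        polyphen_sq=0.0,
        cons_primates=0,
        cons_all=0,
    )
    base.update(overrides)
    return DesignVector(**base)


class TestLinearPredictor:
    def test_zero_parameters_give_zero(self):
        params = ParameterSet(no_domain_genes=frozenset())
        assert linear_predictor(params, _design()) == 0.0

    def test_radical_identity_arithmetic(self):
        params = ParameterSet(alpha_rad=1.0, lambda_rad=1.0, no_domain_genes=frozenset())
        d = _design(
            variant_class="radical", log_prior_odds=1.0, domain=None,
            sift_t=None, grantham_t=None, grantham_t_sq=None,
            polyphen=None, polyphen_sq=None, cons_primates=None, cons_all=None,
        )
        assert linear_predictor(params, d) == pytest.approx(2.0)

    def test_missense_unit_coefficient_sum(self):
        params = ParameterSet(
            beta_sift=1, beta_poly1=1, beta_poly2=1, beta_gran1=1, beta_gran2=1,
            beta_cons_prim=1, beta_cons_all=1, no_domain_genes=frozenset(),
        )
        d = _design(
            sift_t=1.0, polyphen=1.0, polyphen_sq=1.0, grantham_t=1.0,
            grantham_t_sq=1.0, cons_primates=0, cons_all=1,
        )
        assert linear_predictor(params, d) == pytest.approx(6.0)

    def test_additivity_in_each_covariate(self):
        params = ParameterSet(
            alpha_nr=-1.2, lambda_nr=0.7, beta_freq=-2.0, beta_sift=3.0,
            beta_poly1=1.0, beta_poly2=1.5, beta_gran1=0.8, beta_gran2=0.4,
            beta_cons_prim=0.5, beta_cons_all=1.2,
            domain_effects={("GENE1", "TM"): 0.9}, no_domain_genes=frozenset(),
        )
        base = _design(sift_t=0.3)
        bumped = _design(sift_t=0.8)
        diff = linear_predictor(params, bumped) - linear_predictor(params, base)
        assert diff == pytest.approx(params.beta_sift * 0.5)

    def test_no_domain_gene_contributes_zero_delta(self):
        params = ParameterSet(
            domain_effects={("KCNJ2", "TM"): 5.0}, no_domain_genes=frozenset({"KCNJ2"})
        )
        d = _design(gene="KCNJ2")
        assert linear_predictor(params, d) == 0.0

    def test_novel_domain_contributes_zero_with_warning(self, caplog):
        params = ParameterSet(domain_effects={}, no_domain_genes=frozenset())
        with caplog.at_level("WARNING", logger="cardiobayes.model_network"):
            assert linear_predictor(params, _design(domain="unseen-dom")) == 0.0


def _toy_priors(syndromes=("LQTS",)):
    table = PriorOddsTable()
    for s in syndromes:
        for gene in ("GENE1", "GENE2"):
            table.add(PriorOddsEntry(gene, s, "non_radical", 10.0, "synthetic"))
            table.add(PriorOddsEntry(gene, s, "radical", 20.0, "synthetic"))
    return table


_DOMAINS = [("LQTS", "GENE1", "TM"), ("LQTS", "GENE1", "C-term"), ("LQTS", "GENE2", "TM")]


class TestBuildModel:
    def test_full_model_parameter_count_by_hand(self):
        graph = build_model(ModelConfig(syndromes=("LQTS",)), _toy_priors(), _DOMAINS)
        # 13 scalar roles + 3 domain effects sampled, + 1 variance hyperparameter
        assert len(graph.param_names) == 13 + 3
        assert graph.n_params == 13 + 3 + 1
        assert graph.sigma_groups["sigma2_dom"] == [
            n for n in graph.param_names if n.startswith("delta[")
        ]

    def test_no_domain_genes_get_no_delta(self):
        domains = _DOMAINS + [("LQTS", "KCNJ2", "Pore")]
        priors = _toy_priors()
        priors.add(PriorOddsEntry("KCNJ2", "LQTS", "non_radical", 1.0, "synthetic"))
        priors.add(PriorOddsEntry("KCNJ2", "LQTS", "radical", 0.2, "synthetic"))
        graph = build_model(ModelConfig(syndromes=("LQTS",)), priors, domains)
        assert not any("KCNJ2" in n for n in graph.param_names)

    def test_genome_wide_has_no_gene_or_domain_terms(self):
        graph = build_model(
            ModelConfig(syndromes=("LQTS",), ablation="genome_wide"), _toy_priors(), _DOMAINS
        )
        assert not any(n.startswith(("lambda", "delta")) for n in graph.param_names)
        assert "alpha_rad" in graph.param_names and "beta_sift" in graph.param_names

    def test_sift_only_parameters(self):
        graph = build_model(
            ModelConfig(syndromes=("LQTS",), ablation="sift_only"), _toy_priors(), _DOMAINS
        )
        assert set(graph.param_names) == {"alpha_rad", "alpha_nr", "alpha_if", "beta_sift"}

    def test_low_res_domain_merge_map_must_cover_training(self):
        cfg = ModelConfig(
            syndromes=("LQTS",),
            ablation="low_res_domain",
            domain_merge_map={"TM": "transmembrane"},  # C-term missing
        )
        with pytest.raises(ModelConfigError, match="C-term"):
            build_model(cfg, _toy_priors(), _DOMAINS)

    def test_merge_map_coarsens_domains(self):
        cfg = ModelConfig(
            syndromes=("LQTS",),
            ablation="low_res_domain",
            domain_merge_map={"TM": "body", "C-term": "body"},
        )
        graph = build_model(cfg, _toy_priors(), _DOMAINS)
        deltas = [n for n in graph.param_names if n.startswith("delta")]
        assert deltas == ["delta[GENE1:body]", "delta[GENE2:body]"]

    def test_lqts_brs_ties_everything_but_domains(self):
        domains = _DOMAINS + [("BrS", "GENE1", "TM")]
        cfg = ModelConfig(syndromes=("LQTS", "BrS"), join="lqts_brs")
        graph = build_model(cfg, _toy_priors(("LQTS", "BrS")), domains)
        for role in SCALAR_ROLES:
            assert graph.role_map[("LQTS", role)] == graph.role_map[("BrS", role)]
        assert "delta[LQTS:GENE1:TM]" in graph.param_names
        assert "delta[BrS:GENE1:TM]" in graph.param_names

    def test_lqts_hcm_ties_only_score_effects(self):
        cfg = ModelConfig(syndromes=("LQTS", "HCM"), join="lqts_hcm")
        graph = build_model(cfg, _toy_priors(("LQTS", "HCM")), _DOMAINS)
        assert graph.role_map[("LQTS", "beta_sift")] == graph.role_map[("HCM", "beta_sift")]
        for role in ("alpha_rad", "lambda_nr", "beta_freq"):
            assert graph.role_map[("LQTS", role)] != graph.role_map[("HCM", role)]

    def test_shared_parameter_moves_both_syndromes(self):
        domains = _DOMAINS + [("BrS", "GENE1", "TM")]
        cfg = ModelConfig(syndromes=("LQTS", "BrS"), join="lqts_brs")
        priors = _toy_priors(("LQTS", "BrS"))
        graph = build_model(cfg, priors, domains)
        values = {name: 0.0 for name in graph.param_names}
        values[graph.role_map[("LQTS", "beta_freq")]] = -2.5
        for syndrome in ("LQTS", "BrS"):
            v = VariantRecord(
                variant_id="x", gene="GENE1", syndrome=syndrome,
                variant_class="radical", in_control_db=1,
            )
            d = build_design_vector(v, priors)
            ps = graph.parameter_set(values, syndrome)
            assert linear_predictor(ps, d) == pytest.approx(-2.5)


class TestEncodeConsistency:
    def test_design_matrix_matches_direct_linear_predictor(self):
        spec = GeneratorSpec()
        records = generate_from_model(spec, 60, seed=5)
        priors = spec.make_prior_table()
        graph = build_model(
            ModelConfig(syndromes=("LQTS",)), priors, training_domains_of(records)
        )
        rng = np.random.default_rng(12)
        theta = rng.normal(size=len(graph.param_names))
        values = dict(zip(graph.param_names, theta))
        params = graph.parameter_set(values, "LQTS")
        X, y = graph.encode(records)
        assert y.shape == (60,)
        for i, record in enumerate(records):
            d = build_design_vector(record, priors)
            assert X[i] @ theta == pytest.approx(linear_predictor(params, d), abs=1e-12)
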