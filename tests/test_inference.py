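"""Sampler contracts: burn-in, convergence diagnostic, summaries, recovery."""

import numpy as np
import pytest

from cardiobayes.inference import (
    ChainSet,
    InferenceError,
    fit,
    max_rhat,
    potential_scale_reduction,
    summarise,
)
from cardiobayes.model_network import ModelConfig, SCALAR_ROLES, build_model, training_domains_of
from cardiobayes.synthetic import recovery_spec, generate_from_model


def _chainset(arrays):
    return ChainSet(
        draws={"phi": np.asarray(arrays, dtype=float)},
        seed=0, n_iter=len(arrays[0]), burn_fraction=0.0,
    )


class TestPotentialScaleReduction:
    def test_hand_computed_value(self):
        # chains [1,3] and [5,7]: W = 2, B = var(means) = 8, n = 2
        # var_hat = 2*(1/2) + 8/2 = 5; R = sqrt(5/2)
        cs = _chainset([[1, 3], [5, 7]])
        assert potential_scale_reduction(cs, "phi") == pytest.approx(np.sqrt(2.5))

    def test_identical_constant_chains_define_r_as_one(self):
        cs = _chainset([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert potential_scale_reduction(cs, "phi") == 1.0

    def test_b_zero_gives_sub_unity_floor(self):
        # identical non-constant chains: B = 0, R = sqrt((n-1)/n)
        chain = np.sin(np.arange(100.0))
        cs = _chainset([chain, chain.copy()])
        assert potential_scale_reduction(cs, "phi") == pytest.approx(np.sqrt(99 / 100))

    def test_formula_on_synthetic_w_b(self):
        # calibrated chains: per-chain variance 1, chain means 0 and 2 -> B = 2
        rng = np.random.default_rng(4)
        n = 20_000
        base = rng.standard_normal(n)
        base = (base - base.mean()) / base.std(ddof=1)
        cs = _chainset([base, base + 2.0])
        expected = np.sqrt((1.0 * (n - 1) / n + 2.0 / n) / 1.0)
        assert potential_scale_reduction(cs, "phi") == pytest.approx(expected, rel=1e-12)

    def test_r_approaches_one_for_long_mixed_chains(self):
        rng = np.random.default_rng(9)
        cs = _chainset(rng.standard_normal((4, 50_000)))
        r = potential_scale_reduction(cs, "phi")
        assert np.sqrt(49_999 / 50_000) <= r < 1.01

    def test_single_chain_rejected(self):
        cs = _chainset([[1.0, 2.0, 3.0]])
        with pytest.raises(InferenceError):
            potential_scale_reduction(cs, "phi")


class TestSummarise:
    def test_pooled_median_small_case(self):
        cs = _chainset([[1.0, 2.0], [3.0, 4.0]])
        cs.draws["phi"] = np.array([[1.0, 2.0, 3.0]])
        assert summarise(cs).median["phi"] == 2.0

    def test_pooled_median_equals_sort_oracle(self, rng):
        draws = rng.normal(size=(3, 101))
        cs = _chainset(draws)
        flat = np.sort(draws.ravel())
        assert summarise(cs).median["phi"] == pytest.approx(flat[len(flat) // 2])


@pytest.fixture(scope="module")
def recovery_fit():
    """Three seed-pinned recovery runs at n=400."""
    spec = recovery_spec()
    runs = []
    for seed in (0, 1, 2):
        records = generate_from_model(spec, 400, seed=seed)
        graph = build_model(
            ModelConfig(syndromes=("LQTS",)), spec.make_prior_table(),
            training_domains_of(records),
        )
        runs.append(fit(graph, records, n_chains=2, n_iter=2_500, seed=seed))
    return spec, runs


class TestFit:
    def test_burn_in_arithmetic(self, synth_spec):
        records = generate_from_model(synth_spec, 40, seed=2)
        graph = build_model(
            ModelConfig(syndromes=("LQTS",)), synth_spec.make_prior_table(),
            training_domains_of(records),
        )
        chains = fit(graph, records, n_chains=2, n_iter=500, seed=3)
        assert chains.n_kept == 400
        assert chains.n_chains == 2

    def test_single_label_training_set_rejected(self, synth_spec):
        records = generate_from_model(synth_spec, 30, seed=2)
        for r in records:
            r.label = "pathogenic"
        graph = build_model(
            ModelConfig(syndromes=("LQTS",)), synth_spec.make_prior_table(),
            training_domains_of(records),
        )
        with pytest.raises(InferenceError, match="both labels"):
            fit(graph, records, n_chains=2, n_iter=200, seed=0)

    def test_bitwise_reproducibility(self, synth_spec):
        records = generate_from_model(synth_spec, 50, seed=6)
        graph = build_model(
            ModelConfig(syndromes=("LQTS",)), synth_spec.make_prior_table(),
            training_domains_of(records),
        )
        a = fit(graph, records, n_chains=2, n_iter=400, seed=21)
        b = fit(graph, records, n_chains=2, n_iter=400, seed=21)
        for name in a.draws:
            assert np.array_equal(a.draws[name], b.draws[name])

    def test_recovery_of_intercepts_and_sift(self, recovery_fit):
        """Typical (median-over-seeds) recovery error stays within half a logit
        for the well-identified parameters."""
        spec, runs = recovery_fit
        truth = spec.true_parameter_set()
        summaries = [summarise(chains) for chains in runs]
        for role in ("alpha_rad", "alpha_nr", "alpha_if", "beta_sift", "lambda_nr", "beta_freq"):
            errs = sorted(abs(s.median[role] - getattr(truth, role)) for s in summaries)
            assert errs[len(errs) // 2] < 0.5, (role, errs)

    def test_chains_mix_on_recovery_problem(self, recovery_fit):
        _, runs = recovery_fit
        assert all(max_rhat(chains) < 1.1 for chains in runs)

    def test_sigma2_positive_throughout(self, recovery_fit):
        _, runs = recovery_fit
        assert all((chains.draws["sigma2_dom"] > 0).all() for chains in runs)

    def test_uninformative_coefficient_reproduces_prior_spread(self, synth_spec):
        """A coefficient whose covariate is constant zero keeps its N(0,10) prior."""
        records = [
            r for r in generate_from_model(synth_spec, 400, seed=8)
            if r.variant_class != "missense"
        ]
        if not {r.label for r in records} == {"pathogenic", "benign"}:  # pragma: no cover
            pytest.skip("degenerate draw")
        graph = build_model(
            ModelConfig(syndromes=("LQTS",)), synth_spec.make_prior_table(),
            training_domains_of(records),
        )
        chains = fit(graph, records, n_chains=2, n_iter=6_000, seed=10)
        pooled = chains.pooled("beta_poly1")  # missense-only covariate, no data
        assert abs(pooled.std(ddof=1) - np.sqrt(10.0)) / np.sqrt(10.0) < 0.15

    def test_bias_shrinks_with_training_size(self):
        """Mean absolute error of fixed effects decreases from n=100 to n=1000."""
        spec = recovery_spec()
        truth = spec.true_parameter_set()
        sizes = (100, 300, 1000)
        seeds = (0, 1, 2, 3, 4)
        mean_abs_err = []
        for n in sizes:
            errs = []
            for seed in seeds:
                records = generate_from_model(spec, n, seed=seed)
                graph = build_model(
                    ModelConfig(syndromes=("LQTS",)), spec.make_prior_table(),
                    training_domains_of(records),
                )
                chains = fit(graph, records, n_chains=2, n_iter=1_200, seed=100 + seed)
                s = summarise(chains)
                errs.append(
                    np.mean([abs(s.median[r] - getattr(truth, r)) for r in SCALAR_ROLES])
                )
            mean_abs_err.append(np.mean(errs))
        assert mean_abs_err[0] > mean_abs_err[1] > mean_abs_err[2]
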