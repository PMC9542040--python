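"""Design construction, likelihood correctness and posterior behavior."""

import numpy as np
import pytest
from scipy import stats

from phylocrit import model, phylo, synth
from phylocrit.model import (
    MCMCConfig,
    ModelSpec,
    build_design,
    final_model_spec,
    marginal_log_likelihood,
    p_map,
    pointwise_log_likelihood,
    summarize,
)

from conftest import make_clean_record


def toy_records():
    return [
        make_clean_record(species="A", pcrit_kpa=4.0, temp_meas=10.0, log10_gs=0.2, log10_mass=0.5),
        make_clean_record(species="A", pcrit_kpa=5.0, temp_meas=20.0, log10_gs=0.2, log10_mass=0.7),
        make_clean_record(species="B", pcrit_kpa=6.0, temp_meas=15.0, log10_gs=-0.1, log10_mass=1.2, respirometry="closed"),
        make_clean_record(species="B", pcrit_kpa=7.0, temp_meas=25.0, log10_gs=-0.1, log10_mass=1.0),
        make_clean_record(species="C", pcrit_kpa=8.0, temp_meas=30.0, log10_gs=0.4, log10_mass=2.0, respirometry="unknown"),
    ]


class TestModelSpec:
    def test_interaction_requires_mains(self):
        with pytest.raises(ValueError, match="main effects"):
            ModelSpec(name="bad", fixed_terms=("intercept", "temp", "temp:gs"))

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelSpec(name="bad", fixed_terms=("intercept", "latitude"))

    def test_final_model_terms(self):
        spec = final_model_spec()
        assert set(spec.fixed_terms) == {
            "intercept", "temp", "gs", "bm", "salinity", "resid_mr", "temp:gs", "temp:bm",
        }
        assert set(spec.random_terms) == {"phylo", "species"}


class TestBuildDesign:
    def test_intercept_only(self):
        d = build_design(toy_records(), ModelSpec(name="i", fixed_terms=("intercept",)))
        np.testing.assert_array_equal(d.X, np.ones((5, 1)))

    def test_interaction_is_elementwise_product(self):
        spec = ModelSpec(name="x", fixed_terms=("intercept", "temp", "bm", "temp:bm"))
        d = build_design(toy_records(), spec)
        it, ib = d.colnames.index("temp"), d.colnames.index("bm")
        np.testing.assert_allclose(d.X[:, d.colnames.index("temp:bm")], d.X[:, it] * d.X[:, ib])

    def test_grouping_map(self):
        d = build_design(toy_records(), ModelSpec(name="i", fixed_terms=("intercept",)))
        assert d.groups == {0: [0, 1], 1: [2, 3], 2: [4]}
        np.testing.assert_array_equal(d.Z.sum(axis=1), np.ones(5))

    def test_respirometry_dummies_reference_intermittent(self):
        spec = ModelSpec(name="r", fixed_terms=("intercept", "respirometry"))
        d = build_design(toy_records(), spec)
        assert "respirometry[closed]" in d.colnames
        assert "respirometry[unknown]" in d.colnames
        closed = d.X[:, d.colnames.index("respirometry[closed]")]
        np.testing.assert_array_equal(closed, [0, 0, 1, 0, 0])
        # intermittent rows carry zeros in all dummies (reference level)
        assert d.X[0, 1:].sum() == 0

    def test_unseen_species_raises(self):
        with pytest.raises(ValueError, match="missing from"):
            build_design(toy_records(), ModelSpec(name="i", fixed_terms=("intercept",)), species_order=["A", "B"])


def toy_C():
    t = phylo.rho_transform(phylo.grafen_heights(phylo.parse_newick("((A,B),C);")), 0.4)
    return phylo.correlation_matrix(t)


class TestLikelihood:
    def setup_method(self):
        self.records = toy_records()
        self.spec = ModelSpec(name="t", fixed_terms=("intercept", "temp"))
        self.C = toy_C()
        self.d = build_design(self.records, self.spec, species_order=self.C.species)
        self.beta = np.array([1.0, 0.2])

    def test_matches_dense_mvn_oracle(self):
        """Marginal likelihood equals a brute-force dense MVN evaluation."""
        sds = {"sd_phylo": 1.3, "sd_species": 0.7, "sd_resid": 0.9}
        Cm = self.C.reorder(self.d.species_order).matrix
        got = marginal_log_likelihood(self.d.y, self.d.X, self.beta, sds, self.d.Z, Cm)
        cov = (
            sds["sd_phylo"] ** 2 * self.d.Z @ Cm @ self.d.Z.T
            + sds["sd_species"] ** 2 * self.d.Z @ self.d.Z.T
            + sds["sd_resid"] ** 2 * np.eye(5)
        )
        want = stats.multivariate_normal.logpdf(self.d.y, mean=self.d.X @ self.beta, cov=cov)
        assert got == pytest.approx(want, abs=1e-8)

    def test_zero_random_effects_is_iid_regression(self):
        sds = {"sd_phylo": 0.0, "sd_species": 0.0, "sd_resid": 1.1}
        got = marginal_log_likelihood(self.d.y, self.d.X, self.beta, sds, self.d.Z)
        want = stats.norm.logpdf(self.d.y, self.d.X @ self.beta, 1.1).sum()
        assert got == pytest.approx(want, abs=1e-10)

    def test_identity_C_makes_effects_exchangeable(self):
        """With C = I the phylo and species variances only enter as a sum."""
        I = np.eye(3)
        a = marginal_log_likelihood(self.d.y, self.d.X, self.beta, {"sd_phylo": 1.2, "sd_species": 0.5, "sd_resid": 1.0}, self.d.Z, I)
        b = marginal_log_likelihood(self.d.y, self.d.X, self.beta, {"sd_phylo": 0.5, "sd_species": 1.2, "sd_resid": 1.0}, self.d.Z, I)
        assert a == pytest.approx(b, abs=1e-10)

    def test_pointwise_is_conditional_normal(self):
        mu = self.d.X @ self.beta
        got = pointwise_log_likelihood(self.d.y, mu, 0.8)
        np.testing.assert_allclose(got, stats.norm.logpdf(self.d.y, mu, 0.8))


class TestFit:
    def test_fixed_effects_match_ols(self):
        """Fixed-effects-only fit on nearly-noiseless data recovers OLS."""
        rng = np.random.default_rng(8)
        records = []
        for i in range(80):
            t = float(rng.uniform(5, 30))
            lm = float(rng.normal(1, 0.5))
            y = 2.0 + 0.3 * t - 1.1 * lm + float(rng.normal(0, 0.05))
            records.append(make_clean_record(species=f"s{i:03d}", pcrit_kpa=y, temp_meas=t, log10_mass=lm))
        spec = ModelSpec(name="ols", fixed_terms=("intercept", "temp", "bm"), random_terms=())
        post = model.fit(records, spec, mcmc=MCMCConfig(chains=2, iterations=800, warmup=300), seed=1)
        d = post.design
        ols = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        np.testing.assert_allclose(post.flat_beta().mean(axis=0), ols, atol=0.02)

    def test_sd_phylo_shrinks_to_zero_when_absent(self):
        """No between-species variance in truth (C = I): sd_phylo collapses.

        With an identity correlation matrix the phylogenetic and species
        intercepts are exchangeable, so the truth must hold both at zero for
        either to be shrunk away.
        """
        truth = synth.default_truth(seed=9, sd_phylo=0.0, sd_species=0.0)
        records, _, _, truth = synth.simulate_dataset(truth, 160, n_species=40)
        spec = ModelSpec(name="full", fixed_terms=tuple(truth.beta))  # both random terms
        C_eye = phylo.PhyloCorrelation(sorted({r.species_name for r in records}), np.eye(40))
        post = model.fit(records, spec, C=C_eye, mcmc=MCMCConfig(chains=2, iterations=900, warmup=400), seed=3)
        q50_phylo = np.median(post.flat_sd("sd_phylo"))
        q50_resid = np.median(post.flat_sd("sd_resid"))
        assert q50_phylo < 0.2 * q50_resid

    def test_prior_predictive_matches_prior(self):
        """A data-free fit returns draws centered on the prior."""
        spec = ModelSpec(name="p", fixed_terms=("intercept", "temp"), random_terms=("species",))
        post = model.fit([], spec, mcmc=MCMCConfig(chains=2, iterations=3000, warmup=500), seed=4)
        b = post.flat_beta()
        assert abs(b.mean()) < 0.1 * spec.beta_prior_scale
        # half-normal mean is scale*sqrt(2/pi)
        expected_sd_mean = spec.sd_prior_scale * np.sqrt(2 / np.pi)
        assert post.flat_sd("sd_resid").mean() == pytest.approx(expected_sd_mean, rel=0.1)

    def test_record_order_invariance(self, small_dataset):
        """Permuting records changes summaries only within Monte-Carlo error."""
        records, _, C, truth = small_dataset
        cfg = MCMCConfig(chains=2, iterations=700, warmup=300)
        post1 = model.fit(records, truth.spec(), C=C, mcmc=cfg, seed=6)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(records)))
        post2 = model.fit([records[i] for i in perm], truth.spec(), C=C, mcmc=cfg, seed=6)
        m1, m2 = post1.flat_beta().mean(axis=0), post2.flat_beta().mean(axis=0)
        se = post1.flat_beta().std(axis=0) / 5.0  # generous MC error scale
        assert post1.design.colnames == post2.design.colnames
        np.testing.assert_array_less(np.abs(m1 - m2), post1.flat_beta().std(axis=0) * 0.5 + 5 * se)

    def test_missing_C_raises(self):
        with pytest.raises(ValueError, match="correlation"):
            model.fit(toy_records(), final_model_spec())

    def test_rhat_reported_per_parameter(self, small_posterior):
        keys = set(small_posterior.rhat)
        assert {"sd_phylo", "sd_species", "sd_resid"} <= keys
        assert any(k.startswith("beta_") for k in keys)
        assert isinstance(small_posterior.converged, bool)


class TestSummaries:
    def test_p_map_symmetric_draws_near_one(self):
        draws = np.random.default_rng(1).normal(0.0, 1.0, 4000)
        assert p_map(draws) > 0.9

    def test_p_map_far_from_zero(self):
        draws = np.random.default_rng(2).normal(5.0, 0.1, 4000)
        assert p_map(draws) < 1e-3

    def test_summary_table_shape(self, small_posterior):
        s = summarize(small_posterior)
        assert {"mean", "q2.5", "q97.5", "effective_sampling", "p_map"} <= set(s.columns)
        assert (s["q2.5"] <= s["mean"]).all() and (s["mean"] <= s["q97.5"]).all()
        # p(MAP) reported for fixed effects, not for the SDs
        assert np.isnan(s.loc["sd_phylo", "p_map"])
        assert 0 <= s.loc["temp:gs", "p_map"] <= 1

    def test_effective_sampling_near_draw_count_for_iid(self):
        """Independent draws score an ESS within 15% of the draw count."""
        from conftest import make_posterior

        rng = np.random.default_rng(11)
        beta = rng.normal(size=(2, 2000, 1))
        sds = {"sd_resid": np.abs(rng.normal(size=(2, 2000)))}
        s = summarize(make_posterior(beta, sds, colnames=["slope"]))
        assert s.loc["slope", "effective_sampling"] == pytest.approx(4000, rel=0.15)
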