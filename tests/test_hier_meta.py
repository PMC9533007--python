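"""Hierarchical model: density, sampler, summaries, EMMs, diagnostics."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from covgrad.hier_meta import (
    MetaDataset,
    ModelSpec,
    PriorSpec,
    diagnostics,
    estimated_marginal_means,
    log_posterior,
    sample_posterior,
    summarize,
)
from covgrad.phylo_vcv import RelatednessMatrix
from covgrad.synthetic_data import MetaScenario, simulate_meta_dataset


def small_dataset(n=5, seed=0, n_species=3, n_studies=2):
    rng = np.random.default_rng(seed)
    study = np.array([f"s{i % n_studies}" for i in range(n)], object)
    trait_study = np.array([f"s{i % n_studies}::t{i % 3}" for i in range(n)], object)
    species = np.array([f"sp{i % n_species}" for i in range(n)], object)
    return MetaDataset(
        d=rng.normal(1.0, 1.0, n),
        v=rng.uniform(0.05, 0.3, n),
        study=study,
        trait_study=trait_study,
        species=species,
    )


def simple_relatedness(labels, rho=0.4):
    k = len(labels)
    a = np.full((k, k), rho)
    np.fill_diagonal(a, 1.0)
    return RelatednessMatrix(labels=tuple(labels), values=a)


class TestLogPosterior:
    def test_matches_termwise_oracle(self):
        """Density equals an independently assembled prior x likelihood."""
        data = small_dataset()
        a = simple_relatedness(sorted(set(data.species)))
        spec = ModelSpec()
        rng = np.random.default_rng(1)
        state = {
            "beta": np.array([0.7]),
            "u": rng.normal(0, 1, 2),
            "w": rng.normal(0, 1, 5),
            "p": rng.normal(0, 1, 3),
            "sigma_study": 0.6,
            "sigma_trait_study": 1.1,
            "sigma_phylo": 0.8,
        }
        # oracle: assemble every term with scipy, ordering levels as sorted
        pr = spec.priors
        lp = stats.norm.logpdf(0.7, 0, pr.intercept_scale)
        for name in ("sigma_study", "sigma_trait_study", "sigma_phylo"):
            lp += math.log(2) + stats.t.logpdf(
                state[name], pr.sd_df, scale=pr.sd_scale
            )
        lp += stats.norm.logpdf(state["u"], 0, 0.6).sum()
        lp += stats.norm.logpdf(state["w"], 0, 1.1).sum()
        lp += stats.multivariate_normal.logpdf(
            state["p"], np.zeros(3), 0.8**2 * a.values
        )
        studies = sorted(set(data.study))
        tss = sorted(set(data.trait_study))
        sps = sorted(set(data.species))
        for i in range(len(data)):
            theta = (
                0.7
                + state["u"][studies.index(data.study[i])]
                + state["w"][tss.index(data.trait_study[i])]
                + state["p"][sps.index(data.species[i])]
            )
            lp += stats.norm.logpdf(data.d[i], theta, math.sqrt(data.v[i]))
        assert log_posterior(state, data, spec, a) == pytest.approx(lp, rel=1e-12)

    def test_nonpositive_sigma_is_rejected_region(self):
        data = small_dataset()
        a = simple_relatedness(sorted(set(data.species)))
        state = {
            "beta": np.array([0.0]), "u": np.zeros(2), "w": np.zeros(5),
            "p": np.zeros(3), "sigma_study": -0.1,
            "sigma_trait_study": 1.0, "sigma_phylo": 1.0,
        }
        assert log_posterior(state, data, ModelSpec(), a) == -np.inf

    def test_empty_dataset_reduces_to_prior(self):
        empty = MetaDataset(
            d=np.zeros(0), v=np.zeros(0), study=np.array([], object),
            trait_study=np.array([], object), species=np.array([], object),
        )
        spec = ModelSpec(random=("study",))
        state = {"beta": np.array([1.5]), "u": np.zeros(0), "sigma_study": 2.0}
        pr = spec.priors
        expect = stats.norm.logpdf(1.5, 0, pr.intercept_scale) + math.log(2) \
            + stats.t.logpdf(2.0, pr.sd_df, scale=pr.sd_scale)
        assert log_posterior(state, empty, spec, None) == pytest.approx(expect)

    def test_identity_relatedness_equals_iid_species_term(self):
        """With A = I the phylogenetic density is the iid species density."""
        data = small_dataset()
        a_eye = RelatednessMatrix(
            labels=tuple(sorted(set(data.species))), values=np.eye(3)
        )
        state = {
            "beta": np.array([0.3]), "u": np.zeros(2), "w": np.zeros(5),
            "p": np.array([0.4, -0.2, 0.9]), "sigma_study": 1.0,
            "sigma_trait_study": 1.0, "sigma_phylo": 0.7,
        }
        lp = log_posterior(state, data, ModelSpec(), a_eye)
        # replace the MVN term by independent normals: must be identical
        mvn = stats.multivariate_normal.logpdf(
            state["p"], np.zeros(3), 0.7**2 * np.eye(3)
        )
        iid = stats.norm.logpdf(state["p"], 0, 0.7).sum()
        assert mvn == pytest.approx(iid, rel=1e-12)
        assert np.isfinite(lp)


class TestSampler:
    def test_single_record_collapse(self):
        """All sigmas 0 + flat prior: posterior of mu is N(d1, v1)."""
        data = MetaDataset(
            d=np.array([0.8]), v=np.array([0.09]),
            study=np.array(["s"], object),
            trait_study=np.array(["s::t"], object),
            species=np.array(["sp"], object),
        )
        spec = ModelSpec(
            random=("study", "trait_study"),
            priors=PriorSpec(intercept_scale=math.inf),
            fixed_sigma={"study": 0.0, "trait_study": 0.0},
        )
        dr = sample_posterior(data, spec, None, chains=2, iterations=4000,
                              seed=5)
        mu = dr.flat("b_intercept")
        assert mu.mean() == pytest.approx(0.8, abs=0.02)
        assert mu.std() == pytest.approx(0.3, abs=0.02)

    def test_prior_recovery_without_data(self):
        """Zero records: sigma draws recover the half-t prior, the intercept
        its normal prior."""
        empty = MetaDataset(
            d=np.zeros(0), v=np.zeros(0), study=np.array([], object),
            trait_study=np.array([], object), species=np.array([], object),
        )
        dr = sample_posterior(
            empty, ModelSpec(random=("study", "trait_study")), None,
            chains=2, iterations=4000, seed=7,
        )
        s = dr.flat("sigma_study")
        theory = stats.t(3, scale=2.5)
        # quartiles of |t_3| * 2.5: qs of t at 0.625, 0.75, 0.875
        expect = theory.ppf([0.625, 0.75, 0.875])
        assert np.quantile(s, [0.25, 0.5, 0.75]) == pytest.approx(
            expect, rel=0.15
        )
        mu = dr.flat("b_intercept")
        assert mu.mean() == pytest.approx(0.0, abs=0.2)
        assert mu.std() == pytest.approx(5.0, rel=0.1)

    def test_reproducible_and_permutation_invariant(self):
        data, truth = simulate_meta_dataset(
            MetaScenario(n_studies=8, n_species=6), seed=3
        )
        a = truth["relatedness"]
        d1 = sample_posterior(data, ModelSpec(), a, chains=2,
                              iterations=300, seed=9)
        d2 = sample_posterior(data, ModelSpec(), a, chains=2,
                              iterations=300, seed=9)
        perm = np.random.default_rng(0).permutation(len(data))
        shuffled = dataclasses.replace(
            data, d=data.d[perm], v=data.v[perm], study=data.study[perm],
            trait_study=data.trait_study[perm], species=data.species[perm],
            covariates=data.covariates.iloc[perm].reset_index(drop=True),
        )
        d3 = sample_posterior(shuffled, ModelSpec(), a, chains=2,
                              iterations=300, seed=9)
        for k in d1.params:
            assert np.array_equal(d1.params[k], d2.params[k])
            assert np.array_equal(d1.params[k], d3.params[k])

    def test_retained_draw_count(self):
        data = small_dataset(n=8)
        a = simple_relatedness(sorted(set(data.species)))
        dr = sample_posterior(data, ModelSpec(), a, chains=3,
                              iterations=200, warmup=80, thin=4, seed=1)
        assert dr.n_chains == 3
        assert dr.n_draws == (200 - 80) // 4
        df = dr.to_dataframe()
        assert set(df["chain"]) == {0, 1, 2}

    def test_non_psd_relatedness_rejected(self):
        data = small_dataset()
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.9],
                        [-0.99, 0.9, 1.0]])
        with pytest.raises(ValueError):
            a = RelatednessMatrix(
                labels=tuple(sorted(set(data.species))), values=bad
            )
            sample_posterior(data, ModelSpec(), a, chains=1, iterations=10)


class TestSummarize:
    def test_mean_median_of_tiny_sample(self):
        out = summarize({"x": np.array([[1.0, 2.0, 3.0]] * 40)})
        assert out.loc["x", "mean"] == 2.0
        assert out.loc["x", "median"] == 2.0

    def test_monotone_transform_of_quantiles(self, rng):
        # 1001 draws puts the 2.5/50/97.5% points exactly on order
        # statistics, where quantiles commute with monotone transforms
        s = rng.uniform(0.1, 2.0, size=(1, 1001))
        qs = summarize({"sigma": s})
        qs2 = summarize({"sigma2": s**2})
        for col in ("median", "q2.5", "q97.5"):
            assert qs2.loc["sigma2", col] == pytest.approx(
                qs.loc["sigma", col] ** 2
            )

    def test_normal_quantiles(self, rng):
        x = rng.standard_normal((4, 50_000))
        out = summarize({"x": x})
        assert out.loc["x", "q2.5"] == pytest.approx(-1.96, abs=0.03)
        assert out.loc["x", "q97.5"] == pytest.approx(1.96, abs=0.03)

    def test_few_draws_warn(self):
        with pytest.warns(UserWarning, match="retained draws"):
            summarize({"x": np.ones((1, 10))})


@pytest.fixture(scope="module")
def fitted():
    data, truth = simulate_meta_dataset(
        MetaScenario(
            n_studies=12, n_species=6,
            covariate_effects={"trait": {"body size": 1.0},
                               "gradient": {"temperature": 0.8}},
        ),
        seed=21,
    )
    spec = ModelSpec(fixed=("trait", "gradient"))
    draws = sample_posterior(data, spec, truth["relatedness"], chains=2,
                             iterations=3000, seed=2)
    return data, truth, draws


class TestEMM:

    def test_matches_bruteforce_reference_grid(self, fitted):
        data, truth, draws = fitted
        emm = estimated_marginal_means(draws, "trait")
        levels_t = draws.design.levels["trait"]
        levels_g = draws.design.levels["gradient"]
        for lev in levels_t:
            cells = []
            for g in levels_g:
                pred = draws.flat("b_intercept").copy()
                if f"trait[{lev}]" in draws.design.columns:
                    pred = pred + draws.flat(f"b_trait[{lev}]")
                if f"gradient[{g}]" in draws.design.columns:
                    pred = pred + draws.flat(f"b_gradient[{g}]")
                cells.append(pred)
            brute = np.mean(cells, axis=0)
            assert emm.loc[lev, "mean"] == pytest.approx(brute.mean(),
                                                         rel=1e-12)
            assert emm.loc[lev, "median"] == pytest.approx(
                np.median(brute), rel=1e-12
            )

    def test_invariant_to_reference_level(self, fitted):
        data, truth, draws = fitted
        spec2 = ModelSpec(
            fixed=("trait", "gradient"),
            reference_levels={"trait": "metabolic rate"},
        )
        draws2 = sample_posterior(data, spec2, truth["relatedness"], chains=2,
                                  iterations=3000, seed=2)
        emm1 = estimated_marginal_means(draws, "gradient")
        emm2 = estimated_marginal_means(draws2, "gradient")
        # same chains cannot be expected draw-by-draw, but the posterior EMMs
        # must agree within Monte Carlo error
        assert emm1["mean"].to_numpy() == pytest.approx(
            emm2["mean"].to_numpy(), abs=0.15
        )

    def test_unknown_covariate_error(self, fitted):
        _, _, draws = fitted
        with pytest.raises(ValueError, match="not in the model"):
            estimated_marginal_means(draws, "moon_phase")


class TestDiagnostics:
    def test_iid_chains_near_one(self, rng):
        arr = rng.standard_normal((4, 2000))
        out = diagnostics({"x": arr})
        assert 0.99 <= out.loc["x", "rhat"] <= 1.02

    def test_shifted_chains_flagged(self, rng):
        arr = rng.standard_normal((4, 500))
        arr[0] += 3.0
        out = diagnostics({"x": arr})
        assert out.loc["x", "rhat"] > 1.1

    def test_single_chain_warns(self, rng):
        with pytest.warns(UserWarning, match="chains"):
            out = diagnostics({"x": rng.standard_normal((1, 200))})
        assert np.isnan(out.loc["x", "rhat"])

    def test_constant_chain_reported_degenerate(self):
        out = diagnostics({"x": np.ones((4, 100))})
        assert np.isnan(out.loc["x", "ess_bulk"])
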