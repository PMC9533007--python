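"""Generators: reaction-norm experiments and hierarchical meta-datasets."""

import numpy as np
import pytest

from covgrad.effect_sizes import (
    PatternLabel,
    classify_covariation_pattern,
    per_treatment_effect_sizes,
)
from covgrad.synthetic_data import (
    GradientScenario,
    MetaScenario,
    default_home_map,
    random_taxonomy,
    simulate_experiment,
    simulate_meta_dataset,
    simulate_observations_from_meta,
    true_polar_effect,
)


def counter_scenario(**kw):
    base = dict(
        positions=(0.0, 0.5, 1.0),
        genetic_effects=(0.0, 1.0, 2.0),
        env_effects={0.0: 0.0, 1.0: 0.8, 2.0: 1.6},
        covariation="counter",
        sigma_resid=0.5,
        n_per_cell=15,
    )
    base.update(kw)
    return GradientScenario(**base)


class TestSimulateExperiment:
    def test_noiseless_cell_means_exact(self):
        scen = counter_scenario(sampling_noise=False, sigma_gxe=0.0)
        obs = simulate_experiment(scen, seed=0)
        for o in obs:
            p = scen.positions.index(o.gradient_position)
            expect = scen.genetic_effects[p] + scen.env_effects[o.treatment_level]
            assert o.mean == pytest.approx(expect, abs=1e-12)
            assert o.sd == scen.sigma_resid

    def test_same_seed_identical_tables(self):
        scen = counter_scenario(sigma_gxe=0.3)
        assert simulate_experiment(scen, seed=42) == \
            simulate_experiment(scen, seed=42)
        assert simulate_experiment(scen, seed=42) != \
            simulate_experiment(scen, seed=43)

    def test_home_map_covariation_sign(self):
        scen = counter_scenario()
        homes = default_home_map(scen)
        g = np.array(scen.genetic_effects)
        e_home = np.array([scen.env_effects[homes[p]] for p in range(3)])
        assert np.corrcoef(g, e_home)[0, 1] < 0
        co = counter_scenario(covariation="co")
        homes_co = default_home_map(co)
        e_home_co = np.array([co.env_effects[homes_co[p]] for p in range(3)])
        assert np.corrcoef(g, e_home_co)[0, 1] > 0

    def test_invalid_home_map_rejected(self):
        with pytest.raises(ValueError, match="unknown treatments"):
            counter_scenario(home_map={0: 99.0, 1: 0.0, 2: 1.0})

    def test_pipeline_closure(self):
        """Generator output feeds the extraction chain with no adapters."""
        obs = simulate_experiment(counter_scenario(), seed=7)
        recs = per_treatment_effect_sizes(obs)
        assert len(recs) == 3
        label = classify_covariation_pattern(obs)
        assert label == PatternLabel.COUNTERGRADIENT

    def test_noisy_counter_detection(self):
        """Detection holds across seeds when noise is small relative to G."""
        scen = counter_scenario(sigma_gxe=0.1)
        hits = sum(
            classify_covariation_pattern(simulate_experiment(scen, seed=s))
            == PatternLabel.COUNTERGRADIENT
            for s in range(20)
        )
        assert hits >= 19


class TestTruePolarEffect:
    def test_simple_offset(self):
        scen = counter_scenario(
            positions=(0.0, 1.0), genetic_effects=(0.0, 1.0), sigma_resid=1.0
        )
        assert true_polar_effect(scen) == 1.0

    def test_degenerate_dispersion_error(self):
        with pytest.raises(ValueError, match="undefined"):
            true_polar_effect(counter_scenario(sigma_resid=0.0))

    def test_extracted_effects_converge_to_truth(self):
        scen = counter_scenario(n_per_cell=1000)
        d_true = true_polar_effect(scen)
        ds = [
            r.d
            for s in range(5)
            for r in per_treatment_effect_sizes(
                simulate_experiment(scen, seed=s)
            )
        ]
        assert np.mean(ds) == pytest.approx(d_true, rel=0.05)


class TestRandomTaxonomy:
    def test_psd_for_many_seeds(self):
        from covgrad.phylo_vcv import lineages_to_relatedness

        for seed in range(5):
            a = lineages_to_relatedness(random_taxonomy(12, seed))
            assert np.linalg.eigvalsh(a.values).min() >= -1e-10

    def test_fanout_controls_clustering(self):
        lin = random_taxonomy(9, 0, genus_size=3)
        genera = {l.taxa[5] for l in lin}
        assert len(genera) == 3


class TestSimulateMetaDataset:
    def test_record_count_and_structure(self):
        meta = MetaScenario()
        data, truth = simulate_meta_dataset(meta, seed=0)
        assert len(data) == meta.n_records == 200
        assert len(set(data.study)) == 40
        assert len(set(data.species)) == 25
        assert truth["relatedness"].values.shape == (25, 25)

    def test_all_sigmas_zero_gives_pure_sampling_noise(self):
        meta = MetaScenario(
            n_studies=100, sigma_study=0.0, sigma_trait_study=0.0,
            sigma_phylo=0.0,
        )
        data, truth = simulate_meta_dataset(meta, seed=1)
        assert np.all(truth["theta"] == meta.mu)
        z = (data.d - meta.mu) / np.sqrt(data.v)
        assert np.mean(z) == pytest.approx(0.0, abs=0.1)
        assert np.std(z) == pytest.approx(1.0, abs=0.08)

    def test_latent_variance_decomposition(self):
        """Empirical variances of the drawn latent effects match the truth
        within 10% at ~2000 records."""
        meta = MetaScenario(n_studies=400)
        _, truth = simulate_meta_dataset(meta, seed=3)
        assert np.var(list(truth["u"].values())) == pytest.approx(
            meta.sigma_study**2, rel=0.10
        )
        assert np.var(list(truth["w"].values())) == pytest.approx(
            meta.sigma_trait_study**2, rel=0.10
        )

    def test_zero_studies_rejected(self):
        with pytest.raises(ValueError):
            MetaScenario(n_studies=0)


class TestObservationRealization:
    def test_observation_tables_close_the_loop(self):
        meta = MetaScenario(n_studies=6, n_species=5)
        obs, lineages, truth = simulate_observations_from_meta(meta, seed=4)
        assert {o.species for o in obs} <= {l.species for l in lineages}
        # experiments are grouped (study, experiment, trait); each is a
        # valid input to the extraction chain
        from covgrad.effect_sizes import group_experiments

        exps = group_experiments(obs)
        assert len(exps) == meta.n_studies * meta.traits_per_study
        labels = truth["experiments"].set_index(["study_id", "trait"])
        for (study, _, trait), cells in exps.items():
            want = labels.loc[(study, trait), "covariation"]
            got = classify_covariation_pattern(cells)
            if got in (PatternLabel.COUNTERGRADIENT, PatternLabel.COGRADIENT):
                assert got.value.startswith(want)
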