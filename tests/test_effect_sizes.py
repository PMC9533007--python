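"""Hedges' d, polar-population selection and pattern classification."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from covgrad.effect_sizes import (
    DegenerateDispersionError,
    ExperimentExcluded,
    InsufficientReplicationError,
    PatternLabel,
    classify_covariation_pattern,
    hedges_d,
    per_treatment_effect_sizes,
    select_polar_populations,
)
from covgrad.synthetic_data import canonical_pattern_scenarios, simulate_experiment

from conftest import make_experiment


def hedges_d_oracle(m1, s1, n1, m2, s2, n2):
    """Independent evaluation of the Hedges-Olkin formulas."""
    sp = (((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)) ** 0.5
    j = 1 - 3 / (4 * (n1 + n2 - 2) - 1)
    d = j * (m1 - m2) / sp
    return d, 1 / n1 + 1 / n2 + d**2 / (2 * (n1 + n2))


class TestHedgesD:
    def test_identical_means_give_zero(self):
        d, v = hedges_d(10, 2, 10, 10, 2, 10)
        assert d == 0.0
        assert v == pytest.approx(0.2)

    def test_small_sample_corrected_value(self):
        # pooled SD 2, raw SMD 1, J = 1 - 3/71
        d, v = hedges_d(10, 2, 10, 8, 2, 10)
        assert d == pytest.approx(1 - 3 / 71, abs=1e-12)
        assert v == pytest.approx(0.2 + d**2 / 40, abs=1e-12)

    def test_antisymmetry(self):
        d1, v1 = hedges_d(10, 2, 10, 8, 3, 15)
        d2, v2 = hedges_d(8, 3, 15, 10, 2, 10)
        assert d1 == pytest.approx(-d2, abs=1e-15)
        assert v1 == pytest.approx(v2, abs=1e-15)

    @given(
        m1=st.floats(-50, 50), m2=st.floats(-50, 50),
        s1=st.floats(0.1, 20), s2=st.floats(0.1, 20),
        n1=st.integers(2, 500), n2=st.integers(2, 500),
    )
    def test_matches_oracle(self, m1, m2, s1, s2, n1, n2):
        d, v = hedges_d(m1, s1, n1, m2, s2, n2)
        d0, v0 = hedges_d_oracle(m1, s1, n1, m2, s2, n2)
        assert d == pytest.approx(d0, abs=1e-12)
        assert v == pytest.approx(v0, abs=1e-12)
        assert v > 0

    def test_correction_vanishes_for_large_samples(self):
        uncorrected = (10 - 8) / 2.0
        d_small, _ = hedges_d(10, 2, 5, 8, 2, 5)
        d_large, _ = hedges_d(10, 2, 5000, 8, 2, 5000)
        assert abs(d_large - uncorrected) < 1e-3 < abs(d_small - uncorrected)

    def test_errors(self):
        with pytest.raises(DegenerateDispersionError):
            hedges_d(1, 0, 10, 2, 0, 10)
        with pytest.raises(InsufficientReplicationError):
            hedges_d(1, 1, 1, 2, 1, 10)


class TestPolarSelection:
    def test_most_disparate_of_three(self):
        exp = make_experiment(
            means={("a", 0.0): 1.0, ("b", 0.0): 2.0, ("c", 0.0): 3.0},
            positions={"a": 500.0, "b": 1000.0, "c": 1500.0},
            homes={},
        )
        assert select_polar_populations(exp) == ("a", "c")

    def test_two_populations_identity(self):
        exp = make_experiment(
            means={("x", 0.0): 1.0, ("y", 0.0): 2.0},
            positions={"x": 3.0, "y": 1.0},
            homes={},
        )
        assert select_polar_populations(exp) == ("y", "x")

    def test_tie_broken_lexicographically_with_warning(self, caplog):
        exp = make_experiment(
            means={("b", 0.0): 1.0, ("a", 0.0): 2.0, ("c", 0.0): 3.0},
            positions={"b": 1.0, "a": 1.0, "c": 3.0},
            homes={},
        )
        with caplog.at_level(logging.WARNING, logger="covgrad.effect_sizes"):
            assert select_polar_populations(exp) == ("a", "c")
        assert any("tie" in r.message.lower() for r in caplog.records)

    def test_single_population_error(self):
        exp = make_experiment(
            means={("a", 0.0): 1.0}, positions={"a": 1.0}, homes={},
        )
        with pytest.raises(ValueError):
            select_polar_populations(exp)


class TestPerTreatmentEffectSizes:
    def test_one_record_per_shared_treatment(self, counter_experiment):
        recs = per_treatment_effect_sizes(counter_experiment)
        assert len(recs) == 2
        assert all(r.v > 0 for r in recs)
        assert np.mean([r.d for r in recs]) >= 0
        assert {r.treatment_level for r in recs} == {0.0, 1.0}
        assert len({r.orientation for r in recs}) == 1

    def test_middle_population_ignored(self):
        exp = make_experiment(
            means={("a", 0.0): 0.0, ("a", 1.0): 1.0,
                   ("b", 0.0): 5.0, ("b", 1.0): 6.0,
                   ("c", 0.0): 2.0, ("c", 1.0): 3.0},
            positions={"a": 500.0, "b": 1000.0, "c": 1500.0},
            homes={},
        )
        recs = per_treatment_effect_sizes(exp)
        assert all(r.orientation == "c-a" for r in recs)

    def test_unshared_treatments_dropped_pairwise(self):
        exp = make_experiment(
            means={("a", 0.0): 0.0, ("a", 1.0): 1.0, ("a", 2.0): 2.0,
                   ("b", 0.0): 2.0, ("b", 1.0): 3.0},
            positions={"a": 0.0, "b": 1.0},
            homes={},
        )
        recs = per_treatment_effect_sizes(exp)
        assert {r.treatment_level for r in recs} == {0.0, 1.0}

    def test_single_shared_treatment_excluded(self):
        exp = make_experiment(
            means={("a", 0.0): 0.0, ("a", 2.0): 1.0, ("b", 1.0): 2.0,
                   ("b", 0.0): 1.0},
            positions={"a": 0.0, "b": 1.0},
            homes={},
        )
        with pytest.raises(ExperimentExcluded, match="common environments"):
            per_treatment_effect_sizes(exp)  # pair shares only t=0

    def test_noiseless_generator_constant_offset_gives_equal_d(self):
        scen = canonical_pattern_scenarios()["countergradient"]
        obs = simulate_experiment(scen, seed=0)
        recs = per_treatment_effect_sizes(obs)
        # closed form: J * (G_hi - G_lo) / sigma_resid in every treatment
        j = 1 - 3 / (4 * (2 * scen.n_per_cell - 2) - 1)
        expect = j * 2.0 / 1.0
        assert [r.d for r in recs] == pytest.approx([expect] * len(recs))


class TestPatternClassifier:
    def test_canonical_parameterizations(self):
        for name, scen in canonical_pattern_scenarios().items():
            obs = simulate_experiment(scen, seed=0)
            assert classify_covariation_pattern(obs) == PatternLabel(name)

    def test_countergradient_geometry(self, counter_experiment):
        label = classify_covariation_pattern(counter_experiment)
        assert label == PatternLabel.COUNTERGRADIENT

    def test_cogradient_geometry(self):
        # same reaction norms, home assignments swapped
        exp = make_experiment(
            means={("lo", 0.0): 0.0, ("lo", 1.0): 1.0,
                   ("hi", 0.0): 2.0, ("hi", 1.0): 3.0},
            positions={"lo": 10.0, "hi": 50.0},
            homes={"lo": 0.0, "hi": 1.0},
        )
        assert classify_covariation_pattern(exp) == PatternLabel.COGRADIENT

    def test_sign_change_is_crossing(self):
        exp = make_experiment(
            means={("lo", 0.0): 0.0, ("lo", 1.0): 1.0,
                   ("hi", 0.0): 1.0, ("hi", 1.0): 0.0},
            positions={"lo": 0.0, "hi": 1.0},
            homes={"lo": 0.0, "hi": 1.0},
        )
        assert classify_covariation_pattern(exp) == PatternLabel.CROSSING_GXE

    def test_relabeling_populations_keeps_label(self, counter_experiment):
        import dataclasses

        swap = {"lo": "zzz", "hi": "aaa"}
        relabeled = [
            dataclasses.replace(o, population_id=swap[o.population_id])
            for o in counter_experiment
        ]
        assert classify_covariation_pattern(relabeled) == \
            classify_covariation_pattern(counter_experiment)

    def test_missing_home_flags_error(self, counter_experiment):
        import dataclasses

        unflagged = [
            dataclasses.replace(o, is_home=False) for o in counter_experiment
        ]
        with pytest.raises(ValueError, match="home"):
            classify_covariation_pattern(unflagged)
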