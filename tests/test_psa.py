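"""PSA: parameter sampling, draw instantiation, CEAC and CE summaries."""

import numpy as np
import pandas as pd
import pytest

from t2dcea.microsim import simulate_arms
from t2dcea.effects import EffectProfile
from t2dcea.psa import (
    ParameterDistribution,
    _profile_from_inputs,
    _sub_seed,
    ceac,
    instantiate_draw,
    plane_export,
    run_psa,
    sample_parameters,
    summarise_ce,
)
from t2dcea.synthdata import (
    BASE_EFFECT_INPUTS,
    default_cohort_generator,
    gen_psa_spec,
    toy_econ,
    toy_engine,
)


class TestSampling:
    def test_degenerate_normal_is_constant(self):
        spec = [ParameterDistribution("x", "normal", {"mean": 0.0, "sd": 0.0}, "cost")]
        table = sample_parameters(spec, 10, seed=1)
        assert (table["x"] == 0.0).all()

    def test_beta_moment(self):
        spec = [ParameterDistribution("p", "beta", {"a": 2.0, "b": 2.0}, "utility")]
        table = sample_parameters(spec, 100_000, seed=2)
        se = table["p"].std(ddof=1) / np.sqrt(len(table))
        assert table["p"].mean() == pytest.approx(0.5, abs=3 * se)

    def test_same_seed_identical_tables(self):
        spec = gen_psa_spec()
        a = sample_parameters(spec, 50, seed=7)
        b = sample_parameters(spec, 50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_multivariate_block_drawn_jointly(self):
        spec = [
            ParameterDistribution(
                "block",
                "multivariate_normal",
                {
                    "mean": [0.0, 0.0],
                    "cov": [[1.0, 0.95], [0.95, 1.0]],
                    "names": ["u", "v"],
                    "targets": ["econ.management_cost", "econ.utility_intercept"],
                },
                "cost",
            )
        ]
        table = sample_parameters(spec, 5000, seed=3)
        assert np.corrcoef(table["u"], table["v"])[0, 1] > 0.9

    def test_invalid_hyperparameters_fail_at_spec_time(self):
        with pytest.raises(ValueError):
            ParameterDistribution("p", "beta", {"a": -1.0, "b": 2.0}, "utility")
        with pytest.raises(ValueError):
            ParameterDistribution("x", "gamma", {"shape": 0.0, "scale": 1.0}, "cost")
        with pytest.raises(ValueError):
            ParameterDistribution(
                "m", "multivariate_normal",
                {"mean": [0, 0], "cov": [[1, 2], [2, 1]], "names": ["a", "b"],
                 "targets": [None, None]},
                "cost",
            )

    def test_draw_indices_contiguous(self):
        table = sample_parameters(gen_psa_spec(), 25, seed=1)
        assert list(table["draw"]) == list(range(25))


class TestInstantiation:
    def test_targets_reach_engine_econ_and_effects(self):
        spec = gen_psa_spec()
        row = sample_parameters(spec, 1, seed=5).iloc[0]
        engine, econ, eff = instantiate_draw(
            row, spec, toy_engine("low"), toy_econ(), BASE_EFFECT_INPUTS
        )
        assert engine.events["mi"].intercept == pytest.approx(row["mi_intercept"])
        assert econ.management_cost == pytest.approx(row["management_cost"])
        assert eff["hba1c_year1"] == pytest.approx(row["hba1c_year1"])

    def test_templates_not_mutated(self):
        spec = gen_psa_spec()
        engine = toy_engine("low")
        econ = toy_econ()
        before = engine.to_dict()
        row = sample_parameters(spec, 1, seed=6).iloc[0]
        instantiate_draw(row, spec, engine, econ, BASE_EFFECT_INPUTS)
        assert engine.to_dict() == before
        assert econ.management_cost == 500.0


class TestRunPsa:
    def test_degenerate_spec_collapses_to_deterministic_run(self):
        # all-degenerate distributions: one PSA draw equals a plain two-arm run
        spec = [
            ParameterDistribution(
                "hba1c_year1", "normal",
                {"mean": BASE_EFFECT_INPUTS["hba1c_year1"], "sd": 0.0},
                "effectiveness", "effects.hba1c_year1",
            )
        ]
        engine = toy_engine("low")
        econ = toy_econ()
        gen = default_cohort_generator()
        seed = 13
        samples = run_psa(
            spec, gen, engine, BASE_EFFECT_INPUTS, econ,
            intervention_cost_per_patient=0.52, n_outer=1, n_inner=100, seed=seed,
        )
        cohort = gen(100, _sub_seed(seed, 1, 0))
        profile = _profile_from_inputs(BASE_EFFECT_INPUTS, 40)
        direct = simulate_arms(
            cohort, engine, EffectProfile.zero(40), profile, econ,
            intervention_cost_per_patient=0.52, seed=_sub_seed(seed, 2, 0),
        )
        assert samples["delta_cost"].iloc[0] == pytest.approx(direct.delta_cost)
        assert samples["delta_qalys"].iloc[0] == pytest.approx(direct.delta_qalys)

    def test_zero_effect_zero_cost_null(self):
        spec = [
            ParameterDistribution(
                "hba1c_year1", "normal", {"mean": 0.0, "sd": 0.0},
                "effectiveness", "effects.hba1c_year1",
            )
        ]
        eff = {k: 0.0 for k in BASE_EFFECT_INPUTS}
        samples = run_psa(
            spec, default_cohort_generator(), toy_engine("low"), eff, toy_econ(),
            n_outer=3, n_inner=50, seed=2,
        )
        assert (samples["delta_cost"] == 0.0).all()
        assert (samples["delta_qalys"] == 0.0).all()


class TestCeac:
    def test_all_saving_draws_probability_one(self):
        samples = pd.DataFrame({"delta_cost": [-1.0] * 4, "delta_qalys": [0.0] * 4})
        table = ceac(samples, [0, 20_000, 1e6])
        assert (table["probability"] == 1.0).all()

    def test_enumerated_split(self):
        samples = pd.DataFrame(
            {"delta_cost": [10.0, 10.0], "delta_qalys": [0.001, 0.0001]}
        )
        table = ceac(samples, [20_000])
        assert table["probability"].iloc[0] == 0.5

    def test_threshold_zero_counts_cost_saving_draws(self):
        samples = pd.DataFrame(
            {"delta_cost": [-1.0, 0.0, 2.0], "delta_qalys": [0.0, 1.0, 1.0]}
        )
        assert ceac(samples, [0.0])["probability"].iloc[0] == pytest.approx(1 / 3)

    def test_ties_count_against_intervention(self):
        samples = pd.DataFrame({"delta_cost": [20.0], "delta_qalys": [0.001]})
        assert ceac(samples, [20_000])["probability"].iloc[0] == 0.0

    def test_limit_is_fraction_with_positive_qaly_gain(self):
        rng = np.random.default_rng(4)
        samples = pd.DataFrame(
            {"delta_cost": rng.normal(0, 50, 400), "delta_qalys": rng.normal(0, 0.01, 400)}
        )
        frac_positive = (samples["delta_qalys"] > 0).mean()
        assert ceac(samples, [1e12])["probability"].iloc[0] == pytest.approx(frac_positive)


class TestSummary:
    def test_icer_from_mean_increments(self):
        samples = pd.DataFrame({"delta_cost": [48.19], "delta_qalys": [0.0058]})
        result = summarise_ce(samples)
        assert result.icer == pytest.approx(8308.6, abs=0.05)

    def test_probability_matches_ceac_exactly(self):
        rng = np.random.default_rng(8)
        samples = pd.DataFrame(
            {"delta_cost": rng.normal(0, 50, 300), "delta_qalys": rng.normal(0, 0.01, 300)}
        )
        result = summarise_ce(samples, threshold=20_000)
        assert result.probability_cost_effective == ceac(samples, [20_000])["probability"].iloc[0]

    def test_invariant_to_order_and_duplication(self):
        samples = pd.DataFrame(
            {"delta_cost": [10.0, -5.0, 3.0], "delta_qalys": [0.002, 0.001, -0.0005]}
        )
        shuffled = samples.sample(frac=1.0, random_state=0)
        doubled = pd.concat([samples, samples], ignore_index=True)
        base = summarise_ce(samples)
        assert summarise_ce(shuffled).icer == pytest.approx(base.icer)
        assert summarise_ce(doubled).icer == pytest.approx(base.icer)

    def test_zero_mean_qaly_guard(self):
        samples = pd.DataFrame({"delta_cost": [1.0, 1.0], "delta_qalys": [0.001, -0.001]})
        result = summarise_ce(samples)
        assert result.icer is None
        assert "equal QALYs" in result.label


class TestPlaneExport:
    def test_round_trip(self, tmp_path):
        samples = pd.DataFrame(
            {"delta_cost": [1.0, -2.0, 3.0], "delta_qalys": [0.01, -0.02, 0.03]}
        )
        path = tmp_path / "plane.csv"
        written = plane_export(samples, path, scenario_points={"S1": (0.0014, -4.06)})
        read = pd.read_csv(path)
        assert len(read) == 4
        pd.testing.assert_frame_equal(read, written)
        # quadrant counts preserved
        assert ((read["delta_cost"] < 0) & (read["label"] == "psa_draw")).sum() == 1
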