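"""KS objective, variant fits, information weights and model selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftgaze.fitting import (
    FitOptions,
    _objective_factory,
    _pack,
    _prepare_data,
    fit_all_variants,
    fit_variant,
    information_weights,
    ks_statistic,
    ml_objective,
    select_model,
    trim_outliers,
)
from driftgaze.params import CONDITIONS, DDMParams, VariantSpec, all_variants
from driftgaze.wiener import SignedRTPrediction


def inverse_cdf_sample(pred, q):
    """Quantiles of a signed-RT prediction via dense grid inversion."""
    grid = np.linspace(-6, 8, 20001)
    F = pred.cdf(grid)
    return np.interp(q, F, grid)


class TestKSStatistic:
    def test_sample_at_predicted_quantiles_has_minimal_distance(self, default_params):
        pred = SignedRTPrediction(default_params)
        n = 199
        sample = inverse_cdf_sample(pred, np.arange(1, n + 1) / (n + 1))
        ks = ks_statistic(sample, default_params)
        assert ks <= 1 / (n + 1) + 5e-3

    def test_large_sample_from_prediction_stays_below_dkw_band(self, default_params, rng):
        pred = SignedRTPrediction(default_params)
        sample = inverse_cdf_sample(pred, rng.uniform(size=10_000))
        assert ks_statistic(sample, default_params) < 0.025

    def test_two_trial_hand_case_matches_enumeration(self):
        # face @ 0.4 s -> +0.4, noise @ 0.3 s -> -0.3 against a symmetric
        # driftless prediction; enumerate the four jump sides by hand
        params = DDMParams(a=1.0, zr=0.5, v=0.0)
        pred = SignedRTPrediction(params)
        xs = np.array([-0.3, 0.4])
        expected = max(
            abs(pred.cdf(-0.3) - 0.0), abs(pred.cdf(-0.3) - 0.5),
            abs(pred.cdf(0.4) - 0.5), abs(pred.cdf(0.4) - 1.0),
        )
        trials = pd.DataFrame(
            {"choice": ["noise", "face"], "fixation_duration_ms": [300.0, 400.0]}
        )
        assert ks_statistic(trials, params) == pytest.approx(expected, abs=1e-12)
        assert ks_statistic(xs, params) == pytest.approx(expected, abs=1e-12)

    def test_empty_trials_rejected(self, default_params):
        with pytest.raises(ValueError):
            ks_statistic(np.array([]), default_params)


class TestInformationWeights:
    def test_equal_bics_give_uniform_weights(self):
        w = information_weights([100.0] * 8)
        assert np.allclose(w, 0.125)

    def test_two_model_example(self):
        w = information_weights([0.0, 2.0])
        assert w == pytest.approx([0.7310585786, 0.2689414214], abs=1e-9)

    @given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=8), st.floats(-1e4, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_range_normalisation_and_shift_invariance(self, bics, shift):
        w = information_weights(bics)
        assert np.all(w >= 0) and np.all(w <= 1)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(w, information_weights(np.asarray(bics) + shift), atol=1e-9)


class TestModelSelection:
    def test_highest_mean_weight_wins(self):
        names = [v.name for v in all_variants()]
        table = pd.DataFrame([{n: 0.0 for n in names}])
        table.loc[0, "v+t0"] = 1.0
        winner, mean_w = select_model(table)
        assert winner.free == frozenset({"v", "t0"})
        assert mean_w["v+t0"] == 1.0

    def test_exact_tie_breaks_toward_fewer_parameters(self):
        names = [v.name for v in all_variants()]
        table = pd.DataFrame([{n: 0.125 for n in names}])
        winner, _ = select_model(table)
        assert winner.free == frozenset()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_model(pd.DataFrame())


class TestTrimOutliers:
    def test_zero_fraction_is_identity(self, small_session):
        trimmed, log = trim_outliers(small_session.trials, 0.0)
        assert len(trimmed) == small_session.n_trials
        assert log.empty

    def test_five_percent_on_100_trials_leaves_96(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "participant_id": "P1",
                "inspection_identity": "face",
                "preview": "preview",
                "condition": "FP",
                "choice": "face",
                "fixation_duration_ms": rng.uniform(200, 900, 100),
            }
        )
        trimmed, log = trim_outliers(df, 0.05)
        assert len(trimmed) == 96  # floor(2.5) = 2 per tail
        assert len(log) == 4
        # removed trials are the extremes
        kept = trimmed["fixation_duration_ms"]
        assert log["fixation_duration_ms"].min() < kept.min()
        assert log["fixation_duration_ms"].max() > kept.max()

    def test_invalid_fraction_rejected(self, small_session):
        with pytest.raises(ValueError):
            trim_outliers(small_session.trials, 0.6)


@pytest.fixture(scope="module")
def one_participant(small_session):
    return small_session.for_participant(small_session.participants[0])


@pytest.fixture(scope="module")
def recovery_session():
    from driftgaze.synth import SyntheticConfig, generate_session

    return generate_session(SyntheticConfig(n_participants=1, seed=77))


@pytest.fixture(scope="module")
def family_fits(one_participant, fast_fit_options):
    return fit_all_variants(one_participant, fast_fit_options)


class TestVariantFits:
    def test_fit_is_deterministic_under_fixed_seed(self, one_participant, fast_fit_options):
        variant = VariantSpec(frozenset({"v"}))
        a = fit_variant(one_participant, variant, fast_fit_options)
        b = fit_variant(one_participant, variant, fast_fit_options)
        assert a.params_by_condition == b.params_by_condition
        assert a.objective == b.objective
        assert a.bic == b.bic

    def test_objective_prefers_truth_over_perturbed_truth(self, recovery_session, fast_fit_options):
        trials = recovery_session.for_participant("P01")
        truth = {
            c: DDMParams(**recovery_session.metadata["true_params"]["P01"][c])
            for c in CONDITIONS
        }
        variant = VariantSpec(frozenset({"v", "t0"}))
        data = _prepare_data(trials, 40)
        objective = _objective_factory(data, variant, fast_fit_options)
        from dataclasses import replace

        perturbed = {c: replace(p, v=p.v + 0.5) for c, p in truth.items()}
        assert objective(_pack(truth, variant)) <= objective(_pack(perturbed, variant))

    def test_trial_floor_enforced(self, one_participant, fast_fit_options):
        from dataclasses import replace as dc_replace

        opts = FitOptions(**{**vars(fast_fit_options), "trial_floor": 10_000})
        with pytest.raises(ValueError, match="trial_floor"):
            fit_variant(one_participant, VariantSpec(frozenset()), opts)

    def test_family_returns_all_eight_variants(self, family_fits):
        assert set(family_fits) == {v.name for v in all_variants()}
        for fit in family_fits.values():
            assert fit.bic == pytest.approx(
                -2 * fit.log_likelihood + fit.k * np.log(fit.n_trials)
            )

    def test_nesting_monotonicity_of_best_objectives(self, family_fits):
        by_name = {v.name: v for v in all_variants()}
        for rich_name, rich in family_fits.items():
            for poor_name, poor in family_fits.items():
                if by_name[rich_name].nests(by_name[poor_name]):
                    assert rich.objective <= poor.objective + 5e-3

    def test_shared_parameters_identical_across_conditions(self, family_fits):
        fit = family_fits["v+t0"]
        ref = fit.params_by_condition["FP"]
        for c in CONDITIONS[1:]:
            p = fit.params_by_condition[c]
            assert (p.a, p.zr, p.sv, p.sz, p.st0) == (ref.a, ref.zr, ref.sv, ref.sz, ref.st0)


class TestMLObjective:
    def test_fast_guess_trial_gives_infinite_nll(self, default_params):
        trials = pd.DataFrame(
            {
                "participant_id": "P1",
                "condition": ["FP"],
                "choice": ["face"],
                # faster than t0 - st0/2 = 168 ms
                "fixation_duration_ms": [100.0],
            }
        )
        params = {c: default_params for c in CONDITIONS}
        assert ml_objective(trials, params) == np.inf

    def test_likelihood_prefers_truth_over_perturbation(self, small_session):
        pid = small_session.participants[0]
        trials = small_session.for_participant(pid)
        truth = {
            c: DDMParams(**small_session.metadata["true_params"][pid][c])
            for c in CONDITIONS
        }
        from dataclasses import replace

        perturbed = {c: replace(p, v=p.v + 0.8) for c, p in truth.items()}
        assert ml_objective(trials, truth) < ml_objective(trials, perturbed)


class TestRecovery:
    def test_single_participant_recovery_is_unbiased_enough(self, recovery_session, fast_fit_options):
        sess = recovery_session
        trials = sess.for_participant("P01")
        fit = fit_variant(trials, VariantSpec(frozenset({"v", "t0"})), fast_fit_options)
        truth = sess.metadata["true_params"]["P01"]
        v_err = np.mean(
            [abs(fit.params_by_condition[c].v - truth[c]["v"]) for c in CONDITIONS]
        )
        t0_err = np.mean(
            [abs(fit.params_by_condition[c].t0 - truth[c]["t0"]) for c in CONDITIONS]
        )
        assert v_err < 0.35
        assert t0_err < 0.035

    def test_refit_after_trimming_moves_drift_little(self, small_session, fast_fit_options):
        pid = small_session.participants[1]
        trials = small_session.for_participant(pid)
        variant = VariantSpec(frozenset({"v", "t0"}))
        full = fit_variant(trials, variant, fast_fit_options)
        trimmed, _ = trim_outliers(trials, 0.05)
        refit = fit_variant(trimmed, variant, fast_fit_options)
        shift = np.mean(
            [
                abs(full.params_by_condition[c].v - refit.params_by_condition[c].v)
                for c in CONDITIONS
            ]
        )
        assert shift < 0.15
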