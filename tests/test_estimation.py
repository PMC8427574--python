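"""Endpoints, Kaplan-Meier, chi-square, exact binomial CI, survey summary."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import symvert as sv


class TestEndpointEvents:
    def test_combined_counts_both_failure_modes(self, toy_survival_frame):
        times, event = sv.endpoint_events(toy_survival_frame, "combined")
        assert event.sum() == 5  # 3 uncaring + 2 foundress deaths
        assert list(times) == [3, 5, 8, 10, 12, 15]

    def test_uncaring_only_censors_foundress_deaths(self, toy_survival_frame):
        _, event = sv.endpoint_events(toy_survival_frame, "uncaring_only")
        assert event.sum() == 3
        dead = toy_survival_frame["garden_outcome"] == "foundress_dead"
        assert not event[dead.to_numpy()].any()

    def test_all_censored_means_zero_events(self, toy_survival_frame):
        df = toy_survival_frame.assign(garden_outcome="censored",
                                       foundress_died=False)
        for definition in ("combined", "uncaring_only"):
            _, event = sv.endpoint_events(df, definition)
            assert event.sum() == 0

    def test_event_count_matches_constructed_tally(self, default_experiment):
        _, event = sv.endpoint_events(default_experiment, "combined")
        tally = default_experiment["garden_outcome"].isin(
            ["uncaring", "foundress_dead"]).sum()
        assert event.sum() == tally

    def test_unknown_definition_rejected(self, toy_survival_frame):
        with pytest.raises(ValueError, match="definition"):
            sv.endpoint_events(toy_survival_frame, "all_of_them")

    def test_empty_records_rejected(self, toy_survival_frame):
        with pytest.raises(ValueError):
            sv.endpoint_events(toy_survival_frame.iloc[:0], "combined")


def naive_km(times, events):
    """Day-by-day product-limit oracle."""
    days = sorted(set(times[events]))
    surv, out = 1.0, {}
    for u in days:
        at_risk = (times >= u).sum()
        d = ((times == u) & events).sum()
        surv *= 1.0 - d / at_risk
        out[u] = surv
    return out


class TestKaplanMeier:
    def test_no_events_gives_flat_curve(self):
        curves = sv.km_survivorship([5.0, 6.0, 7.0], [False] * 3, ["a"] * 3)
        assert np.allclose(curves["a"]["survival"], 1.0)

    def test_two_subject_hand_computation(self):
        curves = sv.km_survivorship([1.0, 2.0], [True, True], ["a", "a"])
        c = curves["a"].set_index("day")["survival"]
        assert c.loc[1.0] == pytest.approx(0.5)
        assert c.loc[2.0] == pytest.approx(0.0)

    def test_matches_naive_product_oracle_with_censoring(self):
        rng = np.random.default_rng(17)
        times = np.ceil(rng.exponential(8.0, size=120))
        events = rng.random(120) < 0.7
        curves = sv.km_survivorship(times, events, np.zeros(120))
        oracle = naive_km(times, events)
        fitted = curves[0.0].set_index("day")["survival"]
        for day, s in oracle.items():
            assert fitted.loc[day] == pytest.approx(s, abs=1e-12)

    def test_curves_start_at_one_and_never_increase(self, default_experiment):
        t, e = sv.endpoint_events(default_experiment, "combined")
        curves = sv.km_survivorship(t, e, default_experiment["treatment"])
        for df in curves.values():
            s = df["survival"].to_numpy()
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            sv.km_survivorship([-1.0, 2.0], [True, True], ["a", "a"])


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        x2, df, p = sv.chi_square_2x2(10, 10, 10, 10, continuity_correction=False)
        assert x2 == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        x2, df, p = sv.chi_square_2x2(20, 10, 10, 20, continuity_correction=False)
        assert x2 == pytest.approx(20.0 / 3.0)
        assert p == pytest.approx(stats.chi2.sf(20.0 / 3.0, 1))

    def test_row_swap_symmetry(self):
        a = sv.chi_square_2x2(20, 10, 10, 20)
        b = sv.chi_square_2x2(10, 20, 20, 10)
        assert a == b

    def test_yates_correction_reduces_statistic(self):
        plain, _, _ = sv.chi_square_2x2(20, 10, 10, 20, continuity_correction=False)
        corrected, _, _ = sv.chi_square_2x2(20, 10, 10, 20)
        assert corrected < plain

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(ValueError, match="margin"):
            sv.chi_square_2x2(0, 0, 5, 10)


def brute_force_clopper_pearson(k, n, level=0.95):
    """Direct inversion of the binomial tails on a fine grid."""
    alpha = 1 - level
    grid = np.linspace(1e-9, 1 - 1e-9, 200_001)
    upper_tail = stats.binom.sf(k - 1, n, grid)   # P(X >= k)
    lower_tail = stats.binom.cdf(k, n, grid)      # P(X <= k)
    lo = 0.0 if k == 0 else grid[np.argmax(upper_tail >= alpha / 2)]
    hi = 1.0 if k == n else grid[len(grid) - 1 - np.argmax(lower_tail[::-1] >= alpha / 2)]
    return lo, hi


class TestProportionCI:
    def test_disturbance_proportion_reproduces_printed_interval(self):
        p_hat, lo, hi = sv.proportion_ci(60, 96, "clopper_pearson", 0.95)
        assert p_hat == pytest.approx(0.625)
        assert round(100 * lo, 1) == 52.0
        assert round(100 * hi, 1) == 72.2

    def test_zero_successes_pins_lower_bound(self):
        _, lo, _ = sv.proportion_ci(0, 10)
        assert lo == 0.0

    def test_matches_brute_force_tail_inversion(self):
        _, lo, hi = sv.proportion_ci(1, 10)
        blo, bhi = brute_force_clopper_pearson(1, 10)
        assert lo == pytest.approx(blo, abs=1e-4)
        assert hi == pytest.approx(bhi, abs=1e-4)

    @pytest.mark.parametrize("method", ["clopper_pearson", "wilson", "wald"])
    def test_bounds_bracket_estimate(self, method):
        p_hat, lo, hi = sv.proportion_ci(7, 20, method)
        assert 0.0 <= lo <= p_hat <= hi <= 1.0

    @pytest.mark.parametrize("k, n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_counts_rejected(self, k, n):
        with pytest.raises(ValueError):
            sv.proportion_ci(k, n)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            sv.proportion_ci(5, 10, method="jeffreys")


class TestSurveySummary:
    def test_printed_field_counts(self, printed_survey_frame):
        s = sv.survey_summary(printed_survey_frame)
        assert s["V_field"] == pytest.approx(8.0 / 11.0)
        assert round(100 * s["V_field"]) == 73
        assert s["J_max"] == pytest.approx(50.0 / 719.0)
        assert round(s["J_max"], 2) == 0.07

    def test_totals_are_conserved(self, printed_survey_frame):
        s = sv.survey_summary(printed_survey_frame)
        assert s["total_roaches"] == printed_survey_frame["alates_with_roach"].sum()
        assert s["total_alates"] == printed_survey_frame["alates_sampled"].sum()
        assert s["per_colony_prevalence"].sum() * 0 == 0  # finite

    def test_uninfected_survey(self, printed_survey_frame):
        df = printed_survey_frame.assign(alates_with_roach=0)
        s = sv.survey_summary(df)
        assert s["V_field"] == 0.0 and s["J_max"] == 0.0

    def test_zero_sample_colony_excluded_with_warning(self, printed_survey_frame):
        df = pd.concat([
            printed_survey_frame,
            pd.DataFrame([{"colony_id": "col12", "site": "bfl",
                           "alates_sampled": 0, "alates_with_roach": 0}]),
        ], ignore_index=True)
        with pytest.warns(UserWarning, match="zero sampled"):
            s = sv.survey_summary(df)
        assert s["n_colonies"] == 11

    def test_inconsistent_counts_rejected(self, printed_survey_frame):
        df = printed_survey_frame.copy()
        df.loc[0, "alates_with_roach"] = df.loc[0, "alates_sampled"] + 1
        with pytest.raises(ValueError):
            sv.survey_summary(df)


def test_csv_round_trip(tmp_path, default_experiment, printed_survey_frame):
    surv_path = tmp_path / "survival.csv"
    default_experiment.to_csv(surv_path, index=False)
    back = sv.read_survival_csv(surv_path)
    assert len(back) == len(default_experiment)
    fit = sv.fit_survival_experiment(back)
    assert np.isfinite(fit.log_hr)

    survey_path = tmp_path / "survey.csv"
    printed_survey_frame.to_csv(survey_path, index=False)
    s = sv.survey_summary(sv.read_survey_csv(survey_path))
    assert s["n_colonies"] == 11
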