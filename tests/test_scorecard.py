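"""Nine-facet validity scorecard assembly."""

import numpy as np
import pandas as pd
import pytest

from nutrivalid.agreement import bland_altman
from nutrivalid.cohort import CohortParams, ToolParams, generate_cohort_bundle
from nutrivalid.dlw import run_dlw
from nutrivalid.energy import compute_energy_norms
from nutrivalid.goldberg import classification_grid
from nutrivalid.scorecard import (
    NO_OVERESTIMATION,
    ValidityReport,
    build_scorecard,
    misreport_magnitudes,
    percentage_difference,
)


class TestPercentageDifference:
    def test_constant_ratio(self):
        tdee = np.array([2800.0, 3000.0, 3200.0])
        mean, sd = percentage_difference(0.75 * tdee, tdee)
        assert mean == pytest.approx(-25.0)
        assert sd == pytest.approx(0.0)

    def test_identity(self):
        tdee = np.array([2800.0, 3000.0])
        mean, _ = percentage_difference(tdee, tdee)
        assert mean == 0.0

    def test_symmetric_pair(self):
        tdee = np.array([3000.0, 3000.0])
        tdei = np.array([1500.0, 4500.0])
        mean, sd = percentage_difference(tdei, tdee)
        assert mean == pytest.approx(0.0)
        assert sd == pytest.approx(70.7, abs=0.1)

    def test_non_positive_reference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            percentage_difference(np.array([1.0]), np.array([0.0]))

    def test_mean_of_ratios_not_ratio_of_means(self):
        """Per-participant averaging differs from cohort-ratio arithmetic."""
        tdee = np.array([2000.0, 4000.0])
        tdei = np.array([1000.0, 4000.0])
        mean, _ = percentage_difference(tdei, tdee)
        assert mean == pytest.approx(-25.0)  # (-50% + 0%)/2
        ratio_of_means = 100 * (tdei.mean() - tdee.mean()) / tdee.mean()
        assert ratio_of_means == pytest.approx(-100 / 6, abs=0.01)


class TestMisreportMagnitudes:
    def test_two_sided_split(self):
        diffs = np.array([100.0, -200.0, -400.0])
        tdee = np.array([3000.0, 3000.0, 3000.0])
        out = misreport_magnitudes(diffs, tdee)
        assert out["over_kcal"] == pytest.approx(100.0)
        assert out["under_kcal"] == pytest.approx(-300.0)

    def test_all_negative_raises_the_sentinel(self):
        out = misreport_magnitudes(
            np.array([-100.0, -200.0]), np.array([3000.0, 3000.0])
        )
        assert out["over_kcal"] == NO_OVERESTIMATION
        assert out["under_kcal"] == pytest.approx(-150.0)

    def test_all_zero(self):
        out = misreport_magnitudes(np.zeros(3), np.full(3, 3000.0))
        assert out["over_kcal"] == 0.0
        assert out["under_kcal"] == 0.0

    def test_subsets_partition_nonzero_diffs(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0, 500, 50)
        tdee = np.full(50, 3000.0)
        out = misreport_magnitudes(diffs, tdee)
        n_over = (diffs > 0).sum()
        n_under = (diffs < 0).sum()
        assert n_over + n_under == 50
        total = out["over_kcal"] * n_over + out["under_kcal"] * n_under
        assert total == pytest.approx(diffs.sum())


def _full_scorecard(params):
    bundle = generate_cohort_bundle(params)
    tdee = run_dlw(bundle.isotope_samples, bundle.doses).set_index(
        "participant_id"
    )["tdee_kcal_day"]
    norms = compute_energy_norms(bundle.participants, tdee=tdee)
    norms["ree_device_kcal"] = (
        bundle.participants.set_index("participant_id")["ree_device_kcal"]
        .reindex(norms["participant_id"])
        .to_numpy()
    )
    grid = classification_grid(norms, bundle.intake)
    parts = bundle.participants.set_index("participant_id")
    app_daily = bundle.intake[bundle.intake["tool"] == "app"]
    tdei = app_daily.groupby("participant_id")["energy_kcal"].mean()
    report = build_scorecard(
        tdei=tdei,
        tdee=tdee,
        daily_intake=app_daily,
        ffm=parts["ffm_kg"],
        weight_change_kg=parts["weight_day8_kg"] - parts["weight_day1_kg"],
        goldberg_grid=grid,
        tool="app",
    )
    return report, tdei, tdee


class TestBuildScorecard:
    def test_biased_cohort_recovers_construction_percentage(self):
        """Facet 3 mean % difference within 3 SE of the built-in -25% bias."""
        params = CohortParams(n_participants=200, seed=31, isotope_noise_sd_ppm=0.0)
        report, tdei, tdee = _full_scorecard(params)
        acc = report.facets["accuracy"]
        se = acc["sd_pct_diff"] / np.sqrt(len(tdei))
        assert abs(acc["mean_pct_diff"] - (-25.0)) < 3 * se

    def test_identity_cohort_scores_perfectly(self):
        """Zero-noise zero-bias cohort: no bias, all plausible, ICC 1.

        TDEE keeps a small between-person spread (2% CV): the stability ICC
        needs between-person variance to be defined, while the spread stays
        well inside the Goldberg plausibility band.
        """
        tools = (ToolParams("app", 0.0, 0.0, 0.0, 5.0),)
        params = CohortParams(
            n_participants=8,
            seed=33,
            isotope_noise_sd_ppm=0.0,
            weight_sd_kg=0.0,
            height_sd_m=0.0,
            age_sd_y=0.0,
            tdee_sd_kcal=60.0,
            body_fat_frac_sd=0.0,
            ndno_sd=0.0,
            tools=tools,
        )
        report, _, _ = _full_scorecard(params)
        assert report.facets["agreement"]["bias_kcal"] == pytest.approx(0.0, abs=1e-6)
        gb = report.facets["misreporting_goldberg"]
        assert gb["n_plausible"] == 8
        assert report.facets["diet_stability"]["icc"] == pytest.approx(1.0)

    def test_daywise_iid_reporting_noise_kills_stability(self):
        """Pure within-person noise, no person effect: stability ICC near 0."""
        tools = (ToolParams("app", -0.25, 40.0, 0.0, 5.0),)
        params = CohortParams(
            n_participants=100,
            seed=35,
            tdee_sd_kcal=0.0,
            weight_sd_kg=0.0,
            height_sd_m=0.0,
            age_sd_y=0.0,
            body_fat_frac_sd=0.0,
            tools=tools,
        )
        report, _, _ = _full_scorecard(params)
        assert abs(report.facets["diet_stability"]["icc"]) < 0.1

    def test_facet1_equals_agreement_module_bit_for_bit(self, study_bundle):
        tdee = run_dlw(
            study_bundle.isotope_samples, study_bundle.doses
        ).set_index("participant_id")["tdee_kcal_day"]
        app = study_bundle.intake[study_bundle.intake["tool"] == "app"]
        tdei = app.groupby("participant_id")["energy_kcal"].mean()
        report = build_scorecard(tdei=tdei, tdee=tdee, tool="app")
        direct = bland_altman(tdei.to_numpy(), tdee.reindex(tdei.index).to_numpy())
        f1 = report.facets["agreement"]
        assert f1["bias_kcal"] == direct.bias
        assert f1["loa_lower"] == direct.loa[0]
        assert f1["loa_upper"] == direct.loa[1]
        assert f1["se_bias"] == direct.se_bias

    def test_missing_inputs_drop_facets_not_the_report(self, study_bundle):
        tdee = run_dlw(
            study_bundle.isotope_samples, study_bundle.doses
        ).set_index("participant_id")["tdee_kcal_day"]
        app = study_bundle.intake[study_bundle.intake["tool"] == "app"]
        tdei = app.groupby("participant_id")["energy_kcal"].mean()
        report = build_scorecard(tdei=tdei, tdee=tdee, tool="app")
        assert "agreement" in report.facets
        assert "homoeostatic_control" not in report.facets
        assert "diet_stability" not in report.facets

    def test_csv_round_trip(self, tmp_path, study_bundle):
        tdee = run_dlw(
            study_bundle.isotope_samples, study_bundle.doses
        ).set_index("participant_id")["tdee_kcal_day"]
        app = study_bundle.intake[study_bundle.intake["tool"] == "app"]
        tdei = app.groupby("participant_id")["energy_kcal"].mean()
        report = build_scorecard(
            tdei=tdei, tdee=tdee, daily_intake=app, tool="app"
        )
        path = tmp_path / "scorecard.csv"
        report.to_frame().to_csv(path, index=False)
        back = ValidityReport.from_frame(pd.read_csv(path))
        assert back.tool == report.tool
        for facet, metrics in report.facets.items():
            for metric, value in metrics.items():
                if isinstance(value, float):
                    assert back.facets[facet][metric] == pytest.approx(value)
                else:
                    assert back.facets[facet][metric] == value

    def test_render_lists_all_nine_facets(self, study_bundle):
        tdee = run_dlw(
            study_bundle.isotope_samples, study_bundle.doses
        ).set_index("participant_id")["tdee_kcal_day"]
        app = study_bundle.intake[study_bundle.intake["tool"] == "app"]
        tdei = app.groupby("participant_id")["energy_kcal"].mean()
        report = build_scorecard(tdei=tdei, tdee=tdee, tool="app")
        text = report.render()
        for i in range(1, 10):
            assert f"({i})" in text
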