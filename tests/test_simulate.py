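import numpy as np
import pandas as pd
import pytest

from dynrisk.datasets import ConfigurationError, ScenarioConfig, ValidationError
from dynrisk.simulate import (
    DEFAULT_GROUP_SIZES,
    DEFAULT_SLOPE_LEVELS,
    DEFAULT_VARIANCE_LEVELS,
    build_scenario_grid,
    draw_case_event_times,
    simulate_cohort,
    simulate_dataset,
    simulate_joint_law,
    truncated_event_mean,
    truncate_followup,
    visit_times,
)


class TestScenarioConfig:
    def test_defaults_valid(self):
        cfg = ScenarioConfig()
        assert cfg.event_mean == 18.0
        assert cfg.intercept_mean == 6.0
        assert cfg.rand_int_sd == 0.1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_per_group": 0},
            {"n_visits": 1},
            {"followup_span": 25.0},          # > event_mean
            {"event_mean": 21.0},             # > study_end
            {"resid_sd": 0.0},
            {"rand_int_sd": -0.1},
            {"slope_coef": -0.01},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(**kwargs)


class TestScenarioGrid:
    def test_default_grid_has_45_cells(self):
        assert len(build_scenario_grid()) == 45

    def test_singleton_grid(self):
        grid = build_scenario_grid([1.0], [0.05], [10])
        assert len(grid) == 1
        assert grid[0].resid_sd == 1.0 and grid[0].n_per_group == 10

    def test_documented_order(self):
        # variance outer, slope middle, size inner: enumerate by hand
        grid = build_scenario_grid([0.5], [0.0, 0.1], [10, 50])
        cells = [(g.resid_sd, g.slope_coef, g.n_per_group) for g in grid]
        assert cells == [(0.5, 0.0, 10), (0.5, 0.0, 50), (0.5, 0.1, 10), (0.5, 0.1, 50)]

    def test_empty_axis_rejected(self):
        with pytest.raises(ConfigurationError):
            build_scenario_grid([], [0.1], [10])

    def test_default_levels_match_protocol(self):
        assert DEFAULT_VARIANCE_LEVELS == (0.5, 1.0, 1.5)
        assert DEFAULT_SLOPE_LEVELS == (0.0, 0.025, 0.05, 0.075, 0.1)
        assert DEFAULT_GROUP_SIZES == (10, 50, 1000)


class TestSimulateDataset:
    def test_shapes_default_scenario(self):
        data = simulate_dataset(ScenarioConfig(), seed=0)
        assert len(data.measurements) == 1000     # 100 subjects x 10 visits
        assert data.n_subjects == 100
        per_subject = data.measurements.groupby("subject_id")["time"].nunique()
        assert (per_subject == 10).all()

    def test_degenerate_noise_gives_constant_values(self):
        cfg = ScenarioConfig(n_per_group=3, slope_coef=0.0, resid_sd=1e-12,
                             rand_int_sd=0.0)
        data = simulate_dataset(cfg, seed=5)
        assert np.allclose(data.measurements["value"], cfg.intercept_mean, atol=1e-9)

    def test_event_time_mean_matches_truncnorm_oracle(self):
        cfg = ScenarioConfig()
        rng = np.random.default_rng(42)
        draws = draw_case_event_times(10_000, cfg, rng)
        oracle = truncated_event_mean(cfg)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - oracle) < 3 * se
        assert draws.min() > cfg.followup_span and draws.max() <= cfg.study_end

    def test_case_events_in_window_controls_censored(self):
        data = simulate_dataset(ScenarioConfig(n_per_group=50), seed=2)
        subj = data.subjects
        cases = subj[subj["group"] == "case"]
        ctrls = subj[subj["group"] == "control"]
        assert (cases["status"] == 1).all()
        assert ((cases["event_time"] > 15) & (cases["event_time"] <= 20)).all()
        assert (ctrls["status"] == 0).all()
        assert (ctrls["event_time"] == 20.0).all()

    def test_determinism_byte_identical(self):
        cfg = ScenarioConfig(n_per_group=5)
        a = simulate_dataset(cfg, seed=9)
        b = simulate_dataset(cfg, seed=9)
        assert a.measurements.equals(b.measurements)
        assert a.subjects.equals(b.subjects)

    def test_different_seeds_differ(self):
        cfg = ScenarioConfig(n_per_group=5)
        a = simulate_dataset(cfg, seed=9)
        b = simulate_dataset(cfg, seed=10)
        assert not a.measurements["value"].equals(b.measurements["value"])

    def test_validates(self):
        simulate_dataset(ScenarioConfig(n_per_group=10), seed=1).validate()

    def test_group_slopes_recovered_by_ols(self):
        # per-group OLS slope within 3 SE of +/- slope_coef at large n
        cfg = ScenarioConfig(n_per_group=1000, slope_coef=0.1, resid_sd=0.5)
        data = simulate_dataset(cfg, seed=21)
        merged = data.measurements.merge(data.subjects, on="subject_id")
        for group, sign in [("case", 1.0), ("control", -1.0)]:
            sub = merged[merged["group"] == group]
            X = np.column_stack([np.ones(len(sub)), sub["time"]])
            coef, res_ss, *_ = np.linalg.lstsq(X, sub["value"], rcond=None)
            resid = sub["value"] - X @ coef
            xtx_inv = np.linalg.inv(X.T @ X)
            se = np.sqrt(resid.var(ddof=2) * xtx_inv[1, 1])
            assert abs(coef[1] - sign * cfg.slope_coef) < 3 * se

    def test_residual_sd_recovered(self):
        cfg = ScenarioConfig(n_per_group=1000, slope_coef=0.0, resid_sd=1.5,
                             rand_int_sd=0.0)
        data = simulate_dataset(cfg, seed=33)
        merged = data.measurements.merge(data.subjects, on="subject_id")
        sign = np.where(merged["group"] == "case", 1.0, -1.0)
        resid = merged["value"] - cfg.intercept_mean - sign * cfg.slope_coef * merged["time"]
        n = len(resid)
        se_of_sd = cfg.resid_sd / np.sqrt(2 * (n - 1))
        assert abs(resid.std(ddof=1) - cfg.resid_sd) < 3 * se_of_sd


class TestTruncateFollowup:
    def test_identity_at_full_span(self, small_scenario_data):
        out = truncate_followup(small_scenario_data, 15.0)
        assert out.measurements.equals(small_scenario_data.measurements)

    def test_idempotent(self, small_scenario_data):
        once = truncate_followup(small_scenario_data, 5.0)
        twice = truncate_followup(once, 5.0)
        assert once.measurements.equals(twice.measurements)

    def test_visit_count_at_horizon_5(self):
        # linspace(0, 15, 10) has spacing 5/3: times <= 5 are {0, 5/3, 10/3, 5}
        data = simulate_dataset(ScenarioConfig(n_per_group=4), seed=0)
        out = truncate_followup(data, 5.0)
        per_subject = out.measurements.groupby("subject_id").size()
        assert (per_subject == 4).all()

    def test_subjects_table_unchanged(self, small_scenario_data):
        out = truncate_followup(small_scenario_data, 5.0)
        assert out.subjects.equals(small_scenario_data.subjects)

    def test_empty_subject_flagged(self):
        data = simulate_dataset(ScenarioConfig(n_per_group=3), seed=0)
        # shift the first subject's visits later so a tiny horizon empties it
        sid = data.subjects["subject_id"].iloc[0]
        mask = data.measurements["subject_id"] == sid
        data.measurements.loc[mask, "time"] += 1.0
        out = truncate_followup(data, 0.5)
        assert sid in out.truth["flagged_empty"]

    def test_nonpositive_horizon_rejected(self, small_scenario_data):
        with pytest.raises(ValueError):
            truncate_followup(small_scenario_data, 0.0)


class TestVisitTimes:
    def test_inclusive_linspace(self):
        cfg = ScenarioConfig(n_visits=10, followup_span=15.0)
        t = visit_times(cfg)
        assert t[0] == 0.0 and t[-1] == 15.0 and len(t) == 10
        assert np.allclose(np.diff(t), 15.0 / 9)


class TestSimulateCohort:
    def test_counts_and_truth(self):
        data = simulate_cohort(n_cases=6, n_controls=5, n_features=8, n_assoc=3, seed=1)
        assert data.n_subjects == 11
        assert data.n_features == 8
        assert (data.subjects["status"] == 1).sum() == 6
        assert len(data.truth["assoc_features"]) == 3
        data.validate()

    def test_zero_assoc_all_null(self):
        data = simulate_cohort(n_cases=4, n_controls=4, n_features=5, n_assoc=0, seed=2)
        assert data.truth["assoc_features"] == []

    def test_assoc_exceeding_features_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_cohort(n_features=3, n_assoc=4)

    def test_determinism(self):
        a = simulate_cohort(n_cases=4, n_controls=4, n_features=6, n_assoc=2, seed=5)
        b = simulate_cohort(n_cases=4, n_controls=4, n_features=6, n_assoc=2, seed=5)
        assert a.measurements.equals(b.measurements)
        assert a.subjects.equals(b.subjects)
        assert a.features.equals(b.features)

    def test_case_onsets_near_target(self):
        data = simulate_cohort(n_cases=30, n_controls=5, n_features=1, n_assoc=0,
                               seed=8)
        onsets = data.subjects.loc[data.subjects["status"] == 1, "event_time"]
        assert 9.0 < onsets.mean() < 13.5

    def test_planted_features_pass_prefilter(self):
        data = simulate_cohort(n_cases=5, n_controls=5, n_features=20, n_assoc=4,
                               seed=9)
        feats = data.features.set_index("feature_id")
        for fid in data.truth["assoc_features"]:
            assert feats.loc[fid, "n_peptides"] >= 6
            assert feats.loc[fid, "n_missing"] <= 10

    def test_no_post_event_measurements(self):
        data = simulate_cohort(n_cases=6, n_controls=4, n_features=3, n_assoc=1, seed=4)
        data.validate()  # raises on post-event samples


class TestSimulateJointLaw:
    def test_shapes_and_determinism(self, joint_theta):
        a = simulate_joint_law(joint_theta, 20, np.linspace(0, 15, 6), 20.0, seed=3)
        b = simulate_joint_law(joint_theta, 20, np.linspace(0, 15, 6), 20.0, seed=3)
        assert a.n_subjects == 20
        assert a.measurements.equals(b.measurements)
        a.validate()

    def test_alpha_increases_event_rate(self):
        theta0 = {"beta": np.array([1.0, 0.0]), "D": np.diag([0.25, 0.01]),
                  "sigma2": 0.1, "log_kappa": 0.0, "log_lambda": np.log(0.01),
                  "alpha": 0.0}
        theta1 = dict(theta0, alpha=1.5)
        d0 = simulate_joint_law(theta0, 300, [0, 5, 10], 20.0, seed=6)
        d1 = simulate_joint_law(theta1, 300, [0, 5, 10], 20.0, seed=6)
        assert d1.subjects["status"].sum() > d0.subjects["status"].sum()


class TestValidation:
    def test_post_event_measurement_rejected(self):
        data = simulate_dataset(ScenarioConfig(n_per_group=3), seed=0)
        case_id = data.subjects.loc[data.subjects["status"] == 1, "subject_id"].iloc[0]
        extra = pd.DataFrame(
            {"subject_id": [case_id], "time": [25.0], "feature_id": ["feat_0"],
             "value": [6.0]}
        )
        data.measurements = pd.concat([data.measurements, extra], ignore_index=True)
        with pytest.raises(ValidationError, match="post-event"):
            data.validate()

    def test_unknown_subject_rejected(self):
        data = simulate_dataset(ScenarioConfig(n_per_group=3), seed=0)
        data.measurements.loc[0, "subject_id"] = "ghost"
        with pytest.raises(ValidationError, match="unknown subjects"):
            data.validate()
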