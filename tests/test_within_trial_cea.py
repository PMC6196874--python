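"""Within-trial evaluation: QALY AUC, costing, imputation, margins, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedometer_cea.synthetic_data import SyntheticConfig, TrialDataset, apply_missingness, generate_trial
from pedometer_cea.within_trial_cea import (
    Toggles,
    adjusted_means,
    aggregate_costs,
    bootstrap_incrementals,
    estimate_psych_utility_gain,
    impute,
    qaly_auc,
)


class TestQalyAUC:
    @pytest.mark.parametrize(
        "utilities, expected",
        [
            # published per-arm mean EQ-5D at 0 / 3 / 12 months
            ((0.837, 0.840, 0.833), 0.837),
            ((0.850, 0.847, 0.836), 0.843),
            ((0.849, 0.837, 0.831), 0.836),
        ],
    )
    def test_published_arm_trajectories(self, utilities, expected):
        assert round(qaly_auc([0.0, 0.25, 1.0], utilities), 3) == expected

    def test_constant_full_health_over_a_year(self):
        assert qaly_auc([0.0, 1.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_unordered_times_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            qaly_auc([0.0, 1.0, 0.25], [0.8, 0.8, 0.8])

    def test_utility_above_one_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            qaly_auc([0.0, 1.0], [0.9, 1.1])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        u=st.tuples(*[st.floats(0.0, 1.0)] * 3),
        c=st.floats(0.1, 0.9),
    )
    def test_linearity_and_constant_reduction(self, u, c):
        t = [0.0, 0.25, 1.0]
        a = qaly_auc(t, u)
        scaled = qaly_auc(t, [c * x for x in u])
        assert scaled == pytest.approx(c * a, abs=1e-12)
        assert qaly_auc(t, [c] * 3) == pytest.approx(c * 1.0)


def _cost_row(**kw):
    base = dict(
        cost_setup=0.0, cost_delivery_3=0.0, cost_delivery=0.0,
        cost_health_service_3=0.0, cost_health_service_12=0.0,
        cost_sae=0.0, cost_participant_3=0.0, cost_participant=0.0,
    )
    base.update(kw)
    return pd.DataFrame([base])


class TestCostAggregation:
    def test_nhs_12m_matches_published_postal_total(self):
        df = _cost_row(cost_setup=45.0, cost_delivery=10.0,
                       cost_health_service_3=100.0, cost_health_service_12=220.0)
        out = aggregate_costs(df, "nhs", "12m")
        assert out.loc[0, "total"] == pytest.approx(375.0)

    def test_all_zero(self):
        assert aggregate_costs(_cost_row(), "nhs", "12m").loc[0, "total"] == 0.0

    def test_participant_block_scaled_threefold(self):
        df = _cost_row(cost_participant=10.0)
        out = aggregate_costs(df, "nhs_plus_participant", "12m")
        assert out.loc[0, "participant"] == pytest.approx(30.0)
        assert out.loc[0, "total"] == pytest.approx(30.0)

    def test_intervention_only_drops_health_service_use(self):
        df = _cost_row(cost_setup=45.0, cost_delivery=10.0, cost_health_service_3=500.0)
        out = aggregate_costs(df, "intervention_only", "12m")
        assert out.loc[0, "total"] == pytest.approx(55.0)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            aggregate_costs(_cost_row(cost_delivery=-1.0), "nhs", "12m")

    def test_3m_horizon_uses_3m_blocks(self):
        df = _cost_row(cost_setup=105.0, cost_delivery_3=50.0, cost_delivery=52.0,
                       cost_health_service_3=95.0, cost_health_service_12=400.0)
        out = aggregate_costs(df, "nhs", "3m")
        assert out.loc[0, "total"] == pytest.approx(250.0)


class TestToggles:
    """Each deterministic sensitivity switch touches only its target."""

    def test_sae_costing_replaces_only_hsu(self):
        df = _cost_row(cost_setup=45.0, cost_delivery=10.0,
                       cost_health_service_3=100.0, cost_health_service_12=200.0,
                       cost_sae=77.0)
        base = aggregate_costs(df, "nhs", "12m")
        alt = aggregate_costs(df, "nhs", "12m", Toggles(sae_costing=True))
        assert alt.loc[0, "health_service_use"] == 77.0
        for col in ("setup", "delivery", "participant"):
            assert alt.loc[0, col] == base.loc[0, col]

    def test_pedometer_life_scales_only_setup(self):
        df = _cost_row(cost_setup=45.0, cost_delivery=10.0, cost_health_service_3=100.0)
        alt = aggregate_costs(df, "nhs", "12m", Toggles(pedometer_life_scale=0.5))
        assert alt.loc[0, "setup"] == 22.5
        assert alt.loc[0, "delivery"] == 10.0
        assert alt.loc[0, "health_service_use"] == 100.0

    def test_perspective_resolution(self):
        assert Toggles().perspective() == "nhs"
        assert Toggles(intervention_costs_only=True).perspective() == "intervention_only"
        assert Toggles(participant_perspective=True).perspective() == "nhs_plus_participant"

    def test_accelerometry_filter_and_complete_case_change_only_rows(self, small_trial):
        from pedometer_cea.within_trial_cea import _analysis_frame

        cfg = SyntheticConfig(n_per_arm=120, seed=11, missingness={"utility_12": 0.2})
        missing = apply_missingness(small_trial, cfg)
        full = _analysis_frame(missing, Toggles(include_all_randomised=True))
        filtered = _analysis_frame(missing, Toggles())
        cc = _analysis_frame(missing, Toggles(complete_case=True))
        assert len(full) == len(missing.data)
        assert len(filtered) == (missing.data["has_accelerometry"] == 1).sum()
        assert cc["utility_12"].notna().all()
        assert len(cc) < len(filtered)


class TestImputation:
    def test_low_missingness_mean_fill_preserves_arm_mean(self, small_trial):
        cfg = SyntheticConfig(n_per_arm=120, seed=11, missingness={"utility_12": 0.03})
        missing = apply_missingness(small_trial, cfg)
        completed = impute(missing, seed=0)
        assert len(completed) == 1
        comp = completed[0].data
        observed = missing.data
        for arm in ("control", "postal", "nurse"):
            obs_mean = observed.loc[observed["arm"] == arm, "utility_12"].mean()
            comp_mean = comp.loc[comp["arm"] == arm, "utility_12"].mean()
            assert comp_mean == pytest.approx(obs_mean, abs=1e-12)
        assert comp["utility_12"].notna().all()

    def test_no_missingness_returns_dataset_unchanged(self, small_trial):
        completed = impute(small_trial, seed=0)
        assert len(completed) == 1
        pd.testing.assert_frame_equal(completed[0].data, small_trial.data)

    def test_mice_recovers_truth_mean_under_mcar(self):
        cfg = SyntheticConfig(
            n_per_arm=250, seed=8, missingness={"cost_health_service_12": 0.2}
        )
        missing = apply_missingness(generate_trial(cfg), cfg)
        completed = impute(missing, m=5, seed=1)
        assert len(completed) == 5
        truth_mean = missing.truth["cost_health_service_12"].mean()
        imp_means = [d.data["cost_health_service_12"].mean() for d in completed]
        sd = missing.truth["cost_health_service_12"].std()
        se = sd / np.sqrt(len(missing.truth))
        assert abs(np.mean(imp_means) - truth_mean) < 4 * se

    def test_fully_missing_field_rejected(self, small_trial):
        cfg = SyntheticConfig(n_per_arm=120, seed=11, missingness={"mvpa_3": 1.0})
        missing = apply_missingness(small_trial, cfg)
        with pytest.raises(ValueError, match="entirely missing"):
            impute(missing)


class TestAdjustedMeans:
    def test_identical_arms_centre_on_zero(self):
        cfg = SyntheticConfig(n_per_arm=250, seed=6)
        ctrl = cfg.arms["control"]
        cfg.arms = {a: ctrl for a in ("control", "postal", "nurse")}
        ds = generate_trial(cfg)
        res = adjusted_means(ds, "qaly", seed=0)
        for comp, inc in res.incrementals.items():
            lo, hi = inc.ci_effect
            assert lo < 0 < hi, comp
            assert abs(inc.delta_effect) < 0.02

    def test_recovers_injected_arm_effect(self):
        """A +0.02 utility shift at 3 and 12 months in the postal arm is a
        +0.0175 QALY effect (trapezoid weights 0.5 and 0.375)."""
        cfg = SyntheticConfig(n_per_arm=400, seed=3)
        ctrl = cfg.arms["control"]
        ctrl.utility_mean = {"0": 0.75, "3": 0.75, "12": 0.74}
        ctrl.utility_sd = {"0": 0.10, "3": 0.10, "12": 0.10}
        import copy

        shifted = copy.deepcopy(ctrl)
        shifted.utility_mean = {"0": ctrl.utility_mean["0"],
                                "3": ctrl.utility_mean["3"] + 0.02,
                                "12": ctrl.utility_mean["12"] + 0.02}
        cfg.arms = {"control": ctrl, "postal": shifted, "nurse": copy.deepcopy(ctrl)}
        ds = generate_trial(cfg)
        res = adjusted_means(ds, "qaly", seed=0)
        inc = res.incrementals["postal_vs_control"]
        lo, hi = inc.ci_effect
        assert lo < 0.0175 < hi
        assert inc.delta_effect == pytest.approx(0.0175, abs=0.01)

    def test_adjustment_corrects_constructed_confounding(self):
        """With disease burden imbalanced across arms and driving costs,
        the covariate-adjusted incremental is closer to the true null than
        the raw difference of means."""
        rng = np.random.default_rng(42)
        n = 600
        rows = []
        for arm, lam in (("control", 2.5), ("postal", 0.8), ("nurse", 2.5)):
            disease = rng.poisson(lam, n)
            cost = rng.gamma(4.0, (150.0 + 120.0 * disease) / 4.0)
            for i, (d, c) in enumerate(zip(disease, cost)):
                rows.append(dict(
                    pid=len(rows), hid=len(rows), arm=arm,
                    age=int(rng.integers(45, 76)), sex=int(rng.random() < 0.5),
                    ethnicity_white=int(rng.random() < 0.8),
                    disease_count=int(d), has_accelerometry=1,
                    utility_0=0.8, utility_3=0.8, utility_12=0.8,
                    steps_0=7000.0, steps_3=7000.0, steps_12=7000.0,
                    mvpa_0=90.0, mvpa_3=90.0, mvpa_12=90.0,
                    cost_setup=0.0, cost_delivery_3=0.0, cost_delivery=0.0,
                    cost_health_service_3=float(c), cost_health_service_12=0.0,
                    cost_sae=0.0, cost_participant_3=0.0, cost_participant=0.0,
                ))
        ds = TrialDataset(data=pd.DataFrame(rows), seed=0, config_hash="test")
        raw = (
            aggregate_costs(ds.data[ds.data["arm"] == "postal"], "nhs", "12m")["total"].mean()
            - aggregate_costs(ds.data[ds.data["arm"] == "control"], "nhs", "12m")["total"].mean()
        )
        adj = adjusted_means(ds, "cost", seed=0).incrementals["postal_vs_control"].delta_cost
        assert abs(adj) < abs(raw)
        assert abs(adj) < 40.0  # truth is 0; raw bias is ~-200

    def test_standardisation_identity_on_null_model(self, small_trial):
        """Arm-share-weighted recycled-prediction means reproduce the
        observed overall mean for the identity-link model, and the mean
        fitted value equals the mean outcome for canonical-link families."""
        res = adjusted_means(small_trial, "steps", seed=0)
        df = small_trial.data[small_trial.data["has_accelerometry"] == 1]
        shares = df["arm"].value_counts(normalize=True)
        weighted = sum(res.arm_means[a] * shares[a] for a in shares.index)
        assert weighted == pytest.approx(df["steps_12"].mean(), rel=1e-6)

    def test_missing_outcome_rejected(self, small_trial):
        cfg = SyntheticConfig(n_per_arm=120, seed=11, missingness={"utility_12": 0.3})
        missing = apply_missingness(small_trial, cfg)
        with pytest.raises(ValueError, match="missing"):
            adjusted_means(missing, "qaly")


class TestBootstrap:
    def test_same_seed_reproduces_draws(self, small_trial):
        a = bootstrap_incrementals(small_trial, B=25, seed=5)
        b = bootstrap_incrementals(small_trial, B=25, seed=5)
        for comp in a.draws:
            np.testing.assert_array_equal(a.draws[comp], b.draws[comp])

    def test_degenerate_data_gives_identical_draws(self):
        rows = []
        for arm in ("control", "postal", "nurse"):
            for i in range(12):
                rows.append(dict(
                    pid=len(rows), hid=len(rows), arm=arm, age=60, sex=1,
                    ethnicity_white=1, disease_count=1, has_accelerometry=1,
                    utility_0=0.8, utility_3=0.8, utility_12=0.8,
                    steps_0=7000.0, steps_3=7000.0, steps_12=7000.0,
                    mvpa_0=90.0, mvpa_3=90.0, mvpa_12=90.0,
                    cost_setup={"control": 0.0, "postal": 45.0, "nurse": 105.0}[arm],
                    cost_delivery_3=0.0, cost_delivery=0.0,
                    cost_health_service_3=100.0, cost_health_service_12=200.0,
                    cost_sae=0.0, cost_participant_3=0.0, cost_participant=0.0,
                ))
        ds = TrialDataset(data=pd.DataFrame(rows), seed=0, config_hash="degenerate")
        boot = bootstrap_incrementals(ds, B=10, seed=3)
        for comp in boot.draws:
            assert np.allclose(boot.draws[comp], boot.draws[comp][0], atol=1e-6)

    def test_strong_dominance_concentrates_in_se_quadrant(self):
        cfg = SyntheticConfig(n_per_arm=150, seed=12)
        postal = cfg.arms["postal"]
        postal.cost_hsu_3 = (30.0, 20.0)
        postal.cost_hsu_4_12 = (60.0, 40.0)
        for t in ("3", "12"):
            postal.utility_mean[t] = 0.88
            postal.utility_sd[t] = 0.10
        ds = generate_trial(cfg)
        boot = bootstrap_incrementals(ds, B=80, seed=7)
        shares = boot.quadrant_shares("postal_vs_control")
        assert shares["SE"] >= 0.95

    def test_interval_width_shrinks_with_sample_size(self):
        def width(n, seed):
            ds = generate_trial(SyntheticConfig(n_per_arm=n, seed=seed))
            boot = bootstrap_incrementals(ds, B=60, seed=seed)
            d = boot.draws["postal_vs_control"][:, 0]
            return np.percentile(d, 97.5) - np.percentile(d, 2.5)

        w_small = np.mean([width(60, s) for s in (1, 2)])
        w_large = np.mean([width(240, s) for s in (1, 2)])
        ratio = w_small / w_large
        assert 1.25 < ratio < 3.5  # ~2 expected for a 4x sample-size increase

    def test_invalid_b_rejected(self, small_trial):
        with pytest.raises(ValueError, match="B"):
            bootstrap_incrementals(small_trial, B=0)


class TestPsychUtilityGain:
    def test_recovers_injected_activity_shift(self):
        cfg = SyntheticConfig(n_per_arm=500, seed=9, active_utility_shift=0.03)
        for arm_cfg in cfg.arms.values():  # keep utilities away from the cap at 1
            arm_cfg.utility_mean = {"0": 0.70, "3": 0.70, "12": 0.70}
            arm_cfg.utility_sd = {"0": 0.10, "3": 0.10, "12": 0.10}
        ds = generate_trial(cfg)
        est, (lo, hi) = estimate_psych_utility_gain(ds, seed=0)
        assert lo < 0.03 < hi
        assert est == pytest.approx(0.03, abs=0.015)

    def test_null_shift_centres_on_zero(self):
        cfg = SyntheticConfig(n_per_arm=500, seed=10)
        ds = generate_trial(cfg)
        est, (lo, hi) = estimate_psych_utility_gain(ds, seed=0)
        assert lo < 0.0 < hi

    def test_estimate_plumbs_into_markov_parameters(self, small_trial, markov_params):
        est, _ = estimate_psych_utility_gain(small_trial, n_draws=50, seed=0)
        markov_params.one_off_utility_gain = float(est)
        from pedometer_cea.markov_engine import accumulate, run_cohort

        res = accumulate(run_cohort(markov_params, "postal"), markov_params)
        assert np.isfinite(res.qaly_discounted)

    def test_no_active_participants_rejected(self):
        cfg = SyntheticConfig(n_per_arm=30, seed=2)
        ds = generate_trial(cfg)
        ds.data["mvpa_12"] = 50.0
        with pytest.raises(ValueError, match="active"):
            estimate_psych_utility_gain(ds)
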