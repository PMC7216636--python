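import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from dyadema import pipeline
from dyadema.accelerometry import Thresholds, classify_epochs, detect_non_wear
from dyadema.apim import ApimParams, build_design
from dyadema.simulate import (AffectParams, GeneratorConfig, MVPA_TRUTH,
                              SEDENTARY_TRUTH, affect_params_from_totals,
                              apply_missingness, generate_affect,
                              generate_schedule, generate_window_outcomes,
                              render_epoch_counts, simulate_recovery_dataset)
from dyadema.windows import SchedulingError, extract_window, pair_prompts


def one_day_config(m=4, c=3, **kw):
    return dataclasses.replace(GeneratorConfig(), n_dyads=1, n_waves=1,
                               n_days=1, prompts_mother_weekday=m,
                               prompts_child_weekday=c, weekend_days=(), **kw)


class TestSchedule:
    def test_weekday_counts_and_pairing(self):
        sched = generate_schedule(one_day_config(), seed=0)
        assert (sched["member"] == "mother").sum() == 4
        assert (sched["member"] == "child").sum() == 3
        assert len(pair_prompts(sched.assign(answered=True))) == 3

    def test_half_hour_split(self):
        sched = generate_schedule(one_day_config(m=1, c=1), seed=0)
        minute = pd.DatetimeIndex(sched["scheduled_ts"]).minute
        m_min = minute[sched["member"] == "mother"][0]
        c_min = minute[sched["member"] == "child"][0]
        assert m_min < 30 <= c_min

    def test_same_member_gaps_at_least_one_hour(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_dyads=5, n_waves=1)
        sched = generate_schedule(cfg, seed=3)
        for (_, _, mem), grp in sched.groupby(["dyad_id", "day", "member"]):
            ts = grp["scheduled_ts"].sort_values()
            gaps = ts.diff().dropna().dt.total_seconds() / 60
            assert (gaps >= 60).all(), f"{mem} gap < 60 min"

    def test_weekend_tags_follow_calendar(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_dyads=2, n_waves=1)
        sched = generate_schedule(cfg, seed=0)
        dow = pd.DatetimeIndex(sched["scheduled_ts"]).dayofweek
        assert (sched["weekend"] == (dow >= 5)).all()

    def test_mean_mother_child_gap_near_thirty_minutes(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_dyads=30, n_waves=1)
        sched = generate_schedule(cfg, seed=5)
        pairs = pair_prompts(sched.assign(answered=True))
        se = np.sqrt(150.0 / len(pairs))
        assert pairs["prompt_diff"].mean() == pytest.approx(30.0, abs=3 * se)

    def test_infeasible_schedule_raises(self):
        with pytest.raises(SchedulingError):
            generate_schedule(one_day_config(m=9, c=3), seed=0)

    def test_child_exceeding_mother_rejected_at_config(self):
        with pytest.raises(SchedulingError):
            one_day_config(m=3, c=4)


class TestAffect:
    def test_degenerate_variances_give_constant(self):
        params = {k: AffectParams(2.5, 0.0, 0.0, ap.n_items, 0.0)
                  for k, ap in GeneratorConfig().affect_params.items()}
        cfg = dataclasses.replace(one_day_config(), affect_params=params)
        prompts = apply_missingness(generate_schedule(cfg, 0), cfg, 1)
        prompts = generate_affect(prompts, cfg, 2)
        answered = prompts[prompts["answered"]]
        assert (answered["pa"] == 2.5).all() and (answered["na"] == 2.5).all()

    def test_tier2_items_are_ordinal_one_to_four(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_dyads=10, n_waves=1)
        prompts = apply_missingness(generate_schedule(cfg, 0), cfg, 1)
        prompts = generate_affect(prompts, cfg, 2)
        for col in ("pa_item1", "pa_item2", "na_item1", "na_item2", "na_item3"):
            vals = prompts.loc[prompts["answered"], col].dropna().unique()
            assert set(vals) <= {1.0, 2.0, 3.0, 4.0}

    def test_reconstruction_identity(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_dyads=5, n_waves=1)
        prompts = apply_missingness(generate_schedule(cfg, 0), cfg, 1)
        prompts = generate_affect(prompts, cfg, 2)
        a = prompts[prompts["answered"]]
        assert np.allclose(a["pa_pm_true"] + a["pa_dev_true"], a["pa"])

    def test_child_na_icc_converges_to_generating_ratio(self):
        # between^2/(between^2+within^2) = 0.293 at 185 subjects x 50 prompts
        from dyadema.simulate import simulate_icc_panel
        from test_descriptives import anova_icc
        ap = GeneratorConfig().affect_params[("child", "na")]
        assert ap.icc == pytest.approx(0.293, abs=1e-3)
        iccs = []
        for seed in range(21, 31):
            vals, subj = simulate_icc_panel(ap.between_sd, ap.within_sd,
                                            185, 50, ap.mean, seed=seed)
            iccs.append(anova_icc(vals, subj))
        assert np.mean(iccs) == pytest.approx(ap.icc, abs=0.03)

    def test_floor_clipping_shifts_raw_scale_icc_down(self):
        """The 1-4 floor compresses child negative affect (latent mean 1.26),
        so the raw-scale ICC of clipped composites sits below the latent
        variance ratio -- a known floor effect of bounded response scales."""
        cfg = GeneratorConfig()
        df = simulate_recovery_dataset(cfg, seed=21, outcome="mvpa")
        from test_descriptives import anova_icc
        icc = anova_icc(df["c_na"].to_numpy(), df["dyad_id"].to_numpy())
        assert 0.15 < icc < 0.293

    def test_affect_params_from_totals_invariants(self):
        ap = affect_params_from_totals(2.0, 0.8, 0.25, 3, 0.85)
        assert ap.icc == pytest.approx(0.25)
        assert np.hypot(ap.between_sd, ap.within_sd) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            AffectParams(2.0, -0.1, 0.5, 2, 0.1)


class TestMissingness:
    def test_full_compliance(self):
        cfg = dataclasses.replace(one_day_config(), compliance_mother=1.0,
                                  compliance_child=1.0)
        prompts = apply_missingness(generate_schedule(cfg, 0), cfg, 1)
        assert prompts["answered"].all()

    def test_binomial_convergence(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_dyads=140, n_waves=2)
        prompts = apply_missingness(generate_schedule(cfg, 0), cfg, 1)
        m = prompts[prompts["member"] == "mother"]["answered"]
        assert len(m) >= 10000
        se = np.sqrt(0.803 * 0.197 / len(m))
        assert m.mean() == pytest.approx(0.803, abs=3 * se)

    def test_zero_compliance_leads_to_structured_empty_error(self):
        from dyadema.windows import EmptyStageError, build_analysis_set
        cfg = dataclasses.replace(one_day_config(), compliance_mother=0.0,
                                  compliance_child=0.0)
        prompts = generate_affect(
            apply_missingness(generate_schedule(cfg, 0), cfg, 1), cfg, 2)
        pairs = pair_prompts(prompts)
        metrics = pd.DataFrame({"prompt_id": [], "has_data": [], "wear_min": [],
                                "mvpa_min": [], "sed_min": [],
                                "valid_day": []}).set_index("prompt_id")
        with pytest.raises(EmptyStageError, match="answered_reports"):
            build_analysis_set(prompts, pairs, metrics)


class TestWindowOutcomes:
    def residual_only_params(self, rho):
        return ApimParams(fixed={}, G=np.zeros((2, 2)), sigma_m=1.0,
                          sigma_c=1.0, rho=rho)

    def test_residual_only_cross_correlation(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_dyads=40, n_waves=1)
        df = simulate_recovery_dataset(cfg, seed=2, outcome="mvpa")
        out = generate_window_outcomes(df, self.residual_only_params(0.6),
                                       seed=3)
        r = np.corrcoef(out["m_out"], out["c_out"])[0, 1]
        assert r == pytest.approx(0.6, abs=3.0 / np.sqrt(len(out)))

    def test_linear_predictor_term_by_term(self):
        """With G = 0 and vanishing residuals the outcome equals the
        hand-computed sum of coefficient x column products."""
        cfg = dataclasses.replace(GeneratorConfig(), n_dyads=3, n_waves=2)
        df = simulate_recovery_dataset(cfg, seed=4, outcome="mvpa")
        apim = dataclasses.replace(MVPA_TRUTH, G=np.zeros((2, 2)),
                                   sigma_m=1e-9, sigma_c=1e-9, rho=0.0)
        out = generate_window_outcomes(df, apim, seed=5)
        from dyadema.apim import design_terms
        mother_terms, child_terms = design_terms(use_true_affect=True)
        for rec in out.head(4).itertuples(index=False):
            row = rec._asdict()
            row["_one"] = 1.0
            for terms, col in ((mother_terms, "m_out"), (child_terms, "c_out")):
                lp = sum(apim.fixed.get(name, 0.0) * row[src]
                         for name, src in terms)
                assert row[col] == pytest.approx(lp, abs=1e-6)

    def test_bounded_mode_respects_window_limits(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_dyads=20, n_waves=1)
        df = simulate_recovery_dataset(cfg, seed=6, outcome="sedentary",
                                       mode="bounded")
        assert df["m_out"].between(0, 45).all()
        assert df["c_out"].between(0, 45).all()

    def test_non_psd_G_rejected(self):
        with pytest.raises(ValueError):
            ApimParams(fixed={}, G=np.array([[1.0, 2.0], [2.0, 1.0]]),
                       sigma_m=1, sigma_c=1, rho=0)


class TestRenderEpochs:
    def plant(self, mvpa, sed, member="mother", age=None, **cfg_kw):
        cfg = dataclasses.replace(GeneratorConfig(), nonwear_runs_per_day=0.0,
                                  **cfg_kw)
        win = pd.DataFrame({"anchor_ts": [pd.Timestamp("2015-01-05 10:17:23")],
                            "mvpa_min": [mvpa], "sed_min": [sed]})
        es, truth = render_epoch_counts(win, "2015-01-05", 1, "s", member,
                                        cfg, seed=8, age=age)
        return es, truth, win

    def test_all_sedentary_window(self):
        es, _, win = self.plant(0.0, 45.0)
        ann = detect_non_wear(es)
        labels = classify_epochs(es, ann, "mother")
        w = extract_window(labels, es.epoch_start, win["anchor_ts"][0])
        assert w["sed_min"] == 45.0 and w["mvpa_min"] == 0.0

    @pytest.mark.parametrize("member,age", [("mother", None), ("child", 10.0)])
    def test_classification_round_trip(self, member, age):
        es, truth, win = self.plant(3.0, 30.0, member=member, age=age)
        ann = detect_non_wear(es)
        labels = classify_epochs(es, ann, member, age)
        w = extract_window(labels, es.epoch_start, win["anchor_ts"][0])
        assert (w["mvpa_min"], w["sed_min"]) == (3.0, 30.0)
        assert truth["full_wear"].all()

    def test_overfull_window_rejected(self):
        with pytest.raises(ValueError):
            self.plant(30.0, 30.0)

    def test_planted_zero_run_durations(self):
        # 61-min zero run -> non-wear; 59-min -> wear (strict 60-min rule)
        es, _, _ = self.plant(0.0, 0.0)
        counts = es.counts.copy()
        i0 = 9 * 120                       # 09:00, inside wear hours
        counts[i0:i0 + 122] = 0            # 61 min
        i1 = 14 * 120
        counts[i1:i1 + 118] = 0            # 59 min
        from dyadema.accelerometry import EpochSeries
        es2 = EpochSeries("s", es.epoch_start, counts)
        ann = detect_non_wear(es2)
        assert not ann.wear[i0:i0 + 122].any()
        assert ann.wear[i1:i1 + 118].all()


class TestDeterminism:
    def test_fixed_seed_bit_identical(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_dyads=8, n_waves=1)
        a = simulate_recovery_dataset(cfg, seed=13, outcome="mvpa")
        b = simulate_recovery_dataset(cfg, seed=13, outcome="mvpa")
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_distributionally_equivalent(self):
        """KS tests on tier-1 composites across seed pairs: at alpha = .01
        at least 9 of 10 comparisons should not reject."""
        cfg = dataclasses.replace(GeneratorConfig(), n_dyads=20, n_waves=1)

        def composites(seed):
            prompts = generate_affect(
                apply_missingness(generate_schedule(cfg, seed), cfg, seed + 1),
                cfg, seed + 2)
            return prompts.loc[prompts["answered"]
                               & (prompts["member"] == "child"), "pa"]

        not_rejected = sum(
            ks_2samp(composites(100 + i), composites(200 + i)).pvalue > 0.01
            for i in range(10))
        assert not_rejected >= 9


class TestRecoveryDataset:
    def test_target_windows_per_dyad(self):
        cfg = GeneratorConfig()
        df = simulate_recovery_dataset(cfg, seed=17, outcome="mvpa")
        per_dyad = df.groupby("dyad_id").size()
        assert per_dyad.max() <= cfg.target_windows_per_dyad
        assert per_dyad.median() == cfg.target_windows_per_dyad
        assert df["dyad_id"].nunique() == 185

    def test_design_builds_full_rank(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_dyads=30, n_waves=2)
        df = simulate_recovery_dataset(cfg, seed=19, outcome="sedentary")
        from dyadema import scoring
        frame = scoring.add_person_centered(df, pipeline.AFFECT_COLS)
        design = build_design(frame)
        assert np.linalg.matrix_rank(design.X) == design.X.shape[1]

    def test_truth_constants_match_intended_random_structure(self):
        assert MVPA_TRUTH.intercept_sds == pytest.approx((0.181, 0.206))
        assert MVPA_TRUTH.intercept_corr == pytest.approx(0.546)
        assert SEDENTARY_TRUTH.intercept_corr == pytest.approx(0.441)
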