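"""Contracts of the synthetic methylome generator."""

import numpy as np
import pandas as pd
import pytest

from senclock import io as mio
from senclock import stats
from senclock.simulate import (
    SimulationConfig,
    build_truth,
    class_counts,
    simulate_aging_cohort,
    simulate_immortalized_series,
    simulate_mortality_cohort,
    simulate_senescence_experiment,
    simulate_senolytic_trial,
)
from conftest import small_config


class TestConfigAndTruth:
    def test_fractions_must_sum_to_one(self):
        cfg = small_config(cpg_class_fractions={"null": 0.8})
        with pytest.raises(ValueError, match="sum"):
            cfg.validate()

    def test_nonfinite_effect_rejected(self):
        cfg = small_config(effect_logit={"concordant_all": float("inf")})
        with pytest.raises(ValueError, match="non-finite"):
            cfg.validate()

    def test_group_size_below_two_rejected(self):
        cfg = small_config(group_sizes={"d": {"l": {"control": 1,
                                                    "replicative": 4}}})
        with pytest.raises(ValueError, match="group size"):
            cfg.validate()

    def test_class_frequencies_match_fractions_exactly(self):
        cfg = small_config(n_cpgs=1000)
        counts = class_counts(cfg)
        assert sum(counts.values()) == 1000
        for cls, frac in cfg.cpg_class_fractions.items():
            assert abs(counts[cls] - frac * 1000) < 1

    def test_every_cpg_has_exactly_one_truth_row(self):
        cfg = small_config()
        ds, truth = simulate_senescence_experiment(cfg)
        assert truth.table.index.equals(ds.cpg_ids)
        assert not truth.table.index.duplicated().any()

    def test_concordant_truth_signs_agree_across_axes(self):
        truth = build_truth(small_config())
        sub = truth.table[truth.table["cpg_class"] == "concordant_all"]
        assert (sub["sen_direction"] == sub["age_direction"]).all()
        assert (sub["sen_direction"] == sub["mortality_direction"]).all()
        hyper = sub["sen_direction"] == "hyper"
        assert (sub.loc[hyper, "age_slope"] > 0).all()
        assert (sub.loc[hyper, "log_hr"] > 0).all()
        assert (sub.loc[~hyper, "age_slope"] < 0).all()


class TestSenescenceExperiment:
    def test_same_seed_bit_identical(self):
        cfg = small_config(seed=5)
        d1, _ = simulate_senescence_experiment(cfg)
        d2, _ = simulate_senescence_experiment(cfg)
        assert d1.betas.equals(d2.betas)
        assert d1.samples.equals(d2.samples)

    def test_different_seed_differs(self):
        d1, _ = simulate_senescence_experiment(small_config(seed=1))
        d2, _ = simulate_senescence_experiment(small_config(seed=2))
        assert not d1.betas.equals(d2.betas)

    def test_betas_strictly_inside_unit_interval(self):
        ds, _ = simulate_senescence_experiment(small_config())
        vals = ds.betas.to_numpy()
        assert (vals > 0).all() and (vals < 1).all()

    def test_zero_effect_zero_noise_means_identical(self):
        cfg = small_config(
            noise_sd_logit=0.0, cell_line_sd_logit=0.0, batch_shift_logit=0.0,
            effect_logit={c: 0.0 for c in small_config().effect_logit},
        )
        ds, _ = simulate_senescence_experiment(cfg)
        sheet = ds.samples
        sen = ds.betas[sheet.index[sheet["condition"] == "senescent"]]
        ctl = ds.betas[sheet.index[sheet["condition"] == "control"]]
        assert np.allclose(sen.mean(axis=1), ctl.mean(axis=1), atol=1e-12)

    def test_pan_hyper_cpgs_higher_in_every_inducer_and_line(self):
        cfg = small_config(seed=3)
        ds, truth = simulate_senescence_experiment(cfg)
        hyper = truth.cpgs_in_class("pan_senescence_hyper")
        sheet = ds.samples
        for (batch, line), grp in sheet.groupby(["dataset_id", "cell_line"]):
            ctl = grp.index[grp["condition"] == "control"]
            for inducer, sen_grp in grp[grp["condition"] == "senescent"].groupby("inducer"):
                diff = (ds.betas.loc[hyper, sen_grp.index].mean(axis=1)
                        - ds.betas.loc[hyper, ctl].mean(axis=1))
                # group-mean comparison on the generated matrix
                assert (diff > 0).mean() > 0.95

    def test_round_trip_through_io(self, tmp_path):
        cfg = small_config(n_cpgs=50)
        ds, truth = simulate_senescence_experiment(cfg)
        mio.write_beta_matrix(ds, tmp_path / "b.tsv")
        mio.write_sample_sheet(ds.samples, tmp_path / "s.tsv")
        mio.write_truth_table(truth, tmp_path / "t.tsv")
        sheet = mio.read_sample_frame(tmp_path / "s.tsv")
        back = mio.read_beta_matrix(tmp_path / "b.tsv", samples=sheet)
        assert np.allclose(back.betas.to_numpy(), ds.betas.to_numpy(),
                           atol=1e-9)
        truth_back = mio.read_truth_table(tmp_path / "t.tsv")
        assert (truth_back.table["cpg_class"] == truth.table["cpg_class"]).all()


class TestImmortalizedSeries:
    def test_replication_tracking_cpgs_correlate_with_passage(self):
        cfg = small_config(seed=4)
        ds, truth = simulate_immortalized_series(cfg)
        passages = ds.samples["passage"].to_numpy(dtype=float)
        rep = truth.cpgs_in_class("replication_tracking")
        r, _ = stats.bicor_by_feature(ds.betas.loc[rep].to_numpy(), passages)
        assert (np.abs(r) > 0.3).mean() > 0.9

    def test_null_cpgs_rarely_exceed_threshold(self):
        # Monte-Carlo over seeds: |bicor| < 0.3 with probability >= 0.95
        hits, total = 0, 0
        for seed in range(30):
            ds, truth = simulate_immortalized_series(
                small_config(seed=seed, n_cpgs=40)
            )
            null = truth.cpgs_in_class("null")
            r, _ = stats.bicor_by_feature(
                ds.betas.loc[null].to_numpy(),
                ds.samples["passage"].to_numpy(dtype=float),
            )
            hits += (np.abs(r) < 0.3).sum()
            total += len(null)
        assert hits / total >= 0.95

    def test_constant_series_flagged_not_selected(self):
        cfg = small_config(noise_sd_logit=0.0, passage_drift_logit=0.0)
        ds, _ = simulate_immortalized_series(cfg)
        r, flagged = stats.bicor_by_feature(
            ds.betas.to_numpy(), ds.samples["passage"].to_numpy(dtype=float)
        )
        assert flagged.all()

    def test_too_few_passages_rejected(self):
        with pytest.raises(ValueError, match="passages"):
            simulate_immortalized_series(small_config(n_passages=2))


class TestAgingCohort:
    def test_planted_slope_recovered(self):
        cfg = small_config(seed=6, aging_n=500, age_slope=0.5)
        ds, truth = simulate_aging_cohort(cfg)
        aged = truth.cpgs_in_class("age_only")
        res = stats.standardized_slope(
            ds.betas.loc[aged].to_numpy(),
            ds.samples["age"].to_numpy(dtype=float),
        )
        signs = np.where(truth.table.loc[aged, "age_direction"] == "hyper", 1, -1)
        err = np.abs(res["effect"] - signs * 0.5)
        assert np.mean(err < 0.1) > 0.9

    def test_null_cpgs_centered_at_zero(self):
        cfg = small_config(seed=8, aging_n=300)
        ds, truth = simulate_aging_cohort(cfg)
        null = truth.cpgs_in_class("null")
        res = stats.standardized_slope(
            ds.betas.loc[null].to_numpy(),
            ds.samples["age"].to_numpy(dtype=float),
        )
        assert abs(np.mean(res["effect"])) < 0.05

    def test_no_survival_fields(self):
        ds, _ = simulate_aging_cohort(small_config())
        assert ds.samples["survival_time"].isna().all()
        assert ds.samples["event"].isna().all()

    def test_degenerate_age_range_rejected(self):
        with pytest.raises(ValueError, match="age range"):
            simulate_aging_cohort(small_config(age_range=(50.0, 50.0)))


class TestMortalityCohort:
    def test_single_causal_cpg_coverage(self):
        # one mortality CpG, direct planted log HR 0.3: the age-adjusted Cox
        # CI should cover the truth in >= 90% of replicates
        fractions = {"mortality_only": 0.02, "null": 0.98}
        covered = 0
        n_rep = 60
        for seed in range(n_rep):
            cfg = small_config(
                seed=seed, n_cpgs=50, cpg_class_fractions=fractions,
                mortality_n=800,
            )
            ds, truth = simulate_mortality_cohort(cfg)
            cpg = truth.cpgs_in_class("mortality_only")[0]
            beta = ds.betas.loc[[cpg]].to_numpy()
            z = (beta - beta.mean()) / beta.std(ddof=1)
            ages = ds.samples["age"].to_numpy(dtype=float)
            res = stats.cox_by_feature(
                z, (ages - ages.mean()) / ages.std(ddof=1),
                ds.samples["survival_time"].to_numpy(dtype=float),
                ds.samples["event"].to_numpy(dtype=float),
            )
            lo = res["effect"][0] - 1.96 * res["se"][0]
            hi = res["effect"][0] + 1.96 * res["se"][0]
            truth_val = truth.table.loc[cpg, "log_hr"]
            covered += lo <= truth_val <= hi
        assert covered / n_rep >= 0.9

    def test_null_config_gives_unit_hazard_ratios(self):
        cfg = small_config(seed=10, log_hr=0.0, mortality_n=600)
        ds, _ = simulate_mortality_cohort(cfg)
        sub = ds.betas.iloc[:30].to_numpy()
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1,
                                                              keepdims=True)
        ages = ds.samples["age"].to_numpy(dtype=float)
        res = stats.cox_by_feature(
            z, (ages - ages.mean()) / ages.std(ddof=1),
            ds.samples["survival_time"].to_numpy(dtype=float),
            ds.samples["event"].to_numpy(dtype=float),
        )
        assert abs(np.mean(res["effect"])) < 0.05

    def test_censoring_rate_close_to_configured(self):
        cfg = small_config(seed=12, mortality_n=2000)
        ds, _ = simulate_mortality_cohort(cfg)
        observed = 1.0 - ds.samples["event"].mean()
        assert observed == pytest.approx(0.30, abs=0.05)

    def test_full_censoring_rejected(self):
        with pytest.raises(ValueError, match="censoring"):
            small_config(censoring_rate=1.0).validate()


class TestSenolyticTrial:
    def test_null_trial_changes_centered_at_zero(self):
        trial = simulate_senolytic_trial(small_config(seed=13), 0.0, "none")
        sheet = trial.dataset.samples
        pre = trial.dataset.betas[sheet.index[sheet["timepoint"] == "pre"]]
        post = trial.dataset.betas[sheet.index[sheet["timepoint"] == "post"]]
        eligible = trial.truth.cpgs_in_class("concordant_all")
        diff = (post.loc[eligible].mean(axis=1) - pre.loc[eligible].mean(axis=1))
        assert abs(diff.mean()) < 0.02

    def test_full_subtract_restores_control_means(self):
        cfg = small_config(seed=14, noise_sd_logit=0.05, pair_sd_logit=0.0)
        trial = simulate_senolytic_trial(cfg, 1.0, "subtract_effect",
                                         n_pairs=40)
        sen, truth = simulate_senescence_experiment(
            small_config(seed=14, noise_sd_logit=0.05, cell_line_sd_logit=0.0,
                         batch_shift_logit=0.0)
        )
        sheet = trial.dataset.samples
        post = trial.dataset.betas[sheet.index[sheet["timepoint"] == "post"]]
        ctl = sen.betas[sen.samples.index[sen.samples["condition"] == "control"]]
        hyper = truth.cpgs_in_class("pan_senescence_hyper")
        gap = (post.loc[hyper].mean(axis=1) - ctl.loc[hyper].mean(axis=1)).abs()
        assert gap.mean() < 0.02

    def test_remix_shrinks_effect_fivefold(self):
        # senescent weight 0.5 -> 0.1 shrinks the beta-scale effect to ~0.2x
        cfg = small_config(seed=15, noise_sd_logit=0.01, pair_sd_logit=0.0)
        trial = simulate_senolytic_trial(cfg, 0.0, "remix_population",
                                         n_pairs=60, pre_weight=0.5,
                                         post_weight=0.1)
        base, truth = simulate_senescence_experiment(
            small_config(seed=15, noise_sd_logit=0.01, cell_line_sd_logit=0.0,
                         batch_shift_logit=0.0)
        )
        ctl_means = base.betas[
            base.samples.index[base.samples["condition"] == "control"]
        ].mean(axis=1)
        sheet = trial.dataset.samples
        pre = trial.dataset.betas[sheet.index[sheet["timepoint"] == "pre"]].mean(axis=1)
        post = trial.dataset.betas[sheet.index[sheet["timepoint"] == "post"]].mean(axis=1)
        eligible = truth.cpgs_in_class("pan_senescence_hyper")
        ratio = ((post - ctl_means).loc[eligible]
                 / (pre - ctl_means).loc[eligible])
        assert np.median(ratio) == pytest.approx(0.2, abs=0.05)

    def test_pairing_and_labels(self):
        trial = simulate_senolytic_trial(small_config(), 0.5, "subtract_effect")
        sheet = trial.dataset.samples
        assert set(sheet["timepoint"]) == {"pre", "post"}
        assert sheet.groupby("pair_id").size().eq(2).all()
        n_elig = len(trial.truth.cpgs_in_class("concordant_all")) + \
            len(trial.truth.cpgs_in_class("pan_senescence_hyper")) + \
            len(trial.truth.cpgs_in_class("pan_senescence_hypo"))
        assert len(trial.reversed_cpgs) == round(0.5 * n_elig)

    def test_invalid_reversal_fraction_rejected(self):
        with pytest.raises(ValueError, match="reversal_fraction"):
            simulate_senolytic_trial(small_config(), 1.5, "none")
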