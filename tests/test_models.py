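"""Batch harmonization, imputation, elastic-net training and scoring."""

import numpy as np
import pandas as pd
import pytest

from senclock.datasets import MethylationDataset, SampleInfo, samples_to_frame
from senclock.models import (
    ClockModel,
    batch_harmonize,
    mean_impute,
    score,
    split_survival,
    train_clock,
)
from senclock.simulate import (
    simulate_aging_cohort,
    simulate_senescence_experiment,
)
from conftest import small_config


def _two_batch_dataset(seed=0, shift=0.15, n_cpgs=200, n_per=20):
    """Two batches with a planted constant per-CpG beta shift and a
    balanced condition effect."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.25, 0.7, n_cpgs)
    cond_effect = np.zeros(n_cpgs)
    cond_effect[: n_cpgs // 4] = 0.08
    batch_shift = rng.normal(0.0, shift, n_cpgs)
    cols, rows = [], []
    for b, delta in (("batch1", 0.0), ("batch2", 1.0)):
        for k in range(n_per):
            senescent = k % 2 == 1  # balanced within batch
            mean = base + delta * batch_shift + senescent * cond_effect
            cols.append(np.clip(mean + rng.normal(0, 0.02, n_cpgs), 0.01, 0.99))
            rows.append(SampleInfo(
                sample_id=f"{b}_s{k}", dataset_id=b,
                condition="senescent" if senescent else "control",
                inducer="replicative" if senescent else "none",
                cell_line="fibro",
            ))
    betas = pd.DataFrame(np.column_stack(cols),
                         index=[f"cg{i:04d}" for i in range(n_cpgs)],
                         columns=[r.sample_id for r in rows])
    return MethylationDataset(betas, samples_to_frame(rows), "pooled"), \
        batch_shift, cond_effect


class TestBatchHarmonize:
    def test_single_batch_is_identity(self):
        ds, _ = simulate_senescence_experiment(
            small_config(group_sizes={"only": {"fibro": {"control": 5,
                                                         "replicative": 5}}})
        )
        out = batch_harmonize(ds)
        assert np.allclose(out.betas.to_numpy(), ds.betas.to_numpy(),
                           atol=1e-9)

    def test_planted_batch_shift_removed(self):
        ds, _, _ = _two_batch_dataset()
        out = batch_harmonize(ds)
        sheet = out.samples
        b1 = out.betas[sheet.index[sheet["dataset_id"] == "batch1"]].mean(axis=1)
        b2 = out.betas[sheet.index[sheet["dataset_id"] == "batch2"]].mean(axis=1)
        assert (b1 - b2).abs().mean() < 0.01

    def test_balanced_condition_effect_preserved(self):
        ds, _, cond_effect = _two_batch_dataset()
        out = batch_harmonize(ds)
        sheet = out.samples
        sen = out.betas[sheet.index[sheet["condition"] == "senescent"]].mean(axis=1)
        ctl = out.betas[sheet.index[sheet["condition"] == "control"]].mean(axis=1)
        observed = (sen - ctl).to_numpy()[: len(cond_effect) // 4]
        planted = cond_effect[: len(cond_effect) // 4]
        rel_err = np.abs(observed - planted) / planted
        assert rel_err.mean() < 0.10

    def test_output_clipped_to_unit_interval(self):
        ds, _, _ = _two_batch_dataset(shift=0.4)
        out = batch_harmonize(ds)
        vals = out.betas.to_numpy()
        assert (vals >= 1e-6).all() and (vals <= 1 - 1e-6).all()

    def test_missing_values_rejected(self):
        ds, _, _ = _two_batch_dataset()
        ds.betas.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            batch_harmonize(ds)

    def test_matches_sva_combat_reference(self, tmp_path):
        """Cross-check against Bioconductor sva::ComBat on a small fixture."""
        import subprocess

        ds, _, _ = _two_batch_dataset(n_cpgs=40, n_per=10)
        ours = batch_harmonize(ds, covariates=("condition",))
        dat = tmp_path / "dat.tsv"
        ds.betas.to_csv(dat, sep="\t")
        meta = tmp_path / "meta.tsv"
        ds.samples[["dataset_id", "condition"]].to_csv(meta, sep="\t")
        out = tmp_path / "out.tsv"
        script = tmp_path / "combat.R"
        script.write_text(f"""
suppressMessages(library(sva))
dat <- as.matrix(read.delim("{dat}", row.names=1, check.names=FALSE))
meta <- read.delim("{meta}", row.names=1)
mod <- model.matrix(~condition, data=meta)
adj <- ComBat(dat=dat, batch=meta$dataset_id, mod=mod)
write.table(adj, "{out}", sep="\t", quote=FALSE)
""")
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(out, sep="\t", index_col=0)
        dev = np.abs(ours.betas.to_numpy() - ref.to_numpy()).max()
        assert dev < 1e-3


class TestMeanImpute:
    def test_complete_matrix_unchanged(self):
        frame = pd.DataFrame([[0.1, 0.2], [0.3, 0.4]], index=["a", "b"])
        ref = pd.Series([0.9, 0.9], index=["a", "b"])
        assert mean_impute(frame, ref).equals(frame)

    def test_single_missing_cell_filled(self):
        frame = pd.DataFrame([[np.nan, 0.2]], index=["a"], columns=["s1", "s2"])
        out = mean_impute(frame, pd.Series({"a": 0.55}))
        assert out.loc["a", "s1"] == pytest.approx(0.55)
        assert out.loc["a", "s2"] == pytest.approx(0.2)

    def test_fully_missing_row_filled(self):
        frame = pd.DataFrame([[np.nan, np.nan]], index=["a"],
                             columns=["s1", "s2"])
        out = mean_impute(frame, pd.Series({"a": 0.3}))
        assert (out.loc["a"] == 0.3).all()

    def test_missing_reference_rejected(self):
        frame = pd.DataFrame([[0.1]], index=["a"])
        with pytest.raises(ValueError, match="reference"):
            mean_impute(frame, pd.Series({"b": 0.5}))


def _gaussian_toy(seed=0, n=60, p=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = np.array([1.0, -0.5, 0.0, 0.3, 0.8])
    y = 40 + X @ w + rng.normal(0, 0.5, n)
    betas = pd.DataFrame(
        (X - X.min()) / (X.max() - X.min()),  # squeeze into [0,1]
        columns=[f"s{i}" for i in range(n)], index=None,
    )
    return X, y


class TestTrainClock:
    def _age_dataset(self, seed=0, n=60, p=5):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(0.2, 0.8, size=(p, n))
        w = np.array([30.0, -20.0, 0.0, 10.0, 25.0])
        age = 40 + w @ (raw - 0.5) + rng.normal(0, 0.5, n)
        rows = [SampleInfo(f"s{i}", "d", "control", "none", "blood",
                           age=float(age[i])) for i in range(n)]
        betas = pd.DataFrame(raw, index=[f"cg{j}" for j in range(p)],
                             columns=[f"s{i}" for i in range(n)])
        return MethylationDataset(betas, samples_to_frame(rows), "d")

    def test_ridge_alpha_zero_matches_closed_form(self):
        ds = self._age_dataset()
        lam = 0.7
        model = train_clock(ds, "age", list(ds.cpg_ids), alpha=0.0,
                            lambda_=lam, seed=1)
        # closed-form ridge on the standardized design used internally
        X_raw = ds.betas.to_numpy().T
        y = ds.samples["age"].to_numpy(dtype=float)
        mu, sd = X_raw.mean(axis=0), X_raw.std(axis=0)
        X = (X_raw - mu) / sd
        n = len(y)
        w_std = np.linalg.solve(X.T @ X / n + lam * np.eye(X.shape[1]),
                                X.T @ (y - y.mean()) / n)
        w_ref = w_std / sd
        got = pd.Series(0.0, index=ds.cpg_ids)
        got[model.cpg_ids] = model.weights
        assert np.abs(got.to_numpy() - w_ref).max() < 1e-8
        b_ref = y.mean() - np.sum(w_std * mu / sd)
        assert model.intercept == pytest.approx(b_ref, abs=1e-8)

    def test_huge_lambda_shrinks_to_outcome_mean(self):
        ds = self._age_dataset()
        model = train_clock(ds, "age", list(ds.cpg_ids), alpha=0.5,
                            lambda_=1e6, seed=1)
        assert len(model.cpg_ids) == 0
        y = ds.samples["age"].to_numpy(dtype=float)
        assert model.intercept == pytest.approx(y.mean(), rel=1e-6)

    def test_cv_is_deterministic_given_seed(self):
        ds = self._age_dataset(n=80)
        m1 = train_clock(ds, "age", list(ds.cpg_ids), seed=7, n_lambdas=20)
        m2 = train_clock(ds, "age", list(ds.cpg_ids), seed=7, n_lambdas=20)
        assert m1.lambda_ == m2.lambda_
        assert np.array_equal(m1.weights, m2.weights)

    def test_binomial_clock_separates_heldout_senescence(self):
        cfg = small_config(seed=30, n_cpgs=300)
        train_ds, truth = simulate_senescence_experiment(cfg)
        test_ds, _ = simulate_senescence_experiment(
            cfg, group_sizes=cfg.test_group_sizes, dataset_index=60,
            dataset_id="test")
        features = list(truth.concordant)
        model = train_clock(batch_harmonize(train_ds), "senescence", features,
                            seed=30, n_lambdas=20)
        from sklearn.metrics import roc_auc_score

        sc = score(model, test_ds)["score"]
        y = (test_ds.samples["condition"] == "senescent").astype(int)
        assert roc_auc_score(y, sc) >= 0.9

    def test_gaussian_clock_predicts_heldout_age(self):
        cfg = small_config(seed=31, n_cpgs=300, aging_n=300)
        train_ds, truth = simulate_aging_cohort(cfg)
        test_ds, _ = simulate_aging_cohort(cfg, n=150, dataset_index=61,
                                           dataset_id="aging_test")
        features = list(truth.concordant) + \
            list(truth.cpgs_in_class("age_only"))
        model = train_clock(train_ds, "age", features, seed=31, n_lambdas=20)
        sc = score(model, test_ds)["score"]
        r = np.corrcoef(sc, test_ds.samples["age"])[0, 1]
        assert r >= 0.8

    def test_degenerate_outcome_rejected(self):
        ds = self._age_dataset()
        ds.samples["condition"] = "control"
        with pytest.raises(ValueError, match="single class"):
            train_clock(ds, "senescence", list(ds.cpg_ids), seed=0)


class TestScore:
    def _model(self):
        return ClockModel(
            name="toy", family="binomial", cpg_ids=["cgA", "cgB"],
            weights=np.array([2.0, -1.0]), intercept=0.5,
            imputation_means={"cgA": 0.4, "cgB": 0.6},
            alpha=0.5, lambda_=0.1, n_folds=10, seed=0,
        )

    def test_zero_weight_model_scores_intercept(self, tiny_dataset):
        model = ClockModel(
            name="flat", family="gaussian", cpg_ids=[], weights=np.array([]),
            intercept=42.0, imputation_means={}, alpha=0.5, lambda_=1.0,
            n_folds=10, seed=0,
        )
        out = score(model, tiny_dataset)
        assert (out["score"] == 42.0).all()

    def test_all_missing_sample_scores_imputation_identity(self):
        model = self._model()
        rows = [SampleInfo("s1", "d", "control", "none", "x")]
        betas = pd.DataFrame({"s1": [np.nan, np.nan]}, index=["cgA", "cgB"])
        ds = MethylationDataset(betas, samples_to_frame(rows), "d")
        out = score(model, ds)
        expected = 0.5 + 2.0 * 0.4 - 1.0 * 0.6
        assert out.loc["s1", "score"] == pytest.approx(expected)
        assert out.loc["s1", "probability"] == pytest.approx(
            1 / (1 + np.exp(-expected)))

    def test_invariant_to_cpg_row_order(self, tiny_dataset):
        model = ClockModel(
            name="toy", family="gaussian", cpg_ids=["cgA", "cgC"],
            weights=np.array([1.0, 2.0]), intercept=0.0,
            imputation_means={"cgA": 0.5, "cgC": 0.5},
            alpha=0.5, lambda_=0.1, n_folds=10, seed=0,
        )
        shuffled = MethylationDataset(
            tiny_dataset.betas.iloc[::-1], tiny_dataset.samples,
            tiny_dataset.dataset_id,
        )
        assert np.allclose(score(model, tiny_dataset)["score"],
                           score(model, shuffled)["score"])


class TestSplitSurvival:
    def test_stratified_seventy_thirty(self):
        cfg = small_config(seed=40, mortality_n=500)
        ds, _ = __import__("senclock.simulate", fromlist=["x"]) \
            .simulate_mortality_cohort(cfg)
        train, test = split_survival(ds, test_fraction=0.3, seed=40)
        assert test.n_samples == pytest.approx(150, abs=2)
        assert train.n_samples + test.n_samples == 500
        # event rate preserved in both halves
        full_rate = ds.samples["event"].mean()
        assert train.samples["event"].mean() == pytest.approx(full_rate,
                                                              abs=0.02)
        assert test.samples["event"].mean() == pytest.approx(full_rate,
                                                             abs=0.02)

    def test_deterministic(self):
        cfg = small_config(seed=41, mortality_n=300)
        from senclock.simulate import simulate_mortality_cohort

        ds, _ = simulate_mortality_cohort(cfg)
        t1, _ = split_survival(ds, seed=5)
        t2, _ = split_survival(ds, seed=5)
        assert list(t1.sample_ids) == list(t2.sample_ids)
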