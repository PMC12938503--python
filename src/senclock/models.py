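"""Batch harmonization, elastic-net clock training and scoring.

Three clocks are trained on the selected CpG set: a binomial senescence
predictor (SenCultureAge), a gaussian chronological-age predictor
(SenChronoAge) and a Cox time-to-death predictor (SenMortalityAge). All use
the elastic-net penalty lambda * [alpha*||w||_1 + (1-alpha)*||w||_2^2 / 2]
on internally standardized features with lambda chosen by K-fold
cross-validation; weights are reported back on the raw beta scale.
Missing betas are mean-imputed from the training data at fit time and from
the stored model means at scoring time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .datasets import MethylationDataset

CLOCK_FAMILIES = ("binomial", "gaussian", "cox")


# ---------------------------------------------------------------------------
# empirical-Bayes batch harmonization (location/scale, parametric priors)
# ---------------------------------------------------------------------------

def _combat_adjust(
    values: np.ndarray,
    batch_codes: np.ndarray,
    covariates: Optional[np.ndarray],
    max_iter: int = 200,
    conv: float = 1e-4,
) -> np.ndarray:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per feature: fit batch means (+ optional covariates), standardize,
    estimate per-batch location (gamma) and scale (delta^2) effects, shrink
    them toward common priors (normal for gamma, inverse-gamma for delta^2)
    by the iterative posterior-mode equations, remove them, and restore the
    pooled location/scale.
    """
    n_feat, n_samp = values.shape
    batches = np.unique(batch_codes)
    n_batches = batches.size
    onehot = np.column_stack([(batch_codes == b).astype(float) for b in batches])
    design = onehot if covariates is None else np.column_stack([onehot, covariates])

    beta_hat, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    batch_sizes = onehot.sum(axis=0)
    grand_mean = (batch_sizes / n_samp) @ beta_hat[:n_batches]
    resid = values.T - design @ beta_hat
    var_pooled = (resid**2).mean(axis=0)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    stand_mean = np.tile(grand_mean, (n_samp, 1))
    if covariates is not None:
        stand_mean = stand_mean + covariates @ beta_hat[n_batches:]
    z = (values.T - stand_mean) / np.sqrt(var_pooled)

    adjusted = z.copy()
    for b_idx, b in enumerate(batches):
        members = batch_codes == b
        nb = int(members.sum())
        zb = z[members]
        gamma_hat = zb.mean(axis=0)
        delta_hat = zb.var(axis=0, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        if d_var <= 0:
            a_prior, b_prior = 2.0, d_mean
        else:
            a_prior = (2 * d_var + d_mean**2) / d_var
            b_prior = (d_mean * d_var + d_mean**3) / d_var
        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            g_new = (nb * tau2 * gamma_hat + delta_star * gamma_bar) / (
                nb * tau2 + delta_star
            )
            sum2 = ((zb - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b_prior) / (nb / 2.0 + a_prior - 1.0)
            change = max(
                np.abs(g_new - gamma_star).max(initial=0.0),
                np.abs(d_new - delta_star).max(initial=0.0),
            )
            gamma_star, delta_star = g_new, d_new
            if change < conv:
                break
        adjusted[members] = (zb - gamma_star) / np.sqrt(delta_star)
    adjusted = adjusted * np.sqrt(var_pooled) + stand_mean
    return adjusted.T


def batch_harmonize(
    dataset: MethylationDataset,
    batch_column: str = "dataset_id",
    covariates: Sequence[str] = ("condition",),
) -> MethylationDataset:
    """Remove per-batch location/scale effects from a pooled beta matrix.

    Biological covariates (default: condition) are included in the model so
    balanced group differences are preserved. A single batch is returned
    unchanged. Output betas are clipped to [1e-6, 1 - 1e-6].
    """
    sheet = dataset.samples
    batch = sheet[batch_column].astype(str).to_numpy()
    labels = np.unique(batch)
    if labels.size < 2:
        return dataset
    values = dataset.betas.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("batch harmonization requires complete betas; impute first")
    counts = pd.Series(batch).value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"batches with <3 samples: {small}")
    for b in labels:
        members = batch == b
        zero_var = (values[:, members].std(axis=1) == 0).mean()
        if zero_var > 0.5:
            raise ValueError(
                f"batch {b!r} has zero variance for {zero_var:.0%} of CpGs"
            )
    cov = None
    if covariates:
        dummies = pd.get_dummies(sheet[list(covariates)].astype(str),
                                 drop_first=True)
        if dummies.shape[1]:
            cov = dummies.to_numpy(dtype=float)
    adjusted = _combat_adjust(values, batch, cov)
    adjusted = np.clip(adjusted, 1e-6, 1.0 - 1e-6)
    out = pd.DataFrame(adjusted, index=dataset.cpg_ids, columns=dataset.sample_ids)
    return MethylationDataset(out, sheet.copy(), dataset.dataset_id)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def mean_impute(betas: pd.DataFrame, reference_means: pd.Series) -> pd.DataFrame:
    """Replace missing entries with reference (training) means.

    Rows absent from the reference are an error: a model cannot score a CpG
    it has no training mean for.
    """
    missing_ref = betas.index.difference(reference_means.index)
    if len(missing_ref):
        raise ValueError(
            f"no reference mean for CpGs {list(missing_ref[:5])!r}"
        )
    filled = betas.apply(lambda row: row.fillna(reference_means[row.name]), axis=1)
    return filled


# ---------------------------------------------------------------------------
# clock model container
# ---------------------------------------------------------------------------

@dataclass
class ClockModel:
    """Sparse linear clock: CpG weights + intercept + imputation means.

    ``cpg_ids`` holds only nonzero-weight CpGs; ``imputation_means`` covers
    every CpG the model references. ``lambda_`` follows the glmnet
    parametrization of the elastic-net objective.
    """

    name: str
    family: str
    cpg_ids: List[str]
    weights: np.ndarray
    intercept: Optional[float]
    imputation_means: Dict[str, float]
    alpha: float
    lambda_: float
    n_folds: int
    seed: int
    lambda_rule: str = "min"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.family not in CLOCK_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.cpg_ids) != self.weights.size:
            raise ValueError("weight count does not match CpG list")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights")
        missing = [c for c in self.cpg_ids if c not in self.imputation_means]
        if missing:
            raise ValueError(f"imputation means missing for {missing[:5]!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "family": self.family,
            "cpg_ids": list(self.cpg_ids),
            "weights": [float(w) for w in self.weights],
            "intercept": None if self.intercept is None else float(self.intercept),
            "imputation_means": {k: float(v) for k, v in self.imputation_means.items()},
            "alpha": float(self.alpha),
            "lambda": float(self.lambda_),
            "n_folds": int(self.n_folds),
            "seed": int(self.seed),
            "lambda_rule": self.lambda_rule,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ClockModel":
        return cls(
            name=payload["name"],
            family=payload["family"],
            cpg_ids=list(payload["cpg_ids"]),
            weights=np.asarray(payload["weights"], dtype=float),
            intercept=payload["intercept"],
            imputation_means=dict(payload["imputation_means"]),
            alpha=payload["alpha"],
            lambda_=payload["lambda"],
            n_folds=payload["n_folds"],
            seed=payload["seed"],
            lambda_rule=payload.get("lambda_rule", "min"),
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _design_matrix(
    dataset: MethylationDataset, feature_cpgs: Sequence[str]
) -> Tuple[np.ndarray, pd.Series]:
    feats = list(feature_cpgs)
    betas = dataset.betas.reindex(feats)
    means = betas.mean(axis=1)
    if means.isna().any():
        bad = means.index[means.isna()][:5]
        raise ValueError(f"feature CpGs absent from training data: {list(bad)!r}")
    filled = betas.T.fillna(means).T
    return filled.to_numpy(dtype=float).T, means  # samples x features


def _cox_partial_loglik(coefs: np.ndarray, X: np.ndarray, time: np.ndarray,
                        event: np.ndarray) -> float:
    """Breslow log partial likelihood at fixed coefficients."""
    order = np.argsort(time, kind="stable")
    eta = X[order] @ coefs
    e_s = event[order].astype(bool)
    t_s = time[order]
    theta = np.exp(eta - eta.max())
    suffix = np.cumsum(theta[::-1])[::-1]
    first_idx = np.searchsorted(t_s, t_s, side="left")
    log_s0 = np.log(suffix[first_idx]) + eta.max()
    return float((eta[e_s] - log_s0[e_s]).sum())


def train_clock(
    dataset: MethylationDataset,
    outcome: str,
    feature_cpgs: Sequence[str],
    name: Optional[str] = None,
    family: Optional[str] = None,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    lambda_: Optional[float] = None,
    lambda_rule: str = "min",
    n_lambdas: int = 60,
) -> ClockModel:
    """Fit an elastic-net clock on the selected CpGs.

    outcome: ``senescence`` (binomial; senescent vs. control), ``age``
    (gaussian) or ``survival`` (Cox on survival_time/event). Features are
    mean-imputed and standardized internally; lambda is chosen by K-fold CV
    (fold assignment is a pure function of seed and n, stratified by class
    or event status) unless ``lambda_`` is given. Weights are returned on
    the raw beta scale.
    """
    outcome_family = {"senescence": "binomial", "age": "gaussian",
                      "survival": "cox"}
    if outcome not in outcome_family:
        raise ValueError(f"unknown outcome {outcome!r}")
    family = family or outcome_family[outcome]
    if family not in CLOCK_FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    if not feature_cpgs:
        raise ValueError("empty feature set")

    X_raw, means = _design_matrix(dataset, feature_cpgs)
    sd = X_raw.std(axis=0, ddof=0)
    keep = sd > 0
    feats = [c for c, k in zip(feature_cpgs, keep) if k]
    X = (X_raw[:, keep] - X_raw[:, keep].mean(axis=0)) / sd[keep]
    n = X.shape[0]
    sheet = dataset.samples

    if family == "binomial":
        y = (sheet["condition"] == "senescent").to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate outcome: single class")
        w_std, b0, lam = _fit_binomial(X, y, alpha, n_folds, seed, lambda_,
                                       lambda_rule, n_lambdas)
    elif family == "gaussian":
        y = sheet["age"].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError("age outcome missing for some training samples")
        if np.std(y) == 0:
            raise ValueError("degenerate outcome: constant age")
        w_std, b0, lam = _fit_gaussian(X, y, alpha, n_folds, seed, lambda_,
                                       lambda_rule, n_lambdas)
    else:
        time = sheet["survival_time"].to_numpy(dtype=float)
        event = sheet["event"].to_numpy(dtype=float)
        if np.isnan(time).any() or np.isnan(event).any():
            raise ValueError("survival outcome missing for some training samples")
        if event.sum() < 10:
            raise ValueError("need at least 10 events to train a Cox clock")
        w_std, b0, lam = _fit_cox(X, time, event, alpha, n_folds, seed, lambda_,
                                  lambda_rule, n_lambdas)

    # back-transform to the raw beta scale
    w_raw = np.zeros(len(feats))
    nz_sd = sd[keep]
    w_raw = w_std / nz_sd
    mean_keep = X_raw[:, keep].mean(axis=0)
    intercept = None
    if family != "cox":
        intercept = float(b0 - np.sum(w_std * mean_keep / nz_sd))
    nz = w_raw != 0
    kept_cpgs = [c for c, flag in zip(feats, nz) if flag]
    model = ClockModel(
        name=name or f"clock_{family}",
        family=family,
        cpg_ids=kept_cpgs,
        weights=w_raw[nz],
        intercept=intercept,
        imputation_means={c: float(means[c]) for c in kept_cpgs},
        alpha=alpha,
        lambda_=float(lam),
        n_folds=n_folds,
        seed=seed,
        lambda_rule=lambda_rule,
    )
    return model


def _lambda_grid(lmax: float, n_lambdas: int, lmin_ratio: float = 1e-3) -> np.ndarray:
    lmax = max(lmax, 1e-6)
    return np.geomspace(lmax, lmax * lmin_ratio, n_lambdas)


def _pick_lambda(grid: np.ndarray, cv_loss: np.ndarray, cv_se: np.ndarray,
                 rule: str) -> float:
    best = int(np.nanargmin(cv_loss))
    if rule == "min":
        return float(grid[best])
    bound = cv_loss[best] + cv_se[best]
    # largest lambda (grid is decreasing) whose loss is within 1 SE
    for i in range(len(grid)):
        if cv_loss[i] <= bound:
            return float(grid[i])
    return float(grid[best])


def _fit_gaussian(X, y, alpha, n_folds, seed, lambda_, rule, n_lambdas):
    from sklearn.linear_model import ElasticNetCV

    l1 = alpha
    if lambda_ is None:
        cv = KFold(n_folds, shuffle=True, random_state=seed)
        # looser tolerance for the path search; the final fit below is tight
        search = ElasticNetCV(l1_ratio=max(l1, 1e-6), alphas=n_lambdas,
                              cv=cv, max_iter=3000, tol=1e-4)
        search.fit(X, y)
        grid = np.asarray(search.alphas_)
        mse = search.mse_path_  # (n_alphas, n_folds)
        lam = _pick_lambda(grid, mse.mean(axis=1),
                           mse.std(axis=1, ddof=1) / np.sqrt(n_folds), rule)
    else:
        lam = float(lambda_)
    est = ElasticNet(alpha=lam, l1_ratio=l1, max_iter=100000, tol=1e-12)
    est.fit(X, y)
    return est.coef_.copy(), float(est.intercept_), lam


def _fit_binomial(X, y, alpha, n_folds, seed, lambda_, rule, n_lambdas):
    n = len(y)

    def make(lam, n_train, tol=1e-7, max_iter=20000):
        return LogisticRegression(
            solver="saga", l1_ratio=alpha, C=1.0 / max(lam * n_train, 1e-12),
            max_iter=max_iter, tol=tol, random_state=seed, warm_start=True,
        )

    if lambda_ is None:
        p0 = y.mean()
        lmax = np.abs(X.T @ (y - p0)).max() / (n * max(alpha, 0.01))
        # the near-unpenalized tail of the path is never optimal here and
        # dominates solver time, so the grid stops at lmax/100
        grid = _lambda_grid(lmax, n_lambdas, lmin_ratio=1e-2)
        skf = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
        losses = np.zeros((n_folds, len(grid)))
        for f, (tr, te) in enumerate(folds):
            # looser tolerance for the path search; the final fit is tight
            est = make(grid[0], len(tr), tol=1e-4, max_iter=2000)
            for g, lam in enumerate(grid):  # warm-started path, large -> small
                est.C = 1.0 / max(lam * len(tr), 1e-12)
                est.fit(X[tr], y[tr])
                p = np.clip(est.predict_proba(X[te])[:, 1], 1e-12, 1 - 1e-12)
                losses[f, g] = -np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
        lam = _pick_lambda(grid, losses.mean(axis=0),
                           losses.std(axis=0, ddof=1) / np.sqrt(n_folds), rule)
    else:
        lam = float(lambda_)
    est = make(lam, n)
    est.fit(X, y)
    return est.coef_.ravel().copy(), float(est.intercept_[0]), lam


def _fit_cox(X, time, event, alpha, n_folds, seed, lambda_, rule, n_lambdas):
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y_struct = Surv.from_arrays(event=event.astype(bool), time=time)
    if lambda_ is None:
        path = CoxnetSurvivalAnalysis(l1_ratio=max(alpha, 1e-6),
                                      n_alphas=n_lambdas, alpha_min_ratio=1e-3)
        path.fit(X, y_struct)
        grid = np.asarray(path.alphas_)
        skf = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, event.astype(int)))
        losses = np.full((n_folds, len(grid)), np.nan)
        for f, (tr, te) in enumerate(folds):
            est = CoxnetSurvivalAnalysis(l1_ratio=max(alpha, 1e-6), alphas=grid,
                                         alpha_min_ratio=1e-3)
            est.fit(X[tr], y_struct[tr])
            fitted = np.asarray(est.alphas_)
            for g, lam in enumerate(grid):
                j = int(np.argmin(np.abs(fitted - lam)))
                coefs = est.coef_[:, j]
                losses[f, g] = -_cox_partial_loglik(coefs, X[te], time[te], event[te])
        lam = _pick_lambda(grid, np.nanmean(losses, axis=0),
                           np.nanstd(losses, axis=0, ddof=1) / np.sqrt(n_folds), rule)
    else:
        lam = float(lambda_)
    est = CoxnetSurvivalAnalysis(l1_ratio=max(alpha, 1e-6),
                                 alphas=[lam], fit_baseline_model=False)
    est.fit(X, y_struct)
    return est.coef_[:, 0].copy(), None, lam


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score(model: ClockModel, dataset: MethylationDataset) -> pd.DataFrame:
    """Per-sample clock score: intercept + sum(w_i * beta_i).

    CpGs absent from the data, or missing for a sample, are imputed from
    the model's training means; scores are invariant to CpG row order. The
    binomial family additionally reports the inverse-logit probability.
    """
    means = pd.Series(model.imputation_means)
    betas = dataset.betas.reindex(model.cpg_ids)
    filled = betas.T.fillna(means).T
    values = filled.to_numpy(dtype=float)
    lp = model.weights @ values
    if model.intercept is not None:
        lp = lp + model.intercept
    out = pd.DataFrame({"sample_id": dataset.sample_ids, "score": lp})
    out = out.set_index("sample_id", drop=False)
    out.index.name = None
    if model.family == "binomial":
        out["probability"] = expit(lp)
    return out


# ---------------------------------------------------------------------------
# survival-stratified train/test split
# ---------------------------------------------------------------------------

def split_survival(
    dataset: MethylationDataset, test_fraction: float = 0.3, seed: int = 0
) -> Tuple[MethylationDataset, MethylationDataset]:
    """Seeded random split stratified by event status (default 70/30)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    sheet = dataset.samples
    event = sheet["event"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(sheet), dtype=bool)
    for value in np.unique(event):
        idx = np.flatnonzero(event == value)
        n_test = int(round(test_fraction * idx.size))
        chosen = rng.choice(idx, size=n_test, replace=False)
        test_mask[chosen] = True
    train = dataset.subset(sample_mask=pd.Series(~test_mask, index=sheet.index))
    test = dataset.subset(sample_mask=pd.Series(test_mask, index=sheet.index))
    return train, test
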