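"""Clock evaluation readouts.

Senescent-vs-control score differences (two-sample t, Welch by default),
age correlation, age-adjusted standardized hazard ratios of clock scores,
paired pre/post senolytic changes, CpG-level senescence-vs-senolytic effect
concordance, and truth-based recovery metrics. Comparisons are computed
within (dataset, cell line) strata, never pooled across batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import MethylationDataset, TruthTable
from .models import ClockModel, score
from .selection import scale_betas

#: significance tiers used on every heatmap-style table
SIGNIFICANCE_TIERS = ((1e-4, "***"), (1e-3, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for cutoff, mark in SIGNIFICANCE_TIERS:
        if p < cutoff:
            return mark
    return ""


def group_difference(
    scores: pd.Series,
    groups: pd.Series,
    positive: str = "senescent",
    reference: str = "control",
    pooled_var: bool = False,
) -> dict:
    """Mean score difference (positive group minus reference) with a
    two-sample t-test (Welch unless pooled_var)."""
    a = scores[groups == positive].to_numpy(dtype=float)
    b = scores[groups == reference].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=pooled_var)
        t, p = float(t), float(p)
    return {
        "mean_difference": diff,
        "t": t,
        "p": p,
        "n_positive": int(a.size),
        "n_reference": int(b.size),
        "stars": significance_stars(p),
    }


def age_correlation(scores: pd.Series, ages: pd.Series) -> dict:
    """Pearson correlation of clock score with chronological age."""
    joined = pd.concat([scores.rename("s"), ages.rename("a")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 samples")
    if joined["s"].std() == 0:
        return {"r": np.nan, "p": np.nan, "n": len(joined), "flagged": True}
    r, p = sps.pearsonr(joined["s"], joined["a"])
    return {"r": float(r), "p": float(p), "n": len(joined), "flagged": False}


def clock_mortality_hr(
    scores: pd.Series, survival: pd.DataFrame
) -> dict:
    """Age-adjusted Cox HR per 1 SD of clock score, with 95% CI.

    ``survival`` needs columns survival_time, event, age indexed by sample.
    """
    from lifelines import CoxPHFitter

    frame = survival[["survival_time", "event", "age"]].copy()
    frame["z_score"] = (scores - scores.mean()) / scores.std(ddof=1)
    frame = frame.dropna()
    if frame["event"].sum() < 10:
        raise ValueError("need at least 10 events")
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="survival_time", event_col="event")
    except Exception:
        return {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "flagged": True}
    coef = float(cph.params_["z_score"])
    se = float(cph.standard_errors_["z_score"])
    return {
        "hr": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - 1.959963984540054 * se)),
        "ci_high": float(np.exp(coef + 1.959963984540054 * se)),
        "p": float(cph.summary.loc["z_score", "p"]),
        "flagged": False,
    }


def senolytic_change(
    scores: pd.Series, samples: pd.DataFrame, pooled_var: bool = False
) -> dict:
    """Post-minus-pre mean score change under senolytic treatment.

    Paired t-test when pair_id is present for all samples, otherwise a
    two-sample (Welch) test. Sign convention: negative = the clock
    decreased after treatment.
    """
    timepoint = samples["timepoint"]
    pre_ids = samples.index[timepoint == "pre"]
    post_ids = samples.index[timepoint == "post"]
    if len(post_ids) == 0:
        raise ValueError("no post-treatment samples")
    if len(pre_ids) == 0:
        raise ValueError("no pre-treatment samples")
    paired = samples["pair_id"].notna().all()
    if paired:
        pre = scores[pre_ids].to_numpy(dtype=float)
        pairs = samples.loc[pre_ids, "pair_id"]
        post_by_pair = samples.loc[post_ids].set_index("pair_id")
        post = scores[post_by_pair.loc[pairs, "sample_id"]].to_numpy(dtype=float)
        delta = post - pre
        diff = float(delta.mean())
        if np.allclose(delta, 0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(post, pre)
            t, p = float(t), float(p)
        n = len(delta)
    else:
        res = group_difference(scores, timepoint, positive="post",
                               reference="pre", pooled_var=pooled_var)
        diff, t, p = res["mean_difference"], res["t"], res["p"]
        n = res["n_positive"]
    return {
        "mean_difference": diff,
        "t": t,
        "p": p,
        "n": int(n),
        "paired": bool(paired),
        "stars": significance_stars(p),
        "significant_decrease": bool(p < 0.05 and diff < 0),
    }


def effect_concordance(
    senescence_effects: pd.Series, senolytic_effects: pd.Series
) -> Tuple[pd.DataFrame, float]:
    """Per-CpG senescence vs. senolytic scaled effects and the fraction of
    CpGs whose senolytic change carries the same sign as their senescence
    change."""
    common = senescence_effects.index.intersection(senolytic_effects.index)
    if len(common) == 0:
        raise ValueError("disjoint CpG sets")
    table = pd.DataFrame(
        {
            "senescence_effect": senescence_effects[common],
            "senolytic_effect": senolytic_effects[common],
        }
    )
    table["sign_agreement"] = (
        np.sign(table["senescence_effect"]) == np.sign(table["senolytic_effect"])
    ) & (table["senolytic_effect"] != 0)
    agreement = float(table["sign_agreement"].mean())
    return table, agreement


def senolytic_cpg_effects(trial: MethylationDataset) -> pd.Series:
    """Scaled mean post-minus-pre difference per CpG (SD units of the
    pooled trial samples), the senolytic analogue of the senescence scaled
    mean difference."""
    scaled, _ = scale_betas(trial.betas)
    timepoint = trial.samples["timepoint"]
    post = scaled.loc[:, trial.samples.index[timepoint == "post"]].mean(axis=1)
    pre = scaled.loc[:, trial.samples.index[timepoint == "pre"]].mean(axis=1)
    return post - pre


def recovery_metrics(final_set: Set[str], truth: TruthTable) -> dict:
    """Sensitivity and empirical FDR of the final set against the planted
    concordant_all class."""
    target = set(truth.concordant)
    if len(target) == 0:
        return {"sensitivity": np.nan, "fdr": np.nan, "flagged": True,
                "n_final": len(final_set), "n_true": 0}
    if len(final_set) == 0:
        return {"sensitivity": 0.0, "fdr": np.nan, "flagged": True,
                "n_final": 0, "n_true": len(target)}
    tp = len(final_set & target)
    return {
        "sensitivity": tp / len(target),
        "fdr": (len(final_set) - tp) / len(final_set),
        "flagged": False,
        "n_final": len(final_set),
        "n_true": len(target),
    }


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Tabular evaluation results, one frame per readout family."""

    group_differences: pd.DataFrame = field(default_factory=pd.DataFrame)
    age_correlation: pd.DataFrame = field(default_factory=pd.DataFrame)
    clock_hr: pd.DataFrame = field(default_factory=pd.DataFrame)
    senolytic_changes: pd.DataFrame = field(default_factory=pd.DataFrame)
    effect_concordance: pd.DataFrame = field(default_factory=pd.DataFrame)
    recovery: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for frame in (self.group_differences, self.senolytic_changes):
            if len(frame) and "p" in frame:
                p = frame["p"].dropna()
                if ((p < 0) | (p > 1)).any():
                    raise ValueError("p-value outside [0, 1]")
        if len(self.clock_hr):
            ok = self.clock_hr.dropna(subset=["hr"])
            bad = (ok["hr"] < ok["ci_low"]) | (ok["hr"] > ok["ci_high"])
            if bad.any():
                raise ValueError("CI does not contain the HR point estimate")

    def save(self, out_dir) -> None:
        from pathlib import Path
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for attr in ("group_differences", "age_correlation", "clock_hr",
                     "senolytic_changes", "effect_concordance"):
            frame = getattr(self, attr)
            if len(frame):
                frame.to_csv(out / f"{attr}.tsv", sep="\t")
        summary = {
            "recovery": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                         for k, v in self.recovery.items()},
            "n_significant_clock_decreases": int(
                self.senolytic_changes["significant_decrease"].sum()
            ) if len(self.senolytic_changes) else 0,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))


def evaluate_clocks_on_experiment(
    clocks: Mapping[str, ClockModel],
    dataset: MethylationDataset,
    pooled_var: bool = False,
) -> pd.DataFrame:
    """Senescent-vs-control clock differences per (batch, cell line,
    inducer) stratum for every clock."""
    rows = []
    sheet = dataset.samples
    for clock_name, model in clocks.items():
        sc = score(model, dataset)["score"]
        for (batch, line), grp in sheet.groupby(["dataset_id", "cell_line"],
                                                sort=True):
            controls = grp.index[grp["condition"] == "control"]
            if len(controls) < 2:
                continue
            for inducer, sen_grp in grp[grp["condition"] == "senescent"].groupby(
                "inducer", sort=True
            ):
                if len(sen_grp) < 2:
                    continue
                ids = list(controls) + list(sen_grp.index)
                res = group_difference(
                    sc[ids], sheet.loc[ids, "condition"], pooled_var=pooled_var
                )
                rows.append({"clock": clock_name, "dataset": batch,
                             "cell_line": line, "inducer": inducer, **res})
    return pd.DataFrame(rows)
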