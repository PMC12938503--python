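"""CpG selection: from per-stratum senescence associations to the final
senescence / age / mortality concordant set.

The pipeline mirrors standard senescence-EWAS practice: per (dataset, cell
line) logistic associations of senescent status with scaled beta values,
inverse-variance fixed-effects meta-analysis across cell lines within each
inducer, Bonferroni-adjusted direction calls, a 2-of-3 inducer concordance
rule with raw-direction agreement in the remaining inducer, removal of
replication-tracking CpGs (biweight midcorrelation with passage number in
immortalized cells), then sign-concordance of each surviving CpG's age
slope and age-adjusted standardized log hazard ratio with its senescence
direction. A :class:`SelectionLedger` records the CpG set and count at
every stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import stats
from .datasets import MethylationDataset

INDUCER_NAMES = ("replicative", "dna_damage", "oncogene")


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def scale_betas(betas: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Index]:
    """Center each CpG and divide by its sample SD (ddof=1).

    Returns the standardized matrix and the index of constant CpGs, which
    are flagged (rows of NaN) rather than failing; idempotent on already
    scaled data.
    """
    values = betas.to_numpy(dtype=float)
    with warnings.catch_warnings():
        # all-NaN rows (previously flagged CpGs) are legitimate here
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=1, keepdims=True)
        sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    flagged = betas.index[(sd == 0).ravel() | np.isnan(sd).ravel()]
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (values - mean) / sd
    scaled[(sd == 0).ravel()] = np.nan
    return pd.DataFrame(scaled, index=betas.index, columns=betas.columns), flagged


# ---------------------------------------------------------------------------
# per-stratum senescence association
# ---------------------------------------------------------------------------

def senescence_association(
    dataset: MethylationDataset,
    inducer: str,
    cell_line: Optional[str] = None,
    batch: Optional[str] = None,
) -> pd.DataFrame:
    """Logistic regression of senescent status on scaled beta, per CpG.

    Controls and senescent samples of the given inducer (optionally within
    one cell line / batch) enter the model; senescent samples of other
    inducers are excluded. The coefficient sign is the direction of
    methylation change in senescence. Separated CpGs get a Firth-penalized,
    flagged fit. The scaled mean difference (senescent minus control, in SD
    units) is reported alongside for effect-size displays.
    """
    sheet = dataset.samples
    mask = pd.Series(False, index=sheet.index)
    is_ctrl = sheet["condition"] == "control"
    is_sen = (sheet["condition"] == "senescent") & (sheet["inducer"] == inducer)
    mask = is_ctrl | is_sen
    if cell_line is not None:
        mask &= sheet["cell_line"] == cell_line
    if batch is not None:
        mask &= sheet["dataset_id"] == batch
    sub = sheet[mask]
    y = (sub["condition"] == "senescent").to_numpy(dtype=float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError(
            f"need >=2 control and >=2 senescent samples for inducer={inducer!r}, "
            f"cell_line={cell_line!r}, batch={batch!r}"
        )
    betas = dataset.betas[sub.index]
    scaled, constant = scale_betas(betas)
    x = scaled.to_numpy()
    usable = ~betas.index.isin(constant)
    res = stats.logistic_by_feature(x[usable], y)
    out = pd.DataFrame(
        index=betas.index,
        data={
            "effect": np.nan, "se": np.nan, "p": np.nan,
            "scaled_mean_diff": np.nan, "flagged": True,
        },
    )
    out.loc[usable, "effect"] = res["effect"]
    out.loc[usable, "se"] = res["se"]
    out.loc[usable, "p"] = res["p"]
    out.loc[usable, "flagged"] = res["separation"]
    smd = x[:, y == 1].mean(axis=1) - x[:, y == 0].mean(axis=1)
    out["scaled_mean_diff"] = smd
    out["stratum"] = f"{batch or 'all'}/{cell_line or 'pooled'}"
    out["axis"] = f"senescence_{inducer}"
    return out


def senescence_strata(dataset: MethylationDataset, inducer: str) -> List[Tuple[str, str]]:
    """(batch, cell_line) pairs with enough controls and senescent samples."""
    sheet = dataset.samples
    out = []
    for (batch, line), grp in sheet.groupby(["dataset_id", "cell_line"], sort=True):
        n_sen = int(((grp["condition"] == "senescent")
                     & (grp["inducer"] == inducer)).sum())
        n_ctl = int((grp["condition"] == "control").sum())
        if n_sen >= 2 and n_ctl >= 2:
            out.append((batch, line))
    return out


def fixed_effect_meta(associations: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance pooled effect across per-stratum association tables.

    Strata with non-finite SE for a CpG are skipped for that CpG; CpGs with
    no usable stratum stay flagged. The scaled mean differences are pooled
    with the same logistic weights for display.
    """
    if len(associations) == 0:
        raise ValueError("need at least one stratum")
    idx = associations[0].index
    for a in associations[1:]:
        if not a.index.equals(idx):
            raise ValueError("association tables must share the CpG index")
    eff = np.vstack([a["effect"].to_numpy() for a in associations])
    ses = np.vstack([a["se"].to_numpy() for a in associations])
    smd = np.vstack([a["scaled_mean_diff"].to_numpy() for a in associations])
    pooled, pooled_se, p = stats.fixed_effect_meta(eff, ses)
    usable = np.isfinite(eff) & np.isfinite(ses) & (ses > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(usable, 1.0 / ses**2, 0.0)
        smd_pooled = (w * np.where(usable, smd, 0.0)).sum(axis=0) / w.sum(axis=0)
    out = pd.DataFrame(
        index=idx,
        data={
            "effect": pooled,
            "se": pooled_se,
            "p": p,
            "scaled_mean_diff": smd_pooled,
            "n_strata": usable.sum(axis=0),
            "flagged": ~np.isfinite(pooled),
        },
    )
    if "axis" in associations[0].columns:
        out["axis"] = associations[0]["axis"].iloc[0]
    return out


def adjust_pvalues(p, method: str = "bonferroni", m: Optional[int] = None):
    """Module-level re-export (Bonferroni with explicit universe size m,
    or Benjamini-Hochberg step-up)."""
    return stats.adjust_pvalues(np.asarray(p, dtype=float), method=method, m=m)


def classify_senescence_direction(
    meta: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "bonferroni",
    m: Optional[int] = None,
) -> pd.DataFrame:
    """Add adjusted p, significant direction (hyper/hypo/none) and raw
    direction columns to a meta-analysis table.

    direction = hyper if effect > 0 and p_adj < alpha, hypo if effect < 0
    and p_adj < alpha, else none. An effect of exactly 0 has raw direction
    none (it can never satisfy a concordance rule).
    """
    out = meta.copy()
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method=method, m=m)
    eff = out["effect"].to_numpy()
    raw = np.where(eff > 0, "hyper", np.where(eff < 0, "hypo", "none"))
    raw = np.where(np.isfinite(eff), raw, "none")
    sig = out["p_adj"].to_numpy() < alpha
    out["raw_direction"] = raw
    out["direction"] = np.where(sig, raw, "none")
    return out


# ---------------------------------------------------------------------------
# immortalization filter
# ---------------------------------------------------------------------------

def immortalization_association(series: MethylationDataset) -> pd.DataFrame:
    """Biweight midcorrelation of each CpG with passage number, with
    BH-adjusted p-values. Zero-MAD CpGs are flagged (not removable)."""
    passages = series.samples["passage"]
    if passages.isna().any():
        raise ValueError("immortalized series requires passage numbers")
    if passages.nunique() < 3:
        raise ValueError("need at least 3 distinct passages")
    x = series.betas.to_numpy(dtype=float)
    r, flagged = stats.bicor_by_feature(x, passages.to_numpy(dtype=float))
    p = stats.bicor_pvalue(r, n=x.shape[1])
    out = pd.DataFrame(index=series.cpg_ids,
                       data={"r": r, "p": p, "flagged": flagged})
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method="bh")
    return out


def apply_immortalization_threshold(
    assoc: pd.DataFrame, r_threshold: float = 0.3, alpha: float = 0.05
) -> Set[str]:
    """CpGs with |r| strictly above the threshold AND BH-adjusted p < alpha."""
    keep = (
        (assoc["r"].abs() > r_threshold)
        & (assoc["p_adj"] < alpha)
        & ~assoc["flagged"]
    )
    return set(assoc.index[keep.fillna(False)])


def immortalization_filter(
    series: MethylationDataset, r_threshold: float = 0.3, alpha: float = 0.05
) -> Set[str]:
    """Replication-tracking CpG set to remove from downstream analysis."""
    assoc = immortalization_association(series)
    return apply_immortalization_threshold(assoc, r_threshold, alpha)


# ---------------------------------------------------------------------------
# inducer concordance
# ---------------------------------------------------------------------------

def concordance_across_inducers(
    directions: Mapping[str, pd.DataFrame],
    min_significant: int = 2,
    immortalization: Optional[Set[str]] = None,
) -> Tuple[Set[str], Set[str]]:
    """Pan-senescence hyper and hypo sets.

    A CpG is selected for direction d when it is significantly d in at
    least ``min_significant`` inducers and its raw direction is also d in
    every remaining inducer. CpGs in the immortalization set are then
    excluded. ``min_significant=1`` is the relaxed criterion used when the
    usable CpG universe is small (e.g. cross-species arrays).
    """
    inducers = list(directions)
    idx = directions[inducers[0]].index
    removed = immortalization or set()
    out: Dict[str, Set[str]] = {}
    for d in ("hyper", "hypo"):
        sig = np.zeros(len(idx), dtype=int)
        all_raw = np.ones(len(idx), dtype=bool)
        for ind in inducers:
            tbl = directions[ind]
            sig += (tbl["direction"] == d).to_numpy(dtype=int)
            all_raw &= (tbl["raw_direction"] == d).to_numpy()
        chosen = (sig >= min_significant) & all_raw
        out[d] = set(idx[chosen]) - removed
    return out["hyper"], out["hypo"]


# ---------------------------------------------------------------------------
# in-vivo axes
# ---------------------------------------------------------------------------

def age_slope(
    cohort: MethylationDataset, cpgs: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Standardized age slope per CpG: regression of z-scored beta on
    z-scored age (equal to the Pearson correlation), with SE and p."""
    ages = cohort.samples["age"]
    if ages.isna().any():
        raise ValueError("aging cohort requires ages for all samples")
    if ages.nunique() < 2:
        raise ValueError("degenerate (constant) ages")
    betas = cohort.betas if cpgs is None else cohort.betas.loc[list(cpgs)]
    res = stats.standardized_slope(betas.to_numpy(dtype=float),
                                   ages.to_numpy(dtype=float))
    return pd.DataFrame(
        index=betas.index,
        data={"effect": res["effect"], "se": res["se"], "p": res["p"],
              "flagged": res["flagged"], "axis": "age"},
    )


def mortality_hazard(
    cohort: MethylationDataset, cpgs: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Age-adjusted Cox log hazard ratio per 1 SD of beta, per CpG."""
    sheet = cohort.samples
    for col in ("survival_time", "event", "age"):
        if sheet[col].isna().any():
            raise ValueError(f"mortality cohort requires complete {col}")
    event = sheet["event"].to_numpy(dtype=float)
    if event.sum() < 10:
        raise ValueError("need at least 10 events for the mortality axis")
    betas = cohort.betas if cpgs is None else cohort.betas.loc[list(cpgs)]
    scaled, constant = scale_betas(betas)
    usable = ~betas.index.isin(constant)
    z = scaled.to_numpy()[usable]
    ages = sheet["age"].to_numpy(dtype=float)
    z_age = (ages - ages.mean()) / ages.std(ddof=1)
    res = stats.cox_by_feature(z, z_age, sheet["survival_time"].to_numpy(dtype=float),
                               event)
    out = pd.DataFrame(
        index=betas.index,
        data={"effect": np.nan, "se": np.nan, "p": np.nan, "flagged": True},
    )
    out.loc[usable, "effect"] = res["effect"]
    out.loc[usable, "se"] = res["se"]
    out.loc[usable, "p"] = res["p"]
    out.loc[usable, "flagged"] = res["flagged"]
    out["axis"] = "mortality"
    return out


# ---------------------------------------------------------------------------
# ledger and the final directional intersection
# ---------------------------------------------------------------------------

@dataclass
class SelectionLedger:
    """Per-stage CpG sets and counts of the selection pipeline."""

    per_inducer: Dict[str, Dict[str, Set[str]]] = field(default_factory=dict)
    immortalization: Set[str] = field(default_factory=set)
    pan_hyper: Set[str] = field(default_factory=set)
    pan_hypo: Set[str] = field(default_factory=set)
    age_concordant: Set[str] = field(default_factory=set)
    age_discordant: Set[str] = field(default_factory=set)
    age_flagged: Set[str] = field(default_factory=set)
    mortality_discordant: Set[str] = field(default_factory=set)
    mortality_flagged: Set[str] = field(default_factory=set)
    final: Set[str] = field(default_factory=set)
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def pan_senescence(self) -> Set[str]:
        return self.pan_hyper | self.pan_hypo

    def stage_sets(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for ind, dd in self.per_inducer.items():
            for d, s in dd.items():
                out[f"{ind}_{d}"] = s
        out["immortalization"] = self.immortalization
        out["pan_hyper"] = self.pan_hyper
        out["pan_hypo"] = self.pan_hypo
        out["age_concordant"] = self.age_concordant
        out["final"] = self.final
        return out

    def validate(self) -> None:
        if not self.final <= self.age_concordant <= self.pan_senescence:
            raise ValueError("ledger stages are not nested")
        if self.pan_senescence & self.immortalization:
            raise ValueError("pan-senescence set overlaps immortalization set")
        if self.pan_hyper & self.pan_hypo:
            raise ValueError("hyper and hypo sets overlap")
        for ind, dd in self.per_inducer.items():
            if dd.get("hyper", set()) & dd.get("hypo", set()):
                raise ValueError(f"hyper/hypo overlap within inducer {ind}")

    def record_counts(self) -> None:
        for stage, s in self.stage_sets().items():
            self.counts[stage] = len(s)
        self.counts["pan_senescence"] = len(self.pan_senescence)
        self.counts["age_discordant"] = len(self.age_discordant)
        self.counts["age_flagged"] = len(self.age_flagged)
        self.counts["mortality_discordant"] = len(self.mortality_discordant)
        self.counts["mortality_flagged"] = len(self.mortality_flagged)


def directional_intersection(
    pan_hyper: Set[str],
    pan_hypo: Set[str],
    age: pd.DataFrame,
    mortality: pd.DataFrame,
) -> SelectionLedger:
    """Two-stage sign intersection.

    Stage 1 keeps pan-senescence CpGs whose age slope carries the same sign
    as their senescence direction (hyper -> slope > 0, hypo -> slope < 0);
    stage 2 keeps those whose age-adjusted log HR carries that sign too.
    Flagged CpGs (constant, non-converged) are reported separately, never
    silently kept.
    """
    ledger = SelectionLedger(pan_hyper=set(pan_hyper), pan_hypo=set(pan_hypo))
    age_eff = age["effect"]
    mort_eff = mortality["effect"]

    def split(cpgs: Set[str], eff: pd.Series, want_positive: bool):
        same, opposite, flagged = set(), set(), set()
        for c in cpgs:
            v = eff.get(c, np.nan)
            if not np.isfinite(v) or v == 0:
                flagged.add(c)
            elif (v > 0) == want_positive:
                same.add(c)
            else:
                opposite.add(c)
        return same, opposite, flagged

    hyper_same, hyper_opp, hyper_flag = split(set(pan_hyper), age_eff, True)
    hypo_same, hypo_opp, hypo_flag = split(set(pan_hypo), age_eff, False)
    ledger.age_concordant = hyper_same | hypo_same
    ledger.age_discordant = hyper_opp | hypo_opp
    ledger.age_flagged = hyper_flag | hypo_flag

    hyper_final, hyper_mopp, hyper_mflag = split(hyper_same, mort_eff, True)
    hypo_final, hypo_mopp, hypo_mflag = split(hypo_same, mort_eff, False)
    ledger.final = hyper_final | hypo_final
    ledger.mortality_discordant = hyper_mopp | hypo_mopp
    ledger.mortality_flagged = hyper_mflag | hypo_mflag
    ledger.record_counts()
    ledger.validate()
    return ledger


# ---------------------------------------------------------------------------
# one-call driver used by the pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionParams:
    alpha: float = 0.05
    r_threshold: float = 0.3
    min_significant: int = 2
    adjust_method: str = "bonferroni"
    use_raw_p: bool = False


def select_cpgs(
    senescence: MethylationDataset,
    immortalized: MethylationDataset,
    aging: MethylationDataset,
    mortality: MethylationDataset,
    params: SelectionParams = SelectionParams(),
) -> Tuple[SelectionLedger, Dict[str, pd.DataFrame]]:
    """Run the full selection pipeline and return the ledger plus the
    per-axis association tables (meta per inducer, immortalization, age,
    mortality)."""
    universe = senescence.cpg_ids
    m = len(universe)
    tables: Dict[str, pd.DataFrame] = {}
    directions: Dict[str, pd.DataFrame] = {}
    per_inducer_sets: Dict[str, Dict[str, Set[str]]] = {}
    for inducer in INDUCER_NAMES:
        strata = senescence_strata(senescence, inducer)
        if not strata:
            raise ValueError(f"no usable stratum for inducer {inducer!r}")
        per_stratum = [
            senescence_association(senescence, inducer, cell_line=line, batch=batch)
            for batch, line in strata
        ]
        meta = fixed_effect_meta(per_stratum)
        adjust = "none" if params.use_raw_p else params.adjust_method
        if adjust == "none":
            meta = meta.copy()
            meta["p_adj"] = meta["p"]
            eff = meta["effect"].to_numpy()
            raw = np.where(eff > 0, "hyper", np.where(eff < 0, "hypo", "none"))
            meta["raw_direction"] = np.where(np.isfinite(eff), raw, "none")
            meta["direction"] = np.where(meta["p_adj"] < params.alpha,
                                         meta["raw_direction"], "none")
        else:
            meta = classify_senescence_direction(
                meta, alpha=params.alpha, method=adjust, m=m
            )
        directions[inducer] = meta
        tables[f"senescence_{inducer}"] = meta
        per_inducer_sets[inducer] = {
            d: set(meta.index[meta["direction"] == d]) for d in ("hyper", "hypo")
        }

    immortal_assoc = immortalization_association(immortalized)
    tables["immortalization"] = immortal_assoc
    removed = apply_immortalization_threshold(
        immortal_assoc, r_threshold=params.r_threshold, alpha=params.alpha
    )

    pan_hyper, pan_hypo = concordance_across_inducers(
        directions, min_significant=params.min_significant, immortalization=removed
    )

    pan = sorted(pan_hyper | pan_hypo)
    age_tbl = age_slope(aging, cpgs=pan)
    tables["age"] = age_tbl
    age_sign = age_tbl["effect"]
    stage1 = [
        c for c in pan
        if np.isfinite(age_sign.get(c, np.nan)) and age_sign[c] != 0
        and ((age_sign[c] > 0) == (c in pan_hyper))
    ]
    mort_tbl = mortality_hazard(mortality, cpgs=stage1) if stage1 else \
        pd.DataFrame(columns=["effect", "se", "p", "flagged", "axis"])
    tables["mortality"] = mort_tbl

    ledger = directional_intersection(pan_hyper, pan_hypo, age_tbl, mort_tbl)
    ledger.per_inducer = per_inducer_sets
    ledger.immortalization = removed
    ledger.record_counts()
    return ledger, tables
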