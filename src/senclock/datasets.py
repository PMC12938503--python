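"""Core in-memory containers for methylation data.

A :class:`MethylationDataset` couples a CpG x sample beta matrix (values in
[0, 1], NaN = missing) with a sample sheet describing condition, senescence
inducer, cell line, passage, age, survival follow-up, and senolytic trial
arm/timepoint. It is the exchange object every pipeline stage consumes and
produces. A :class:`TruthTable` carries the planted per-CpG ground truth of
the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("control", "senescent", "immortalized")
INDUCERS = ("replicative", "dna_damage", "oncogene", "none")
ARMS = ("untreated", "senolytic")

#: canonical sample-sheet column order (TSV header)
SHEET_COLUMNS = [
    "sample_id",
    "dataset_id",
    "condition",
    "inducer",
    "cell_line",
    "passage",
    "age",
    "survival_time",
    "event",
    "arm",
    "timepoint",
    "pair_id",
]

#: CpG classes recognised by the synthetic generator / truth table
CPG_CLASSES = (
    "concordant_all",
    "pan_senescence_hyper",
    "pan_senescence_hypo",
    "inducer_specific",
    "replication_tracking",
    "age_only",
    "mortality_only",
    "discordant",
    "null",
)


@dataclass
class SampleInfo:
    """One row of a sample sheet.

    Optional phenotype fields are ``None`` when absent; ``event`` is 0/1.
    """

    sample_id: str
    dataset_id: str = ""
    condition: str = "control"
    inducer: str = "none"
    cell_line: str = ""
    passage: Optional[float] = None
    age: Optional[float] = None
    survival_time: Optional[float] = None
    event: Optional[int] = None
    arm: Optional[str] = None
    timepoint: Optional[str] = None
    pair_id: Optional[str] = None

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown condition {self.condition!r}"
            )
        if self.inducer not in INDUCERS:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown inducer {self.inducer!r}"
            )
        if self.condition == "senescent" and self.inducer == "none":
            raise ValueError(
                f"sample {self.sample_id!r}: senescent sample must name an inducer"
            )
        if self.event is not None:
            if self.event not in (0, 1):
                raise ValueError(
                    f"sample {self.sample_id!r}: event must be 0 or 1, got {self.event!r}"
                )
            if self.survival_time is None or not self.survival_time > 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: event present requires survival_time > 0"
                )
        if self.arm is not None and self.arm not in ARMS:
            raise ValueError(f"sample {self.sample_id!r}: unknown arm {self.arm!r}")

    def to_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_row(cls, row: dict) -> "SampleInfo":
        known = {f.name for f in fields(cls)}
        info = cls(**{k: v for k, v in row.items() if k in known})
        info.validate()
        return info


def samples_to_frame(samples: Sequence[SampleInfo]) -> pd.DataFrame:
    frame = pd.DataFrame([s.to_row() for s in samples], columns=SHEET_COLUMNS)
    return frame.set_index("sample_id", drop=False)


@dataclass
class MethylationDataset:
    """Beta matrix (CpGs x samples) plus the sample sheet.

    ``dataset_id`` labels the collection; per-sample ``dataset_id`` in the
    sheet doubles as the batch label when several series are pooled.
    """

    betas: pd.DataFrame
    samples: pd.DataFrame
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        if "sample_id" not in self.samples.columns:
            raise ValueError("sample sheet must carry a sample_id column")
        self.samples = self.samples.set_index(
            self.samples["sample_id"].astype(str), drop=False
        )
        self.samples.index.name = None
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        cpgs = self.betas.index
        samps = self.betas.columns
        if cpgs.duplicated().any():
            dup = cpgs[cpgs.duplicated()][0]
            raise ValueError(f"duplicate CpG id {dup!r}")
        if samps.duplicated().any():
            dup = samps[samps.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if list(samps) != list(self.samples.index):
            missing = set(samps).symmetric_difference(self.samples.index)
            raise ValueError(
                f"beta matrix columns and sample sheet disagree (mismatch: {sorted(missing)[:5]})"
            )
        values = self.betas.to_numpy(dtype=float)
        bad = (values < 0) | (values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value {values[i, j]!r} outside [0, 1] at CpG "
                f"{cpgs[i]!r}, sample {samps[j]!r}"
            )

    # -- convenience -----------------------------------------------------
    @property
    def cpg_ids(self) -> pd.Index:
        return self.betas.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.betas.columns

    @property
    def n_cpgs(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    def subset(
        self,
        cpgs: Optional[Iterable[str]] = None,
        sample_mask: Optional[pd.Series] = None,
    ) -> "MethylationDataset":
        """Restrict to given CpGs and/or a boolean mask over samples."""
        betas = self.betas
        sheet = self.samples
        if cpgs is not None:
            betas = betas.loc[list(cpgs)]
        if sample_mask is not None:
            keep = sheet.index[sample_mask.reindex(sheet.index, fill_value=False)]
            betas = betas[keep]
            sheet = sheet.loc[keep]
        return MethylationDataset(betas=betas.copy(), samples=sheet.copy(),
                                  dataset_id=self.dataset_id)

    def sample_infos(self) -> list:
        return [SampleInfo.from_row(r) for r in
                self.samples.where(self.samples.notna(), None).to_dict("records")]


TRUTH_COLUMNS = [
    "cpg_class",
    "sen_direction",
    "replicative_direction",
    "dna_damage_direction",
    "oncogene_direction",
    "age_direction",
    "mortality_direction",
    "age_slope",
    "log_hr",
]


@dataclass
class TruthTable:
    """Planted per-CpG ground truth: class label, per-axis direction
    (hyper/hypo/none), true standardized age slope and marginal log HR."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRUTH_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"truth table missing columns {missing}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate CpG id in truth table")
        bad = set(self.table["cpg_class"]) - set(CPG_CLASSES)
        if bad:
            raise ValueError(f"unknown CpG classes {sorted(bad)}")

    def cpgs_in_class(self, name: str) -> pd.Index:
        return self.table.index[self.table["cpg_class"] == name]

    @property
    def concordant(self) -> pd.Index:
        return self.cpgs_in_class("concordant_all")

    def class_counts(self) -> pd.Series:
        return self.table["cpg_class"].value_counts()
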