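"""Readers and writers for the on-disk exchange formats.

Everything is tab-separated UTF-8 text with "." decimals: beta matrices
(first column CpG id, header row of sample ids, empty cell = missing),
sample sheets (fixed header, see :data:`senclock.datasets.SHEET_COLUMNS`),
truth tables, selection ledgers, and clock models (JSON with a schema
version). Readers reject malformed input rather than coercing it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    SHEET_COLUMNS,
    TRUTH_COLUMNS,
    MethylationDataset,
    SampleInfo,
    TruthTable,
    samples_to_frame,
)

CLOCK_SCHEMA_VERSION = 1
_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# beta matrices
# ---------------------------------------------------------------------------

def write_beta_matrix(dataset: MethylationDataset, path) -> None:
    frame = dataset.betas.copy()
    frame.index.name = "cpg_id"
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="")


def read_beta_matrix(path, samples: pd.DataFrame | None = None,
                     dataset_id: str | None = None) -> MethylationDataset:
    """Read a beta-matrix TSV. If ``samples`` is omitted a minimal sheet of
    control samples is synthesised so the matrix can stand alone."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    values = frame.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    # distinguish genuinely empty cells from unparseable junk
    raw_blank = frame.isna() | frame.apply(lambda c: c.astype(str).str.strip() == "")
    junk = values.isna() & ~raw_blank
    if junk.to_numpy().any():
        i, j = np.argwhere(junk.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric beta {frame.iat[i, j]!r} at CpG "
            f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
        )
    out_of_range = (values < 0) | (values > 1)
    if out_of_range.to_numpy().any():
        i, j = np.argwhere(out_of_range.to_numpy())[0]
        raise ValueError(
            f"{path}: beta value {values.iat[i, j]} outside [0, 1] at CpG "
            f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
        )
    if dataset_id is None:
        dataset_id = Path(path).stem
    if samples is None:
        samples = samples_to_frame(
            [SampleInfo(sample_id=s, dataset_id=dataset_id) for s in values.columns]
        )
    return MethylationDataset(betas=values, samples=samples, dataset_id=dataset_id)


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def write_sample_sheet(samples: pd.DataFrame | Sequence[SampleInfo], path) -> None:
    if not isinstance(samples, pd.DataFrame):
        samples = samples_to_frame(list(samples))
    cols = SHEET_COLUMNS + [c for c in samples.columns if c not in SHEET_COLUMNS]
    samples.to_csv(path, sep="\t", index=False, columns=cols,
                   float_format=_FLOAT_FMT, na_rep="")


def read_sample_sheet(path) -> List[SampleInfo]:
    frame = read_sample_frame(path)
    records = frame.where(frame.notna(), None).to_dict("records")
    return [SampleInfo.from_row(r) for r in records]


def read_sample_frame(path) -> pd.DataFrame:
    """Sample sheet as a DataFrame (unknown columns preserved)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    if frame["sample_id"].duplicated().any():
        dup = frame["sample_id"][frame["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    for col in ("passage", "age", "survival_time"):
        frame[col] = pd.to_numeric(frame[col], errors="raise")
    frame["event"] = pd.to_numeric(frame["event"], errors="raise").astype("Int64")
    frame = frame.set_index(frame["sample_id"], drop=False)
    frame.index.name = None
    # validate every row through SampleInfo
    for row in frame.where(frame.notna(), None).to_dict("records"):
        info = SampleInfo.from_row(
            {k: (None if v is pd.NA else v) for k, v in row.items()}
        )
        info.validate()
    return frame


# ---------------------------------------------------------------------------
# truth tables
# ---------------------------------------------------------------------------

def write_truth_table(truth: TruthTable, path) -> None:
    out = truth.table.copy()
    out.index.name = "cpg_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="")


def read_truth_table(path) -> TruthTable:
    # keep_default_na=False: "null" is a legitimate class label
    frame = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    frame.index = frame.index.astype(str)
    for col in ("age_slope", "log_hr"):
        frame[col] = pd.to_numeric(frame[col].replace("", np.nan))
    missing = [c for c in TRUTH_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: truth table missing columns {missing}")
    return TruthTable(table=frame)


# ---------------------------------------------------------------------------
# CpG universe
# ---------------------------------------------------------------------------

def intersect_universe(datasets: Sequence[MethylationDataset]) -> list:
    """Sorted intersection of CpG ids across datasets (lexicographic).

    The shared universe is the set of probes present in every dataset; all
    association analyses are restricted to it so per-axis results are
    comparable CpG for CpG.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    common = set(datasets[0].cpg_ids)
    for ds in datasets[1:]:
        common &= set(ds.cpg_ids)
    if not common:
        sizes = {ds.dataset_id: ds.n_cpgs for ds in datasets}
        raise ValueError(f"empty CpG intersection; per-dataset sizes: {sizes}")
    return sorted(common)


# ---------------------------------------------------------------------------
# clock models (JSON)
# ---------------------------------------------------------------------------

def save_clock(model, path) -> None:
    from .models import ClockModel  # local import to avoid cycle

    if not isinstance(model, ClockModel):
        raise TypeError("save_clock expects a ClockModel")
    payload = model.to_dict()
    payload["schema_version"] = CLOCK_SCHEMA_VERSION
    Path(path).write_text(json.dumps(payload, indent=1))


def load_clock(path):
    from .models import ClockModel

    payload = json.loads(Path(path).read_text())
    version = payload.pop("schema_version", None)
    if version != CLOCK_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: clock schema version {version!r} unsupported "
            f"(expected {CLOCK_SCHEMA_VERSION})"
        )
    return ClockModel.from_dict(payload)


# ---------------------------------------------------------------------------
# selection ledgers
# ---------------------------------------------------------------------------

def write_ledger(ledger, out_dir) -> None:
    """Ledger -> <out_dir>/ledger.tsv (stage, count, cpg list file) plus one
    text file of CpG ids per stage."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for stage, cpgs in ledger.stage_sets().items():
        list_file = f"cpgs_{stage}.txt"
        (out_dir / list_file).write_text("\n".join(sorted(cpgs)) + "\n")
        rows.append({"stage": stage, "count": len(cpgs), "cpg_list": list_file})
    for stage, count in ledger.counts.items():
        if not any(r["stage"] == stage for r in rows):
            rows.append({"stage": stage, "count": count, "cpg_list": ""})
    pd.DataFrame(rows).to_csv(out_dir / "ledger.tsv", sep="\t", index=False)


def read_cpg_list(path) -> list:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
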