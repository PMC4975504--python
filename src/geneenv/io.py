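"""Readers and writers for cohort, lesion, and genotype-count tables.

Cohort tables are CSV/TSV with one row per subject; genotype strings are
normalized case-insensitively to GG/AG/AA.  Count tables are TSV with rows
``case``/``control`` and columns ``GG``/``AG``/``AA``.  Lesion tables are
CSV with columns subject_id, segment, stenosis_pct, acute_occlusion.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import GENOTYPES, GenotypeTable
from .gensini import normalize_segment

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_counts",
    "write_counts",
    "read_lesions",
    "write_lesions",
    "cohort_to_genotype_table",
    "write_json",
]

#: Columns a cohort table must provide.
COHORT_REQUIRED = ("subject_id", "status", "genotype")

_STATUS_MAP = {"case": 1, "control": 0, "1": 1, "0": 0}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def _normalize_genotype(value, row: int) -> str:
    s = str(value).strip().upper()
    if s == "GA":
        s = "AG"
    if s not in GENOTYPES:
        raise ValueError(f"row {row}: unknown genotype {value!r} (expected GG/AG/AA)")
    return s


def read_cohort(path) -> pd.DataFrame:
    """Read and validate an individual-level cohort table (CSV or TSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.empty:
        raise ValueError(f"{path}: cohort table has no data rows")
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise KeyError(f"{path}: cohort table missing columns {missing}")
    bad = df[list(COHORT_REQUIRED)].isna().any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # 1-based incl. header
        raise ValueError(f"{path}: missing values in required columns at file rows {rows}")
    df = df.copy()
    df["genotype"] = [
        _normalize_genotype(v, i + 2) for i, v in enumerate(df["genotype"])
    ]
    status = df["status"].astype(str).str.strip().str.lower().map(_STATUS_MAP)
    if status.isna().any():
        rows = (df.index[status.isna()] + 2).tolist()
        raise ValueError(f"{path}: unparseable status at file rows {rows} (use case/control or 1/0)")
    df["status"] = status.astype(int)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_counts(path, label: str = "") -> GenotypeTable:
    """Read a 2x3 genotype count table (TSV; rows case/control, columns GG/AG/AA)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: count table has no data rows")
    df.index = df.index.astype(str).str.strip().str.lower()
    df.columns = [str(c).strip().upper() for c in df.columns]
    missing_rows = {"case", "control"} - set(df.index)
    missing_cols = set(GENOTYPES) - set(df.columns)
    if missing_rows or missing_cols:
        raise KeyError(
            f"{path}: count table needs rows case/control and columns GG/AG/AA; "
            f"missing rows {sorted(missing_rows)}, columns {sorted(missing_cols)}"
        )
    counts = df.loc[["case", "control"], list(GENOTYPES)].to_numpy(dtype=np.int64)
    return GenotypeTable(counts, label=label or path.stem)


def write_counts(g: GenotypeTable, path) -> None:
    pd.DataFrame(g.counts, index=["case", "control"], columns=list(GENOTYPES)).to_csv(
        Path(path), sep="\t", index_label="group"
    )


def read_lesions(path) -> pd.DataFrame:
    """Read a lesion table (CSV: subject_id, segment, stenosis_pct, acute_occlusion)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.empty:
        raise ValueError(f"{path}: lesion table has no data rows")
    required = {"subject_id", "segment", "stenosis_pct", "acute_occlusion"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"{path}: lesion table missing columns {sorted(missing)}")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["segment"] = [normalize_segment(s) for s in df["segment"]]
    df["stenosis_pct"] = df["stenosis_pct"].astype(float)
    df["acute_occlusion"] = df["acute_occlusion"].astype(bool)
    return df


def write_lesions(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), index=False)


def cohort_to_genotype_table(df: pd.DataFrame, label: str = "") -> GenotypeTable:
    """Aggregate an individual-level cohort into 2x3 genotype counts."""
    counts = np.zeros((2, 3), dtype=np.int64)
    for i, status in enumerate((1, 0)):
        sub = df[df["status"] == status]
        for j, g in enumerate(GENOTYPES):
            counts[i, j] = int((sub["genotype"] == g).sum())
    return GenotypeTable(counts, label=label)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
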