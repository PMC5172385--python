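"""Tidy container for tract-averaged phenotypes plus covariates.

``TractMetricTable`` is the single currency of the pipeline: a long-format
table with one row per (subject, tract, hemisphere, measure), an attached
per-subject covariate table (age, sex, handedness, exclusion flags) and an
attached volumetric table (head-size-corrected volumes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .tracts import make_tract_catalog, normalize_tract_name

__all__ = ["TractMetricTable", "read_metric_table", "write_metric_table"]

LONG_COLUMNS = ["subject_id", "tract", "hemisphere", "measure", "value"]
REQUIRED_COVARIATES = ["age", "sex"]


def entry_label(tract: str, hemisphere: str) -> str:
    if hemisphere == "midline":
        return tract
    return f"{tract}_{'L' if hemisphere == 'left' else 'R'}"


def split_entry(entry: str) -> tuple[str, str]:
    if entry.endswith("_L"):
        return entry[:-2], "left"
    if entry.endswith("_R"):
        return entry[:-2], "right"
    return entry, "midline"


@dataclass
class TractMetricTable:
    """Long-format tract metric values with covariates and volumetrics.

    Parameters
    ----------
    long : DataFrame with columns subject_id, tract, hemisphere, measure, value.
    covariates : DataFrame indexed by subject_id (age, sex, handedness, ...).
    volumetrics : optional DataFrame indexed by subject_id.
    """

    long: pd.DataFrame
    covariates: pd.DataFrame
    volumetrics: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.long.columns]
        if missing:
            raise ValueError(f"long table missing columns: {missing}")
        for c in REQUIRED_COVARIATES:
            if c not in self.covariates.columns:
                raise ValueError(f"covariate table missing column: {c!r}")
        dup = self.long.duplicated(subset=LONG_COLUMNS[:4])
        if dup.any():
            rows = self.long.loc[dup, LONG_COLUMNS[:4]].head()
            raise ValueError(f"duplicate (subject, tract, hemisphere, measure) rows:\n{rows}")

    @property
    def measures(self) -> list[str]:
        return sorted(self.long["measure"].unique())

    @property
    def subjects(self) -> pd.Index:
        return self.covariates.index

    def wide(self, measure: str, entries: Optional[Iterable[str]] = None) -> pd.DataFrame:
        """Subjects x tract-entry matrix for one measure (columns e.g. SLF_L)."""
        sub = self.long[self.long["measure"] == measure]
        if sub.empty:
            raise ValueError(f"measure {measure!r} not present")
        col = sub["tract"].where(
            sub["hemisphere"] == "midline",
            sub["tract"] + "_" + sub["hemisphere"].map({"left": "L", "right": "R"}),
        )
        w = sub.assign(entry=col).pivot(index="subject_id", columns="entry", values="value")
        w = w.reindex(self.covariates.index)
        if entries is not None:
            entries = list(entries)
            absent = [e for e in entries if e not in w.columns]
            if absent:
                raise ValueError(f"entries not in table: {absent}")
            w = w[entries]
        return w

    def subset_subjects(self, subject_ids: Iterable[str]) -> "TractMetricTable":
        ids = pd.Index(subject_ids)
        return TractMetricTable(
            long=self.long[self.long["subject_id"].isin(ids)].reset_index(drop=True),
            covariates=self.covariates.loc[ids],
            volumetrics=None if self.volumetrics is None else self.volumetrics.loc[ids],
        )

    # ------------------------------------------------------------------ I/O
    def write(self, directory: str | Path, manifest: Optional[dict] = None) -> None:
        """Write values/covariates/volumetrics TSVs plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.long.to_csv(directory / "tract_values.tsv", sep="\t", index=False)
        self.covariates.rename_axis("subject_id").to_csv(directory / "covariates.tsv", sep="\t")
        if self.volumetrics is not None:
            self.volumetrics.rename_axis("subject_id").to_csv(directory / "volumetrics.tsv", sep="\t")
        meta = {"n_subjects": int(len(self.covariates)), "measures": self.measures}
        if manifest:
            meta.update(manifest)
        (directory / "manifest.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, directory: str | Path) -> "TractMetricTable":
        directory = Path(directory)
        long = read_metric_table(directory / "tract_values.tsv")
        cov = pd.read_csv(directory / "covariates.tsv", sep="\t", index_col="subject_id")
        vol_path = directory / "volumetrics.tsv"
        vol = pd.read_csv(vol_path, sep="\t", index_col="subject_id") if vol_path.exists() else None
        cov.index = cov.index.astype(str)
        if vol is not None:
            vol.index = vol.index.astype(str)
        return cls(long=long, covariates=cov, volumetrics=vol)


def read_metric_table(path: str | Path) -> pd.DataFrame:
    """Read a tidy tract-values file, validating tract names against the catalog.

    Accepts documented aliases ("Forceps minor" -> FMin); raises on unknown
    tract names, malformed numeric cells (with the row number) and duplicate
    (subject, tract, hemisphere, measure) rows.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[LONG_COLUMNS].copy()
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna() & (df["value"].str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(f"{path}: malformed numeric value {df['value'][bad].iloc[0]!r} at line {row}")
    df["value"] = values
    df["tract"] = [normalize_tract_name(t) for t in df["tract"]]
    valid_hemi = {"left", "right", "midline"}
    bad_hemi = set(df["hemisphere"]) - valid_hemi
    if bad_hemi:
        raise ValueError(f"{path}: unknown hemisphere labels {sorted(bad_hemi)}")
    midline = {t.name for t in make_tract_catalog() if t.laterality == "midline"}
    wrong = df[(df["tract"].isin(midline)) != (df["hemisphere"] == "midline")]
    if len(wrong):
        raise ValueError(f"{path}: hemisphere label inconsistent with tract laterality:\n{wrong.head()}")
    if df.duplicated(subset=LONG_COLUMNS[:4]).any():
        raise ValueError(f"{path}: duplicate (subject, tract, hemisphere, measure) rows")
    df["subject_id"] = df["subject_id"].astype(str)
    return df.reset_index(drop=True)


def write_metric_table(table: TractMetricTable, directory: str | Path, manifest: Optional[dict] = None) -> None:
    table.write(directory, manifest=manifest)
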