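"""Reading and writing of expression matrices, sample sheets and reports.

The exchange formats are plain TSV (GEO series-matrix files are TSV-like):

* expression matrix — header ``mir_id<TAB>sample ...``, one row per miR,
  non-negative decimal intensities;
* sample sheet — header ``sample_id  strain  treatment  day`` with treatment
  one of ``naive``/``sham``/``IRI`` and day a non-negative integer;
* analysis report — JSON; PC coordinates — TSV with columns
  ``series  day  pc1..pck``.

This module validates but performs no computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "TREATMENTS",
    "ExpressionMatrix",
    "SampleSheet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_report",
    "read_report",
    "write_coordinates",
]

TREATMENTS = ("naive", "sham", "IRI")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Raw intensity matrix: rows are miRs, columns are samples.

    Values are arbitrary fluorescence units; all must be finite and >= 0.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate miR IDs: {dups}")
        if df.columns.duplicated().any():
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample IDs: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at miR {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative intensity at miR {df.index[r]!r}, sample {df.columns[c]!r}"
            )

    @property
    def mir_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_mirs(self, mir_ids) -> "ExpressionMatrix":
        missing = [m for m in mir_ids if m not in self.data.index]
        if missing:
            raise ValidationError(f"unknown miR IDs: {missing}")
        return ExpressionMatrix(self.data.loc[list(mir_ids)])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample IDs: {missing}")
        return ExpressionMatrix(self.data[list(sample_ids)])


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample annotation: strain, treatment and day post-surgery.

    Exactly one naive sample is required per strain; it serves as the day-0
    reference point for both treatment arms of that strain.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        required = ["sample_id", "strain", "treatment", "day"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("sample sheet is empty")
        if df["sample_id"].duplicated().any():
            dups = sorted(df["sample_id"][df["sample_id"].duplicated()])
            raise ValidationError(f"duplicate sample IDs: {dups}")
        bad = sorted(set(df["treatment"]) - set(TREATMENTS))
        if bad:
            raise ValidationError(
                f"unknown treatment labels {bad}; expected one of {list(TREATMENTS)}"
            )
        days = df["day"]
        if not np.issubdtype(days.dtype, np.integer):
            try:
                as_int = days.astype(int)
            except (TypeError, ValueError) as exc:
                raise ValidationError("days must be integers") from exc
            if not (as_int == days.astype(float)).all():
                raise ValidationError("days must be integers")
            object.__setattr__(self, "data", df.assign(day=as_int))
            df = self.data
        if (df["day"] < 0).any():
            raise ValidationError("days must be non-negative")
        for strain, grp in df.groupby("strain"):
            naive = grp[grp["treatment"] == "naive"]
            if len(naive) != 1:
                raise ValidationError(
                    f"strain {strain!r} must have exactly one naive sample, "
                    f"found {len(naive)}"
                )
            if int(naive["day"].iloc[0]) != 0:
                raise ValidationError(
                    f"naive sample of strain {strain!r} must be day 0"
                )
            for treatment, arm in grp.groupby("treatment"):
                if arm["day"].duplicated().any():
                    raise ValidationError(
                        f"duplicate days within arm ({strain}, {treatment})"
                    )

    @property
    def strains(self) -> list[str]:
        return sorted(self.data["strain"].unique())

    def naive_sample(self, strain: str) -> str:
        df = self.data
        row = df[(df["strain"] == strain) & (df["treatment"] == "naive")]
        if len(row) == 0:
            raise ValidationError(f"no naive sample for strain {strain!r}")
        return str(row["sample_id"].iloc[0])

    def samples_for(self, strain: str, treatment: str) -> pd.DataFrame:
        """Rows for one (strain, treatment) arm, sorted by day ascending."""
        df = self.data
        sel = df[(df["strain"] == strain) & (df["treatment"] == treatment)]
        return sel.sort_values("day").reset_index(drop=True)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Parse a TSV expression matrix (first column miR ID, header sample IDs)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found (missing header?)")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at miR "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at miR {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    try:
        return ExpressionMatrix(numeric.astype(float))
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "mir_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_sheet(path) -> SampleSheet:
    """Parse a TSV sample sheet with columns sample_id, strain, treatment, day."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "strain": str,
                                                "treatment": str})
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: sample sheet is empty") from exc
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(report: dict, path) -> None:
    """Write an analysis report as JSON (numpy types converted in place)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_to_jsonable(report), fh, indent=2)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_coordinates(projections, path) -> None:
    """Export PC coordinates as TSV: series, day, pc1..pck."""
    rows = []
    for proj in projections:
        for day, coords in zip(proj.days, np.atleast_2d(proj.coordinates)):
            row = {"series": proj.label, "day": day}
            row.update({f"pc{i + 1}": float(v) for i, v in enumerate(coords)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
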