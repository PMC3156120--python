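"""Normalization chain and digital knockout.

Raw microarray intensities below 200 are considered unreliable, so every
value is floored at 200 before any ratio is formed.  miRs whose mean raw
intensity over the samples entering an analysis stays below 200 are dropped
entirely.  Each retained miR is then expressed as the natural log of its
floored intensity over the floored intensity in the strain's naive (day-0)
kidney; a miR that never clears the floor therefore carries the value 0 at
every time point.

A "digital knockout" removes the contribution of a chosen miR set by zeroing
its normalized (log-ratio) values at every time point before PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import ExpressionMatrix, SampleSheet

__all__ = [
    "NormalizedSeries",
    "floor_intensities",
    "filter_by_mean",
    "normalize_series",
    "digital_knockout",
]

DEFAULT_FLOOR = 200.0


@dataclass(frozen=True)
class NormalizedSeries:
    """One (strain, treatment) arm as log-ratio vectors ordered by day.

    The naive reference is included as day 0, so its own vector is zero.
    """

    strain: str
    treatment: str
    days: tuple
    vectors: np.ndarray  # (n_days, n_mirs)
    mir_ids: tuple
    reference_id: str

    @property
    def label(self) -> str:
        return f"{self.strain}/{self.treatment}"


def floor_intensities(matrix: ExpressionMatrix, floor: float = DEFAULT_FLOOR) -> ExpressionMatrix:
    """Clip every intensity from below at ``floor`` (elementwise max)."""
    if floor <= 0:
        raise ValidationError(f"floor must be > 0, got {floor}")
    return ExpressionMatrix(matrix.data.clip(lower=floor))


def filter_by_mean(
    matrix: ExpressionMatrix,
    threshold: float = DEFAULT_FLOOR,
    sample_subset=None,
) -> ExpressionMatrix:
    """Retain miRs whose mean raw intensity over ``sample_subset`` is >= threshold.

    Row order is preserved.  ``sample_subset=None`` uses all samples.
    """
    if sample_subset is None:
        sub = matrix.data
    else:
        sample_subset = list(sample_subset)
        if not sample_subset:
            raise ValidationError("sample_subset must be non-empty")
        missing = [s for s in sample_subset if s not in matrix.data.columns]
        if missing:
            raise ValidationError(f"unknown sample IDs in subset: {missing}")
        sub = matrix.data[sample_subset]
    keep = sub.mean(axis=1) >= threshold
    if not keep.any():
        raise ValidationError(
            f"mean filter at threshold {threshold} removed every miR"
        )
    return ExpressionMatrix(matrix.data.loc[keep])


def normalize_series(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    strain: str,
    treatment: str,
    floor: float = DEFAULT_FLOOR,
) -> NormalizedSeries:
    """Log-ratio series for one arm: w_day = ln(max(x_day, floor)/max(x_naive, floor)).

    Days are sorted ascending and the naive reference is prepended as day 0
    (its vector is identically zero by construction).
    """
    if floor <= 0:
        raise ValidationError(f"floor must be > 0, got {floor}")
    if treatment == "naive":
        raise ValidationError("normalize_series expects a sham or IRI arm")
    arm = sheet.samples_for(strain, treatment)
    if len(arm) == 0:
        raise ValidationError(f"no samples for ({strain!r}, {treatment!r})")
    ref_id = sheet.naive_sample(strain)
    sample_ids = [ref_id] + [str(s) for s in arm["sample_id"]]
    missing = [s for s in sample_ids if s not in matrix.data.columns]
    if missing:
        raise ValidationError(f"samples missing from expression matrix: {missing}")
    days = (0,) + tuple(int(d) for d in arm["day"])
    if 0 in set(arm["day"].tolist()):
        raise ValidationError(
            f"arm ({strain}, {treatment}) already contains day 0; the naive "
            "sample is the only day-0 point"
        )
    floored = matrix.data[sample_ids].clip(lower=floor)
    ref = floored[ref_id]
    w = np.log(floored.div(ref, axis=0)).to_numpy(dtype=float).T  # (n_days, n_mirs)
    return NormalizedSeries(
        strain=strain,
        treatment=treatment,
        days=days,
        vectors=w,
        mir_ids=tuple(matrix.mir_ids),
        reference_id=ref_id,
    )


def digital_knockout(series, knockout_set):
    """Zero the normalized values of every miR in ``knockout_set``.

    Accepts a single :class:`NormalizedSeries` or a list of them; returns the
    same shape.  Unknown miR IDs raise a :class:`ValidationError` listing them.
    """
    if isinstance(series, (list, tuple)):
        return type(series)(digital_knockout(s, knockout_set) for s in series)
    knockout_set = list(knockout_set)
    if not knockout_set:
        return series
    index = {m: i for i, m in enumerate(series.mir_ids)}
    unknown = [m for m in knockout_set if m not in index]
    if unknown:
        raise ValidationError(f"unknown miR IDs in knockout set: {unknown}")
    vectors = series.vectors.copy()
    cols = [index[m] for m in knockout_set]
    vectors[:, cols] = 0.0
    return replace(series, vectors=vectors)
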