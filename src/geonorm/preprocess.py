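"""Outlier flooring and per-experiment rescaling.

Scanner saturation and hybridization artefacts can leave a handful of
probes orders of magnitude above everything else in an experiment.  Left
alone, such spikes distort both the linear rescaling and the averaged
reference distribution used for quantile normalization.  Flooring caps
them: in each experiment the top 0.1% of non-missing values are replaced by
the minimum value within that top slice.  Each experiment column is then
linearly mapped onto a common 0-10,000 range so that intensities from
different platforms share a scale before quantile normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, StateError
from .matrix import ExpressionMatrix

DEFAULT_FLOOR_FRACTION = 0.001
DEFAULT_RANGE = (0.0, 10000.0)


@dataclass
class FlooringRecord:
    """What flooring did to one experiment column."""

    experiment_id: str
    n_floored: int          # ceil(fraction * n_non_missing), always >= 1
    flooring_value: float   # minimum of the top slice == post-floor column max


def floor_outliers(
    column: np.ndarray,
    fraction: float = DEFAULT_FLOOR_FRACTION,
    experiment_id: str = "",
) -> tuple[np.ndarray, FlooringRecord]:
    """Cap the top ``ceil(fraction * n)`` values of one experiment column.

    The flooring value is the minimum among the top slice; every value
    above it is replaced by it, so the post-floor column maximum equals the
    flooring value.  Missing values are excluded from ``n`` and untouched.

    Raises
    ------
    ParameterError
        If ``fraction`` is outside (0, 1).
    ValueError
        If the column has no non-missing value.
    """
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"floor fraction must be in (0, 1), got {fraction}")
    column = np.asarray(column, dtype=float)
    present = ~np.isnan(column)
    n = int(present.sum())
    if n == 0:
        raise ValueError("column has no non-missing values")
    k = max(1, math.ceil(fraction * n))
    values = column[present]
    # flooring value = k-th largest value = min of the top-k slice
    flooring_value = float(np.partition(values, n - k)[n - k])
    out = column.copy()
    above = present & (column > flooring_value)
    out[above] = flooring_value
    return out, FlooringRecord(experiment_id, k, flooring_value)


def rescale(
    column: np.ndarray,
    lo: float = DEFAULT_RANGE[0],
    hi: float = DEFAULT_RANGE[1],
) -> np.ndarray:
    """Linearly map one experiment column onto ``[lo, hi]``.

    ``v -> lo + (v - min) * (hi - lo) / (max - min)`` over non-missing
    values; the output minimum is exactly ``lo`` and maximum exactly ``hi``.

    Raises
    ------
    ValueError
        ``degenerate-range`` when the column has fewer than two distinct
        non-missing values (such a dataset should already have failed QC).
    """
    if not hi > lo:
        raise ParameterError(f"invalid range [{lo}, {hi}]")
    column = np.asarray(column, dtype=float)
    present = ~np.isnan(column)
    values = column[present]
    if values.size < 2 or np.min(values) == np.max(values):
        raise ValueError("degenerate-range: column has < 2 distinct values")
    vmin, vmax = float(np.min(values)), float(np.max(values))
    out = column.copy()
    out[present] = lo + (values - vmin) * (hi - lo) / (vmax - vmin)
    # guard endpoint rounding so min/max land exactly on lo/hi
    out[present & (column == vmin)] = lo
    out[present & (column == vmax)] = hi
    return out


def scale_matrix(
    matrix: ExpressionMatrix,
    fraction: float = DEFAULT_FLOOR_FRACTION,
    lo: float = DEFAULT_RANGE[0],
    hi: float = DEFAULT_RANGE[1],
) -> tuple[ExpressionMatrix, list[FlooringRecord]]:
    """Floor then rescale every experiment column of a raw matrix.

    Returns the scaled matrix (state ``scaled``) and per-experiment
    flooring records.
    """
    if matrix.state != "raw":
        raise StateError(f"scale_matrix expects a raw matrix, got {matrix.state!r}")
    values = matrix.values.copy()
    records = []
    for j, exp_id in enumerate(matrix.experiment_ids):
        col, record = floor_outliers(values[:, j], fraction, exp_id)
        values[:, j] = rescale(col, lo, hi)
        records.append(record)
    return matrix.with_values(values, "scaled"), records


def write_flooring_log(records: list[FlooringRecord], sink) -> None:
    """Write flooring records as a TSV (experiment, n_floored, flooring_value)."""
    fh, close = (open(sink, "wt", encoding="utf-8"), True) if isinstance(
        sink, str
    ) else (sink, False)
    try:
        fh.write("experiment_id\tn_floored\tflooring_value\n")
        for r in records:
            fh.write(f"{r.experiment_id}\t{r.n_floored}\t{r.flooring_value:.6g}\n")
    finally:
        if close:
            fh.close()
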