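"""Mean/median-ratio quality control.

Healthy one-color microarray data is approximately lognormal: a pronounced
normal peak of unexpressed (noise-level) genes at low intensities with
expressed genes spread across a long right tail.  That shape forces the
dataset mean to exceed its median, so the mean/median (MM) ratio is a
cheap, distribution-level quality screen: a ratio near 1 signals symmetric
(corrupted, pre-transformed, e.g. log-scale) data.  Datasets with zero
mean or median, negative values, or an MM ratio at or below the threshold
(default 1.2) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_MM_THRESHOLD = 1.2


@dataclass
class QCReport:
    """Per-dataset QC outcome; ``reason`` is empty when passed."""

    dataset_id: str
    mean: float
    median: float
    mm_ratio: float
    passed: bool
    reason: str = ""


def qc_dataset(
    grid: np.ndarray,
    threshold: float = DEFAULT_MM_THRESHOLD,
    dataset_id: str = "",
) -> QCReport:
    """Screen one dataset's gene x sample grid.

    Mean and median are pooled over all non-missing values of the dataset.
    Failure reasons, checked in order: ``empty`` (no non-missing values),
    ``negative-values``, ``zero-mean``, ``zero-median``, ``mm-ratio``
    (ratio <= threshold).
    """
    values = np.asarray(grid, dtype=float).ravel()
    values = values[~np.isnan(values)]
    if values.size == 0:
        return QCReport(dataset_id, np.nan, np.nan, np.nan, False, "empty")
    mean = float(np.mean(values))
    median = float(np.median(values))
    if np.any(values < 0):
        ratio = mean / median if median != 0 else np.nan
        return QCReport(dataset_id, mean, median, ratio, False, "negative-values")
    if mean == 0:
        return QCReport(dataset_id, mean, median, np.nan, False, "zero-mean")
    if median == 0:
        return QCReport(dataset_id, mean, median, np.nan, False, "zero-median")
    ratio = mean / median
    if ratio <= threshold:
        return QCReport(dataset_id, mean, median, ratio, False, "mm-ratio")
    return QCReport(dataset_id, mean, median, ratio, True, "")


def mm_histogram(
    reports: list[QCReport], bins=20
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bin MM ratios across datasets (QC pass/fail status is ignored).

    Parameters
    ----------
    reports : list of QCReport
        At least one report.
    bins : int or array of bin edges
        Passed through to :func:`numpy.histogram`.

    Returns
    -------
    (counts, bin_edges, median_ratio)
        ``median_ratio`` is the median MM ratio over reports with a
        defined ratio.
    """
    if not reports:
        raise ValueError("mm_histogram requires at least one report")
    ratios = np.array([r.mm_ratio for r in reports], dtype=float)
    ratios = ratios[~np.isnan(ratios)]
    counts, edges = np.histogram(ratios, bins=bins)
    median_ratio = float(np.median(ratios)) if ratios.size else np.nan
    return counts, edges, median_ratio


def write_qc_report(reports: list[QCReport], sink) -> None:
    """Write reports as a TSV (dataset_id, mean, median, mm_ratio, passed, reason)."""
    fh, close = (open(sink, "wt", encoding="utf-8"), True) if isinstance(
        sink, str
    ) else (sink, False)
    try:
        fh.write("dataset_id\tmean\tmedian\tmm_ratio\tpassed\treason\n")
        for r in reports:
            fh.write(
                f"{r.dataset_id}\t{r.mean:.6g}\t{r.median:.6g}\t{r.mm_ratio:.6g}\t"
                f"{int(r.passed)}\t{r.reason}\n"
            )
    finally:
        if close:
            fh.close()
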