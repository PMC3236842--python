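"""Quantile normalization against a shared average reference distribution.

Quantile normalization forces every experiment column onto one common value
distribution while preserving each column's internal rank order.  The
reference is the positionwise mean of the sorted columns ("an average
distribution over all experiments"); each value is then replaced by the
reference value at its within-column rank.

Columns may carry missing values (platforms differ in gene coverage), so
both directions use interpolated quantile mapping: a column with ``n``
non-missing values contributes its sorted values interpolated onto the
reference grid, and its ordinal rank ``j`` maps back to quantile position
``(j - 0.5) / n`` on the reference index scale.  With no missing values
this reduces exactly to classical quantile normalization.  Ties receive
the mean of their tied ranks' reference values.
"""

from __future__ import annotations

import numpy as np

from .errors import StateError
from .matrix import ExpressionMatrix


def _rank_positions(n: int, n_ref: int) -> np.ndarray:
    """Reference-index positions of ordinal ranks 1..n of an n-value column."""
    p = (np.arange(1, n + 1) - 0.5) / n
    return np.clip(p * n_ref - 0.5, 0.0, n_ref - 1.0)


def reference_distribution(values: np.ndarray) -> np.ndarray:
    """Positionwise mean of sorted columns, interpolated to the gene count.

    Returns a non-decreasing vector of length ``n_genes``.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_exps = values.shape
    grid = np.zeros(n_genes)
    for j in range(n_exps):
        col = values[:, j]
        col = np.sort(col[~np.isnan(col)])
        n = col.size
        if n < 2:
            raise ValueError(f"column {j} has fewer than 2 non-missing values")
        pos = _rank_positions(n_genes, n)
        grid += np.interp(pos, np.arange(n), col)
    return grid / n_exps


def _map_column(col: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace one column's values by reference values at their ranks."""
    out = col.copy()
    present = ~np.isnan(col)
    v = col[present]
    n = v.size
    order = np.argsort(v, kind="mergesort")
    sorted_v = v[order]
    mapped = np.interp(
        _rank_positions(n, reference.size), np.arange(reference.size), reference
    )
    # tie groups share the mean of their tied ranks' reference values
    starts = np.r_[0, np.flatnonzero(np.diff(sorted_v) != 0) + 1]
    counts = np.diff(np.r_[starts, n])
    group_means = np.add.reduceat(mapped, starts) / counts
    new_sorted = np.repeat(group_means, counts)
    new_v = np.empty_like(v)
    new_v[order] = new_sorted
    out[present] = new_v
    return out


def quantile_normalize(
    matrix: ExpressionMatrix, reference: np.ndarray | None = None
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Quantile-normalize all experiment columns jointly.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Must be in state ``scaled``; every column needs >= 2 non-missing
        values.
    reference : array, optional
        A frozen reference distribution (e.g. saved from a previous corpus)
        to project onto instead of computing one from this matrix.

    Returns
    -------
    (normalized_matrix, reference)
        The matrix in state ``normalized`` plus the reference used.
    """
    if matrix.state != "scaled":
        raise StateError(
            f"quantile_normalize expects a scaled matrix, got {matrix.state!r}"
        )
    values = matrix.values
    if reference is None:
        reference = reference_distribution(values)
    else:
        reference = np.asarray(reference, dtype=float)
        if np.any(np.diff(reference) < 0):
            raise ValueError("reference distribution must be non-decreasing")
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[:, j] = _map_column(values[:, j], reference)
    return matrix.with_values(out, "normalized"), reference


def compare_pre_post(pre: ExpressionMatrix, post: ExpressionMatrix) -> float:
    """Coefficient of determination (R^2) between paired non-missing values.

    Used to confirm that normalization only gently rescales the data:
    identical matrices and affine transforms both give R^2 = 1.
    """
    if pre.shape != post.shape:
        raise ValueError(f"shape mismatch: {pre.shape} vs {post.shape}")
    if not np.array_equal(pre.mask, post.mask):
        raise ValueError("missing-value masks differ between matrices")
    keep = ~pre.mask
    x = pre.values[keep]
    y = post.values[keep]
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def save_reference(reference: np.ndarray, sink) -> None:
    """Save a reference distribution as a single-column TSV."""
    fh, close = (open(sink, "wt", encoding="utf-8"), True) if isinstance(
        sink, str
    ) else (sink, False)
    try:
        for v in np.asarray(reference, dtype=float):
            fh.write(repr(float(v)) + "\n")
    finally:
        if close:
            fh.close()


def load_reference(source) -> np.ndarray:
    """Load a reference distribution saved by :func:`save_reference`."""
    if isinstance(source, str):
        with open(source, "rt", encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = source.readlines()
    return np.array([float(line) for line in lines if line.strip()], dtype=float)
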