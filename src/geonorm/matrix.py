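"""Gene x experiment expression matrix container.

The matrix is the central data structure of the pipeline: rows are Entrez
gene IDs, columns are individual microarray experiments (GEO GSM samples),
and missing values are carried as NaN.  A processing-state tag records how
far along the pipeline the values are:

``raw``
    probe-aggregated intensities exactly as parsed from the source files
``scaled``
    outlier-floored and linearly rescaled to a common range (0-10,000)
``normalized``
    quantile-normalized against a shared reference distribution
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STATES = ("raw", "scaled", "normalized")


@dataclass
class ExpressionMatrix:
    """Gene (Entrez ID) x experiment intensity grid with NaN as missing.

    Attributes
    ----------
    gene_ids : np.ndarray
        Integer Entrez gene IDs, strictly increasing.
    experiment_ids : list of str
        Experiment (sample) identifiers, one per column.
    values : np.ndarray
        Float grid of shape ``(len(gene_ids), len(experiment_ids))``;
        NaN marks missing measurements.
    state : str
        One of ``raw``, ``scaled``, ``normalized``.
    sources : list of str, optional
        Per-experiment source dataset identifier (e.g. the GDS accession a
        column came from).
    """

    gene_ids: np.ndarray
    experiment_ids: list[str]
    values: np.ndarray
    state: str = "raw"
    sources: list[str] | None = field(default=None)

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.values.shape != (len(self.gene_ids), len(self.experiment_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.experiment_ids)} experiments"
            )
        if self.gene_ids.size and np.any(np.diff(self.gene_ids) <= 0):
            raise ValueError("gene_ids must be strictly increasing")
        if self.sources is not None and len(self.sources) != len(self.experiment_ids):
            raise ValueError("sources must align with experiment_ids")

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where the value is missing."""
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, state: str) -> "ExpressionMatrix":
        """Return a copy carrying new values and a new processing state."""
        return replace(self, values=np.asarray(values, dtype=float), state=state)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            np.array_equal(self.gene_ids, other.gene_ids)
            and self.experiment_ids == other.experiment_ids
            and self.state == other.state
            and np.array_equal(self.values, other.values, equal_nan=True)
        )
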