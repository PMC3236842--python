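"""Reading and writing GEO GDS SOFT files and the dataset-selection filter.

Only the GDS subset of the SOFT dialect is implemented: one ``^DATASET``
entity with ``!dataset_*`` attribute lines and a single
``!dataset_table_begin`` .. ``!dataset_table_end`` tab-delimited table whose
first two columns are ``ID_REF`` (platform probe ID) and ``IDENTIFIER``
(per-probe gene annotation).  ``^SUBSET`` blocks, which annotate sample
groupings and play no role in matrix assembly, are skipped with a warning.

Table cells equal to the literal string ``null`` (any case) or empty are
parsed as missing; all other cells must be decimal numbers.  Negative
values are kept at parse time — flagging them is a quality-control concern,
not a parsing one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .errors import SoftParseError
from .matrix import ExpressionMatrix

#: metadata fields consulted by :func:`select_dataset`, in check order,
#: with the accepted (lower-cased, trimmed) values for each.
SELECTION_RULES: list[tuple[str, frozenset[str]]] = [
    ("dataset_sample_organism", frozenset({"homo sapiens"})),
    ("dataset_type", frozenset({"nucleotide", "gene expression"})),
    ("dataset_channel_count", frozenset({"single", "1"})),
    ("dataset_value_type", frozenset({"count"})),
]


@dataclass
class GDSDataset:
    """A parsed GDS SOFT file: metadata plus the probe x sample table."""

    dataset_id: str
    metadata: dict[str, str]
    probe_ids: list[str]
    gene_labels: list[str]
    samples: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(
            len(self.probe_ids), len(self.samples)
        )
        if len(self.gene_labels) != len(self.probe_ids):
            raise ValueError("gene_labels must align with probe_ids")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("probe_ids must be unique within a dataset")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GDSDataset):
            return NotImplemented
        return (
            self.dataset_id == other.dataset_id
            and self.metadata == other.metadata
            and self.probe_ids == other.probe_ids
            and self.gene_labels == other.gene_labels
            and self.samples == other.samples
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


def _iter_lines(source) -> Iterable[str]:
    if isinstance(source, str):
        with open(source, "rt", encoding="utf-8") as fh:
            yield from fh
    elif hasattr(source, "read"):
        yield from source
    else:  # iterable of lines
        yield from source


def parse_soft(source) -> GDSDataset:
    """Parse one GDS SOFT file into a :class:`GDSDataset`.

    Parameters
    ----------
    source : path, text file object, or iterable of lines

    Raises
    ------
    SoftParseError
        On structural defects (no ``^DATASET`` block, missing or misnamed
        ID_REF/IDENTIFIER columns, ragged table rows, non-numeric cells),
        naming the offending line number.
    """
    dataset_id = None
    metadata: dict[str, str] = {}
    entity = None
    probe_ids: list[str] = []
    gene_labels: list[str] = []
    samples: list[str] | None = None
    rows: list[list[float]] = []
    in_table = False
    table_done = False
    header_len = 0
    seen_probes: set[str] = set()
    warned_subset = False
    last_line = 0

    for lineno, raw in enumerate(_iter_lines(source), start=1):
        last_line = lineno
        line = raw.rstrip("\r\n")
        if in_table:
            if line.lower().startswith("!dataset_table_end"):
                in_table = False
                table_done = True
                continue
            cells = line.split("\t")
            if samples is None:  # table header row
                if (
                    len(cells) < 2
                    or cells[0].strip().upper() != "ID_REF"
                    or cells[1].strip().upper() != "IDENTIFIER"
                ):
                    raise SoftParseError(
                        lineno, "table header must begin with ID_REF and IDENTIFIER"
                    )
                samples = [c.strip() for c in cells[2:]]
                header_len = len(cells)
                continue
            if len(cells) != header_len:
                raise SoftParseError(
                    lineno,
                    f"ragged table row: expected {header_len} fields, got {len(cells)}",
                )
            probe = cells[0].strip()
            if probe in seen_probes:
                raise SoftParseError(lineno, f"duplicate probe ID {probe!r}")
            seen_probes.add(probe)
            probe_ids.append(probe)
            gene_labels.append(cells[1].strip())
            row = []
            for cell in cells[2:]:
                cell = cell.strip()
                if cell == "" or cell.lower() == "null":
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(cell))
                    except ValueError:
                        raise SoftParseError(
                            lineno, f"non-numeric table cell {cell!r}"
                        ) from None
            rows.append(row)
            continue

        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("^"):
            name, _, value = stripped[1:].partition("=")
            entity = name.strip().upper()
            if entity == "DATASET":
                dataset_id = value.strip()
            elif entity == "SUBSET" and not warned_subset:
                warnings.warn(
                    "ignoring ^SUBSET block(s): sample-group annotations are "
                    "not used for matrix assembly",
                    stacklevel=2,
                )
                warned_subset = True
        elif stripped.startswith("!"):
            key, _, value = stripped[1:].partition("=")
            key = key.strip().lower()
            if key == "dataset_table_begin":
                in_table = True
                samples = None
            elif entity == "DATASET":
                metadata[key] = value.strip()
        # '#' column-description lines and anything else are ignored

    if dataset_id is None:
        raise SoftParseError(0, "no ^DATASET block found")
    if in_table or not table_done:
        raise SoftParseError(last_line, "missing or unterminated dataset table")
    values = (
        np.array(rows, dtype=float)
        if rows
        else np.empty((0, len(samples or [])), dtype=float)
    )
    return GDSDataset(
        dataset_id=dataset_id,
        metadata=metadata,
        probe_ids=probe_ids,
        gene_labels=gene_labels,
        samples=list(samples or []),
        values=values,
    )


def select_dataset(metadata: dict[str, str]) -> tuple[bool, str]:
    """Decide whether a dataset qualifies for processing.

    A dataset is accepted iff it is a human, single-channel, raw-count
    gene-expression dataset: ``dataset_sample_organism`` is "homo sapiens",
    ``dataset_type`` is "nucleotide" or "gene expression",
    ``dataset_channel_count`` is "single" or "1" and ``dataset_value_type``
    is "count".  Matching is case-insensitive and whitespace-trimmed.

    Returns
    -------
    (accepted, reason) : tuple of bool and str
        ``reason`` is "" on acceptance, the first failing field name on a
        value mismatch, or ``"missing:<field>"`` when a required field is
        absent.  The decision depends only on the four named fields.
    """
    for fieldname, allowed in SELECTION_RULES:
        if fieldname not in metadata:
            return False, f"missing:{fieldname}"
        if metadata[fieldname].strip().lower() not in allowed:
            return False, fieldname
    return True, ""


def _format_value(v: float) -> str:
    if np.isnan(v):
        return "null"
    return repr(float(v))


def _open_sink(sink) -> tuple[TextIO, bool]:
    if isinstance(sink, str):
        return open(sink, "wt", encoding="utf-8"), True
    return sink, False


def write_soft(dataset: GDSDataset, sink) -> None:
    """Write a :class:`GDSDataset` as SOFT text that :func:`parse_soft` inverts.

    Missing values are written as the literal ``null``.  Refuses to write a
    dataset with no sample columns or no probe rows (there is nothing a
    downstream parser could reconstruct from such a file).
    """
    if dataset.n_samples == 0:
        raise ValueError("refusing to write dataset with no samples")
    if dataset.n_probes == 0:
        raise ValueError("refusing to write dataset with no probes")
    fh, close = _open_sink(sink)
    try:
        fh.write(f"^DATASET = {dataset.dataset_id}\n")
        for key, value in dataset.metadata.items():
            fh.write(f"!{key} = {value}\n")
        fh.write("!dataset_table_begin\n")
        fh.write("\t".join(["ID_REF", "IDENTIFIER", *dataset.samples]) + "\n")
        for i, (probe, label) in enumerate(zip(dataset.probe_ids, dataset.gene_labels)):
            cells = [probe, label] + [_format_value(v) for v in dataset.values[i]]
            fh.write("\t".join(cells) + "\n")
        fh.write("!dataset_table_end\n")
    finally:
        if close:
            fh.close()


def write_matrix(matrix: ExpressionMatrix, sink) -> None:
    """Write an :class:`ExpressionMatrix` as a TSV.

    First column is the Entrez gene ID, the header row carries experiment
    IDs, missing values are empty cells, and rows are ordered by ascending
    Entrez ID.
    """
    order = np.argsort(matrix.gene_ids)
    fh, close = _open_sink(sink)
    try:
        fh.write("\t".join(["EntrezID", *matrix.experiment_ids]) + "\n")
        for i in order:
            cells = [str(int(matrix.gene_ids[i]))] + [
                "" if np.isnan(v) else repr(float(v)) for v in matrix.values[i]
            ]
            fh.write("\t".join(cells) + "\n")
    finally:
        if close:
            fh.close()


def read_matrix(source, state: str = "raw") -> ExpressionMatrix:
    """Read a TSV written by :func:`write_matrix` back into a matrix."""
    df = pd.read_csv(source, sep="\t", index_col=0)
    return ExpressionMatrix(
        gene_ids=df.index.to_numpy(dtype=np.int64),
        experiment_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        state=state,
    )
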