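"""Probe -> Entrez Gene ID mapping and multi-probe aggregation.

Platforms name their probes in vendor-specific namespaces (GenBank
accessions, Affymetrix ``_at`` IDs, gene symbols, ...).  To make expression
values comparable across platforms every probe is mapped onto NCBI's
"one gene - one ID" Entrez namespace using the per-probe IDENTIFIER
annotation and a catalog built from an NCBI gene_info table (official
symbols plus synonyms).  Probes that target the same gene — typically
isoform-specific designs alongside an all-isoform design — are collapsed by
taking the maximum expression value per sample: the all-isoform probe is
expected to report the highest signal, so the maximum recovers it without
parsing vendor suffix conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gds_io import GDSDataset
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

# NCBI gene_info column positions (header-less files)
_COL_TAX, _COL_GENEID, _COL_SYMBOL, _COL_SYNONYMS = 0, 1, 2, 4


@dataclass
class GeneCatalog:
    """Uppercase symbol/synonym -> Entrez ID lookup table."""

    symbol_to_id: dict[str, int]
    id_set: set[int] = field(default_factory=set)

    def __post_init__(self):
        if not self.id_set:
            self.id_set = set(self.symbol_to_id.values())

    def lookup(self, label: str) -> int | None:
        """Case-insensitive, whitespace-trimmed lookup; None when unmapped."""
        return self.symbol_to_id.get(label.strip().upper())

    def __len__(self) -> int:
        return len(self.symbol_to_id)


@dataclass
class ProbeMap:
    """Probe -> Entrez assignment for one platform/dataset.

    ``probe_to_gene`` keys and ``unmapped`` are disjoint and together cover
    every probe of the dataset the map was built from.
    """

    probe_to_gene: dict[str, int]
    unmapped: list[str]


def load_gene_info(source) -> GeneCatalog:
    """Build a :class:`GeneCatalog` from an NCBI gene_info tab-delimited table.

    Both official symbols and pipe-separated synonyms are keyed (uppercased).
    Precedence: an official symbol always wins over another gene's synonym;
    symbol-vs-symbol (and synonym-vs-synonym) collisions resolve to the
    lowest GeneID and are logged.  A ``-`` synonyms field means the gene has
    no synonyms.

    Parameters
    ----------
    source : path, file object, or iterable of lines

    Raises
    ------
    ValueError
        If a data row lacks the GeneID or Symbol column.
    """
    if isinstance(source, str):
        with open(source, "rt", encoding="utf-8") as fh:
            lines = fh.readlines()
    elif hasattr(source, "read"):
        lines = source.readlines()
    else:
        lines = list(source)

    idx_geneid, idx_symbol, idx_syn = _COL_GENEID, _COL_SYMBOL, _COL_SYNONYMS
    data_lines = []
    for line in lines:
        line = line.rstrip("\r\n")
        if not line:
            continue
        if line.startswith("#"):
            # header line: locate columns by name when present
            cols = [c.strip().lower() for c in line.lstrip("#").split("\t")]
            if "geneid" in cols:
                idx_geneid = cols.index("geneid")
            if "symbol" in cols:
                idx_symbol = cols.index("symbol")
            if "synonyms" in cols:
                idx_syn = cols.index("synonyms")
            continue
        data_lines.append(line)

    officials: dict[str, int] = {}
    synonyms: dict[str, int] = {}
    for line in data_lines:
        cells = line.split("\t")
        if len(cells) <= max(idx_geneid, idx_symbol):
            raise ValueError("gene_info row lacks GeneID/Symbol columns: " + line[:80])
        try:
            gene_id = int(cells[idx_geneid])
        except ValueError:
            raise ValueError(f"non-integer GeneID {cells[idx_geneid]!r}") from None
        symbol = cells[idx_symbol].strip().upper()
        if symbol and symbol != "-":
            if symbol in officials and officials[symbol] != gene_id:
                kept = min(officials[symbol], gene_id)
                logger.warning(
                    "symbol collision %r: GeneIDs %d vs %d, keeping %d",
                    symbol, officials[symbol], gene_id, kept,
                )
                officials[symbol] = kept
            else:
                officials[symbol] = gene_id
        syn_field = cells[idx_syn].strip() if len(cells) > idx_syn else "-"
        if syn_field and syn_field != "-":
            for syn in syn_field.split("|"):
                syn = syn.strip().upper()
                if not syn or syn == "-":
                    continue
                if syn in synonyms and synonyms[syn] != gene_id:
                    synonyms[syn] = min(synonyms[syn], gene_id)
                else:
                    synonyms[syn] = gene_id

    # official symbols take precedence over synonyms of other genes
    table = dict(synonyms)
    table.update(officials)
    return GeneCatalog(symbol_to_id=table)


def map_probes(
    dataset: GDSDataset, catalog: GeneCatalog, unmapped_log=None
) -> ProbeMap:
    """Resolve each probe's IDENTIFIER through the catalog.

    Unresolved probes (empty labels, labels absent from the catalog) are a
    normal outcome and are collected in ``unmapped``; when a log sink is
    given, one ``dataset_id<TAB>probe_id<TAB>identifier`` line is written
    per unmapped probe.  A fully unmapped platform triggers a warning since
    it usually means the catalog lacks that platform's namespace entirely.
    """
    probe_to_gene: dict[str, int] = {}
    unmapped: list[str] = []
    for probe, label in zip(dataset.probe_ids, dataset.gene_labels):
        gene = catalog.lookup(label) if label else None
        if gene is None:
            unmapped.append(probe)
        else:
            probe_to_gene[probe] = gene
    if unmapped and not probe_to_gene:
        logger.warning(
            "dataset %s: no probes mapped — the platform may lack mapping data",
            dataset.dataset_id,
        )
    if unmapped_log is not None and unmapped:
        fh, close = (open(unmapped_log, "at", encoding="utf-8"), True) if isinstance(
            unmapped_log, str
        ) else (unmapped_log, False)
        try:
            labels = dict(zip(dataset.probe_ids, dataset.gene_labels))
            for probe in unmapped:
                fh.write(f"{dataset.dataset_id}\t{probe}\t{labels[probe]}\n")
        finally:
            if close:
                fh.close()
    return ProbeMap(probe_to_gene=probe_to_gene, unmapped=unmapped)


def aggregate_to_genes(dataset: GDSDataset, pmap: ProbeMap) -> ExpressionMatrix:
    """Collapse probe rows to gene rows by the per-sample maximum.

    For each Entrez ID and sample the output is the maximum over that
    gene's probes' non-missing values; all-missing stays missing; unmapped
    probes are dropped.  Returns a raw-state :class:`ExpressionMatrix` with
    genes sorted by ascending Entrez ID.
    """
    gene_rows: dict[int, list[int]] = {}
    for i, probe in enumerate(dataset.probe_ids):
        gene = pmap.probe_to_gene.get(probe)
        if gene is not None:
            gene_rows.setdefault(gene, []).append(i)
    gene_ids = np.array(sorted(gene_rows), dtype=np.int64)
    out = np.full((len(gene_ids), dataset.n_samples), np.nan)
    for g, gene in enumerate(gene_ids):
        sub = dataset.values[gene_rows[int(gene)]]
        present = ~np.isnan(sub)
        any_present = present.any(axis=0)
        if any_present.any():
            out[g, any_present] = np.nanmax(sub[:, any_present], axis=0)
    return ExpressionMatrix(
        gene_ids=gene_ids,
        experiment_ids=list(dataset.samples),
        values=out,
        state="raw",
        sources=[dataset.dataset_id] * dataset.n_samples,
    )
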