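"""Co-expression neighbor-voting GO prediction and its precision/recall score.

Genes with strongly correlated expression across many heterogeneous
experiments tend to share biological function, so the functional categories
of a gene's most co-expressed neighbors predict its own.  This module scores
that prediction as a validation of preprocessing: for each annotated gene,
take the top ``k`` (default 20) genes by Pearson correlation of expression
profiles, predict every category annotated to at least ``m`` (default 2) of
those neighbors, and compare against the gene's own annotations.  Exact
category matches only — no ontology-hierarchy expansion.  Counts are pooled
over genes (micro-average) into

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F         = 2 * precision * recall / (precision + recall)

A cleaner normalization should tighten co-expression neighborhoods and
raise the F-measure; that ordering (raw <= scaled <= normalized) is the
validation criterion.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_K = 20
DEFAULT_VOTE = 2
DEFAULT_MIN_OVERLAP = 3


@dataclass
class GOAnnotationSet:
    """Entrez gene ID -> set of annotated category IDs (opaque tokens)."""

    gene_to_categories: dict[int, set[str]]

    def __post_init__(self):
        for gene, cats in self.gene_to_categories.items():
            if not cats:
                raise ValueError(f"gene {gene} has no categories")

    @classmethod
    def from_tsv(cls, source) -> "GOAnnotationSet":
        """Load a two-column (Entrez ID, category ID) TSV, one pair per line."""
        mapping: dict[int, set[str]] = {}
        fh, close = (open(source, "rt", encoding="utf-8"), True) if isinstance(
            source, str
        ) else (source, False)
        try:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                gene_s, cat = line.split("\t")[:2]
                mapping.setdefault(int(gene_s), set()).add(cat)
        finally:
            if close:
                fh.close()
        return cls(mapping)

    def to_tsv(self, sink) -> None:
        fh, close = (open(sink, "wt", encoding="utf-8"), True) if isinstance(
            sink, str
        ) else (sink, False)
        try:
            for gene in sorted(self.gene_to_categories):
                for cat in sorted(self.gene_to_categories[gene]):
                    fh.write(f"{gene}\t{cat}\n")
        finally:
            if close:
                fh.close()


@dataclass
class EvalResult:
    """Micro-averaged confusion counts and derived scores.

    Zero-denominator cases are defined as 0.
    """

    tp: int
    fp: int
    fn: int
    n_genes_scored: int = 0
    n_genes_skipped: int = 0
    precision: float = field(init=False)
    recall: float = field(init=False)
    f_measure: float = field(init=False)

    def __post_init__(self):
        self.precision = self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        self.recall = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        pr = self.precision + self.recall
        self.f_measure = 2.0 * self.precision * self.recall / pr if pr else 0.0


def _pairwise_correlations(
    matrix: ExpressionMatrix,
    gene_ids: np.ndarray,
    min_overlap: int,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between the given genes."""
    idx = np.searchsorted(matrix.gene_ids, gene_ids)
    sub = matrix.values[idx]
    df = pd.DataFrame(sub.T, columns=gene_ids)
    return df.corr(min_periods=min_overlap)


def top_correlated(
    matrix: ExpressionMatrix,
    gene: int,
    k: int = DEFAULT_K,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    candidates: np.ndarray | None = None,
) -> list[int]:
    """The ``k`` genes most correlated with ``gene`` (query excluded).

    Correlations use pairwise-complete observations with at least
    ``min_overlap`` shared experiments.  Ties are broken by ascending
    Entrez ID.

    Raises
    ------
    ValueError
        If the query gene is absent or fewer than ``k`` candidates have a
        defined correlation with it.
    """
    if gene not in matrix.gene_ids:
        raise ValueError(f"gene {gene} not in matrix")
    if candidates is None:
        candidates = matrix.gene_ids
    candidates = np.asarray(candidates, dtype=np.int64)
    if gene not in candidates:
        candidates = np.sort(np.append(candidates, gene))
    corr = _pairwise_correlations(matrix, candidates, min_overlap)
    return _rank_neighbors(corr[gene], gene, k)


def _rank_neighbors(r: pd.Series, gene: int, k: int) -> list[int]:
    r = r.drop(index=gene).dropna()
    if len(r) < k:
        raise ValueError(
            f"gene {gene}: only {len(r)} candidates with a defined correlation, "
            f"need {k}"
        )
    # sort by descending correlation, ties by ascending Entrez ID
    order = sorted(r.items(), key=lambda item: (-item[1], item[0]))
    return [int(g) for g, _ in order[:k]]


def predict_categories(
    gene: int,
    neighbors: list[int],
    annotations: GOAnnotationSet,
    m: int = DEFAULT_VOTE,
) -> set[str]:
    """Categories annotated to at least ``m`` of the neighbors.

    The query gene's own annotations are never consulted.
    """
    if not neighbors:
        raise ValueError("neighbors must be nonempty")
    votes: Counter[str] = Counter()
    for n in neighbors:
        votes.update(annotations.gene_to_categories.get(n, ()))
    return {cat for cat, count in votes.items() if count >= m}


def evaluate(
    matrix: ExpressionMatrix,
    annotations: GOAnnotationSet,
    k: int = DEFAULT_K,
    m: int = DEFAULT_VOTE,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> EvalResult:
    """Score neighbor-voting category prediction over all annotated genes.

    Per gene: TP = predicted AND annotated, FP = predicted but not
    annotated, FN = annotated but not predicted; counts are summed over
    genes (micro-average).  Genes with too few correlated candidates are
    skipped and logged.
    """
    candidates = np.array(
        sorted(set(map(int, matrix.gene_ids)) & set(annotations.gene_to_categories)),
        dtype=np.int64,
    )
    if candidates.size < 2:
        raise ValueError("need >= 2 annotated genes present in the matrix")
    corr = _pairwise_correlations(matrix, candidates, min_overlap)
    tp = fp = fn = 0
    scored = skipped = 0
    for gene in candidates:
        try:
            neighbors = _rank_neighbors(corr[gene], int(gene), k)
        except ValueError:
            skipped += 1
            logger.info("gene %d skipped: too few correlated candidates", gene)
            continue
        predicted = predict_categories(int(gene), neighbors, annotations, m)
        annotated = annotations.gene_to_categories[int(gene)]
        tp += len(predicted & annotated)
        fp += len(predicted - annotated)
        fn += len(annotated - predicted)
        scored += 1
    result = EvalResult(tp=tp, fp=fp, fn=fn, n_genes_scored=scored, n_genes_skipped=skipped)
    logger.debug(
        "evaluate: P=%.4f R=%.4f F(harmonic)=%.4f F(arithmetic)=%.4f",
        result.precision,
        result.recall,
        result.f_measure,
        0.5 * (result.precision + result.recall),
    )
    return result
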