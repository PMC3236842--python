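"""End-to-end orchestration: SOFT files in, normalized matrix out.

Stage order: parse -> select -> map probes -> aggregate to genes -> QC ->
floor outliers -> rescale -> assemble one matrix -> quantile-normalize ->
fit noise threshold -> (optionally) evaluate GO prediction.  A run summary
records the funnel counts at every stage (files seen, parsed, selected,
QC-passed, experiments retained, genes in the matrix).

Memory behavior is streaming-by-dataset up to assembly: each SOFT file is
parsed, mapped, QC'd and reduced to its gene x sample grid before the next
file is touched; only the gene-level grids are held for matrix assembly.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import gds_io, noise_model, normalize, preprocess, probe_mapping, qc
from .coexpr_eval import EvalResult, GOAnnotationSet, evaluate
from .errors import FitError, SoftParseError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters; round-trips losslessly through YAML."""

    input_dir: str
    gene_info: str
    output_dir: str = "geonorm_out"
    mm_threshold: float = qc.DEFAULT_MM_THRESHOLD
    floor_fraction: float = preprocess.DEFAULT_FLOOR_FRACTION
    scale_lo: float = preprocess.DEFAULT_RANGE[0]
    scale_hi: float = preprocess.DEFAULT_RANGE[1]
    noise_k: float = noise_model.DEFAULT_K
    noise_fit_on: str = "reference"  # "reference" | "pooled"
    eval_k: int = 20
    eval_vote: int = 2
    annotations: str | None = None
    strict: bool = False  # raise on the first malformed SOFT file
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def to_yaml(self, path: str) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix            # state = normalized
    scaled_matrix: ExpressionMatrix
    qc_reports: list[qc.QCReport]
    flooring: list[preprocess.FlooringRecord]
    reference: np.ndarray
    noise: noise_model.NoiseModel | None
    eval_result: EvalResult | None
    summary: dict[str, int] = field(default_factory=dict)


def assemble_matrix(grids: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Stack per-dataset gene grids into one raw gene x experiment matrix.

    Genes are the sorted union of per-dataset Entrez IDs; a gene absent
    from a dataset's platform is missing in that dataset's columns.
    Duplicate experiment IDs across datasets keep the first occurrence and
    are logged.
    """
    if not grids:
        raise ValueError("no grids to assemble")
    gene_union = np.unique(np.concatenate([g.gene_ids for g in grids]))
    experiment_ids: list[str] = []
    sources: list[str] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for grid in grids:
        rows = np.searchsorted(gene_union, grid.gene_ids)
        for j, exp_id in enumerate(grid.experiment_ids):
            if exp_id in seen:
                src = grid.sources[j] if grid.sources else "?"
                logger.warning(
                    "duplicate experiment %s in %s: keeping first occurrence",
                    exp_id, src,
                )
                continue
            seen.add(exp_id)
            col = np.full(gene_union.size, np.nan)
            col[rows] = grid.values[:, j]
            columns.append(col)
            experiment_ids.append(exp_id)
            sources.append(grid.sources[j] if grid.sources else "")
    return ExpressionMatrix(
        gene_ids=gene_union,
        experiment_ids=experiment_ids,
        values=np.column_stack(columns),
        state="raw",
        sources=sources,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline over every ``*.soft`` file in ``input_dir``.

    Raises
    ------
    RuntimeError
        If no input files are found or no dataset survives selection + QC.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    paths = sorted(glob.glob(os.path.join(config.input_dir, "*.soft")))
    if not paths:
        raise RuntimeError(f"no SOFT files found in {config.input_dir}")
    catalog = probe_mapping.load_gene_info(config.gene_info)
    unmapped_log = os.path.join(config.output_dir, "unmapped_probes.txt")
    if os.path.exists(unmapped_log):
        os.remove(unmapped_log)

    summary = {
        "files_seen": len(paths),
        "files_parsed": 0,
        "datasets_selected": 0,
        "datasets_qc_passed": 0,
        "experiments_retained": 0,
        "genes_in_matrix": 0,
    }
    qc_reports: list[qc.QCReport] = []
    grids: list[ExpressionMatrix] = []
    for path in paths:
        try:
            dataset = gds_io.parse_soft(path)
        except SoftParseError as exc:
            if config.strict:
                raise
            logger.warning("skipping unparseable file %s: %s", path, exc)
            continue
        summary["files_parsed"] += 1
        accepted, reason = gds_io.select_dataset(dataset.metadata)
        if not accepted:
            logger.info("dataset %s rejected: %s", dataset.dataset_id, reason)
            continue
        summary["datasets_selected"] += 1
        pmap = probe_mapping.map_probes(dataset, catalog, unmapped_log)
        grid = probe_mapping.aggregate_to_genes(dataset, pmap)
        report = qc.qc_dataset(
            grid.values, config.mm_threshold, dataset.dataset_id
        )
        qc_reports.append(report)
        if not report.passed:
            logger.info(
                "dataset %s failed QC: %s", dataset.dataset_id, report.reason
            )
            continue
        summary["datasets_qc_passed"] += 1
        grids.append(grid)

    qc.write_qc_report(qc_reports, os.path.join(config.output_dir, "qc_report.tsv"))
    if not grids:
        raise RuntimeError(
            "no dataset survived selection and QC; summary: " + json.dumps(summary)
        )

    raw = assemble_matrix(grids)
    summary["experiments_retained"] = len(raw.experiment_ids)
    summary["genes_in_matrix"] = int(raw.gene_ids.size)

    scaled, flooring = preprocess.scale_matrix(
        raw, config.floor_fraction, config.scale_lo, config.scale_hi
    )
    preprocess.write_flooring_log(
        flooring, os.path.join(config.output_dir, "flooring_log.tsv")
    )
    normalized, reference = normalize.quantile_normalize(scaled)
    normalize.save_reference(
        reference, os.path.join(config.output_dir, "reference.tsv")
    )
    gds_io.write_matrix(normalized, os.path.join(config.output_dir, "matrix.tsv"))

    model = None
    try:
        if config.noise_fit_on == "reference" and reference.size >= 1000:
            fit_values = reference
        else:
            # desk-scale corpora have reference vectors far shorter than the
            # fit needs; pool the matrix values instead
            fit_values = normalized.values[~normalized.mask]
        model = noise_model.fit_noise(fit_values, k=config.noise_k)
        model.to_json(os.path.join(config.output_dir, "noise_model.json"))
    except (FitError, ValueError) as exc:
        logger.warning("noise model not fitted: %s", exc)

    eval_result = None
    if config.annotations:
        annotations = GOAnnotationSet.from_tsv(config.annotations)
        eval_result = evaluate(
            normalized, annotations, k=config.eval_k, m=config.eval_vote
        )

    with open(
        os.path.join(config.output_dir, "run_summary.tsv"), "wt", encoding="utf-8"
    ) as fh:
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
    logger.info("pipeline summary: %s", summary)
    return PipelineResult(
        matrix=normalized,
        scaled_matrix=scaled,
        qc_reports=qc_reports,
        flooring=flooring,
        reference=reference,
        noise=model,
        eval_result=eval_result,
        summary=summary,
    )
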