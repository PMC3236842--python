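"""Synthetic one-color microarray corpora with known ground truth.

The generator emulates the statistical structure the pipeline assumes so
every stage is testable without downloads:

* per-sample intensity distributions that are a mixture of a normal
  low-expression noise peak (truncated at 0) and a lognormal expressed
  component;
* platform and hybridization effects: a per-dataset multiplicative gain
  and a per-experiment monotone response-curvature exponent (scanner
  nonlinearity varying from scan to scan);
* rare saturated outliers at the top of the intensity range;
* genes measured by one or several probes, of which the reference probe
  reports the full signal and secondary (isoform-specific) probes report a
  fraction of it;
* planted co-expression modules: groups of expressed genes sharing a
  per-sample latent factor, tied to synthetic GO categories for the
  neighbor-voting evaluation.

All randomness flows from the single ``SimSpec.seed``; the same seed
reproduces the corpus byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .coexpr_eval import GOAnnotationSet
from .errors import ParameterError
from .gds_io import GDSDataset

ENTREZ_BASE = 1000  # first synthetic Entrez ID


@dataclass
class SimSpec:
    """Study conditions for a synthetic corpus.

    Defaults describe a desk-scale heterogeneous compendium: 5 datasets of
    10 single-channel experiments over a shared space of 200 genes, 40% of
    which are expressed; noise peak N(36, 26) truncated at 0; expressed
    intensities lognormal around 500 with per-gene baselines; platform
    gains spread log-uniformly over (0.5, 20); per-experiment
    response-curvature exponents over (0.8, 1.25); 0.1% saturated outliers
    at 8x magnitude; three planted modules of 25 genes at correlation 0.8.
    """

    n_genes: int = 200
    probe_count_probs: tuple[float, ...] = (0.7, 0.2, 0.1)  # P(1, 2, 3 probes)
    n_datasets: int = 5
    samples_per_dataset: int = 10
    noise_mu: float = 36.0
    noise_sigma: float = 26.0
    expressed_fraction: float = 0.4
    expressed_meanlog: float = math.log(500.0)
    expressed_sdlog: float = 0.6        # within-sample variation (log scale)
    baseline_sdlog: float = 0.7         # between-gene baseline spread (log scale)
    platform_scale_factors: tuple[float, ...] | None = None
    gain_range: tuple[float, float] = (0.5, 20.0)
    distortion_exponent_range: tuple[float, float] = (0.8, 1.25)
    outlier_fraction: float = 0.001
    outlier_magnitude: float = 8.0
    n_modules: int = 3
    genes_per_module: int = 25
    module_correlation: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.expressed_fraction <= 1.0:
            raise ParameterError("expressed_fraction must be in [0, 1]")
        if not 0.0 <= self.module_correlation < 1.0:
            raise ParameterError("module_correlation must be in [0, 1)")
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise ParameterError("modules exceed the gene space")
        if self.n_modules * self.genes_per_module > self.n_expressed:
            raise ParameterError(
                "module genes exceed the expressed gene count; raise "
                "expressed_fraction or shrink the modules"
            )
        if abs(sum(self.probe_count_probs) - 1.0) > 1e-9:
            raise ParameterError("probe_count_probs must sum to 1")
        if self.platform_scale_factors is not None and any(
            g <= 0 for g in self.platform_scale_factors
        ):
            raise ParameterError("platform gains must be positive")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ParameterError("outlier_fraction must be in [0, 1)")

    @property
    def n_expressed(self) -> int:
        return int(round(self.expressed_fraction * self.n_genes))


@dataclass
class _CorpusStructure:
    """Seed-determined structure shared by all datasets of a corpus."""

    gene_ids: np.ndarray
    symbols: list[str]
    expressed: np.ndarray        # bool per gene
    module_of: np.ndarray        # module index per gene, -1 for none
    baselines: np.ndarray        # per-gene meanlog (expressed genes)
    gains: np.ndarray            # per-dataset multiplicative gain
    probes_per_gene: np.ndarray
    probe_efficiencies: list[np.ndarray] = field(repr=False)


def _structure(spec: SimSpec) -> _CorpusStructure:
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    n = spec.n_genes
    gene_ids = ENTREZ_BASE + np.arange(n, dtype=np.int64)
    symbols = [f"G{gid}" for gid in gene_ids]

    module_of = np.full(n, -1, dtype=int)
    n_module_genes = spec.n_modules * spec.genes_per_module
    for m in range(spec.n_modules):
        module_of[m * spec.genes_per_module : (m + 1) * spec.genes_per_module] = m

    expressed = np.zeros(n, dtype=bool)
    expressed[:n_module_genes] = True
    extra = spec.n_expressed - n_module_genes
    if extra > 0:
        pool = np.arange(n_module_genes, n)
        expressed[rng.choice(pool, size=extra, replace=False)] = True

    baselines = spec.expressed_meanlog + spec.baseline_sdlog * rng.standard_normal(n)

    if spec.platform_scale_factors is not None:
        gains = np.array(
            [
                spec.platform_scale_factors[d % len(spec.platform_scale_factors)]
                for d in range(spec.n_datasets)
            ],
            dtype=float,
        )
    else:
        lo, hi = spec.gain_range
        gains = np.exp(rng.uniform(math.log(lo), math.log(hi), spec.n_datasets))

    probes_per_gene = rng.choice(
        np.arange(1, len(spec.probe_count_probs) + 1),
        size=n,
        p=np.asarray(spec.probe_count_probs, dtype=float),
    )
    probe_efficiencies = [
        np.r_[1.0, rng.uniform(0.4, 0.9, int(c) - 1)] for c in probes_per_gene
    ]
    return _CorpusStructure(
        gene_ids=gene_ids,
        symbols=symbols,
        expressed=expressed,
        module_of=module_of,
        baselines=baselines,
        gains=gains,
        probes_per_gene=probes_per_gene,
        probe_efficiencies=probe_efficiencies,
    )


def simulate_dataset(spec: SimSpec, dataset_index: int) -> GDSDataset:
    """Generate one GDS dataset of the corpus defined by ``spec``.

    Deterministic in ``(spec.seed, dataset_index)`` and consistent with
    :func:`simulate_corpus`: dataset ``i`` of the corpus equals
    ``simulate_dataset(spec, i)``.  Metadata fields are set so the dataset
    passes the selection filter.
    """
    if not 0 <= dataset_index < spec.n_datasets:
        raise ParameterError(
            f"dataset_index {dataset_index} outside 0..{spec.n_datasets - 1}"
        )
    st = _structure(spec)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 1 + int(dataset_index)])
    )
    n, s = spec.n_genes, spec.samples_per_dataset
    rho = spec.module_correlation

    factors = rng.standard_normal((max(spec.n_modules, 1), s))
    eps = rng.standard_normal((n, s))
    base = np.empty((n, s))

    expressed = st.expressed
    mod = st.module_of
    shared = np.zeros((n, s))
    has_mod = mod >= 0
    if has_mod.any():
        shared[has_mod] = factors[mod[has_mod]]
    z = np.where(
        (mod >= 0)[:, None],
        math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * eps,
        eps,
    )
    base[expressed] = np.exp(
        st.baselines[expressed, None] + spec.expressed_sdlog * z[expressed]
    )

    n_noise = int((~expressed).sum())
    if n_noise:
        a = (0.0 - spec.noise_mu) / spec.noise_sigma
        base[~expressed] = stats.truncnorm.rvs(
            a, np.inf, loc=spec.noise_mu, scale=spec.noise_sigma,
            size=(n_noise, s), random_state=rng,
        )

    # saturated outliers on the final per-entry values
    outliers = rng.random((n, s)) < spec.outlier_fraction
    base[outliers] *= spec.outlier_magnitude

    # per-hybridization response curvature: each scan compresses or expands
    # the intensity scale a little differently (a column-wise monotone
    # distortion, exactly what quantile normalization is meant to undo)
    gammas = rng.uniform(*spec.distortion_exponent_range, s)
    gain = st.gains[dataset_index]
    y = gain * np.power(base, gammas[None, :])

    probe_ids: list[str] = []
    gene_labels: list[str] = []
    rows: list[np.ndarray] = []
    for g in range(n):
        for p, eff in enumerate(st.probe_efficiencies[g]):
            probe_ids.append(f"P{st.gene_ids[g]}_{p}_at")
            gene_labels.append(st.symbols[g])
            rows.append(y[g] * eff)

    dataset_id = f"GDS{9001 + dataset_index}"
    metadata = {
        "dataset_title": f"synthetic corpus seed {spec.seed} dataset {dataset_index}",
        "dataset_sample_organism": "Homo sapiens",
        "dataset_type": "gene expression",
        "dataset_channel_count": "1",
        "dataset_value_type": "count",
        "dataset_platform": f"GPL{9001 + dataset_index}",
    }
    samples = [f"GSM{(dataset_index + 1) * 1000 + i}" for i in range(s)]
    return GDSDataset(
        dataset_id=dataset_id,
        metadata=metadata,
        probe_ids=probe_ids,
        gene_labels=gene_labels,
        samples=samples,
        values=np.vstack(rows),
    )


def simulate_corpus(spec: SimSpec) -> tuple[list[GDSDataset], GOAnnotationSet]:
    """Generate the full corpus plus ground-truth annotations.

    Each planted module gets a unique synthetic category shared by its
    genes; every other gene gets a singleton category, so module recovery
    is the only route to true-positive predictions under a >= 2 vote.
    """
    st = _structure(spec)
    datasets = [simulate_dataset(spec, d) for d in range(spec.n_datasets)]
    annotations: dict[int, set[str]] = {}
    for g, gid in enumerate(st.gene_ids):
        m = st.module_of[g]
        cat = f"MOD{m:03d}" if m >= 0 else f"SNG{gid}"
        annotations[int(gid)] = {cat}
    return datasets, GOAnnotationSet(annotations)


def normalization_benefit_spec(seed: int) -> SimSpec:
    """Study conditions for measuring the benefit of normalization.

    The neighbor-voting validation can only discriminate preprocessing
    quality when module recovery is neither impossible nor saturated: a
    planted signal strong enough to be found in raw data regardless of
    distortion says nothing about normalization.  These conditions put the
    task in that informative regime: weak modules (correlation 0.25, four
    modules of 25 genes in a 1200-gene space), strongly heterogeneous
    platforms (gains cycling through 1/10/100, per-experiment response
    curvature spanning 0.4-2.0) and 8 datasets of 8 experiments.
    """
    return SimSpec(
        seed=seed,
        n_genes=1200,
        n_modules=4,
        genes_per_module=25,
        module_correlation=0.25,
        distortion_exponent_range=(0.4, 2.0),
        n_datasets=8,
        samples_per_dataset=8,
        platform_scale_factors=(1.0, 10.0, 100.0),
    )


def simulate_intensity_mixture(
    n: int,
    rng: np.random.Generator,
    noise_fraction: float = 0.6,
    noise_mu: float = 36.0,
    noise_sigma: float = 26.0,
    expressed_meanlog: float = math.log(500.0),
    expressed_sdlog: float = 0.8,
) -> np.ndarray:
    """Pooled intensity sample: truncated-normal noise + lognormal expressed.

    Mirrors the post-normalization value distribution: ``noise_fraction``
    of the values come from N(noise_mu, noise_sigma) truncated at 0, the
    rest from a right-shifted lognormal expressed component.
    """
    n_noise = int(round(n * noise_fraction))
    a = (0.0 - noise_mu) / noise_sigma
    noise = stats.truncnorm.rvs(
        a, np.inf, loc=noise_mu, scale=noise_sigma, size=n_noise, random_state=rng
    )
    expressed = rng.lognormal(expressed_meanlog, expressed_sdlog, n - n_noise)
    values = np.concatenate([noise, expressed])
    rng.shuffle(values)
    return values


def gene_info_text(spec: SimSpec) -> str:
    """An NCBI gene_info-style catalog covering the corpus' gene space."""
    st = _structure(spec)
    lines = [
        "#tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\tdbXrefs\tchromosome\t"
        "map_location\tdescription\ttype_of_gene"
    ]
    for gid, sym in zip(st.gene_ids, st.symbols):
        lines.append(
            f"9606\t{gid}\t{sym}\t-\t-\t-\t-\t-\tsynthetic gene {sym}\tprotein-coding"
        )
    return "\n".join(lines) + "\n"


def write_corpus(spec: SimSpec, outdir: str) -> list[str]:
    """Write SOFT files, truth annotations, gene catalog and a spec echo.

    Returns the list of SOFT file paths written.
    """
    import os

    import yaml

    from .gds_io import write_soft

    os.makedirs(outdir, exist_ok=True)
    datasets, annotations = simulate_corpus(spec)
    paths = []
    for ds in datasets:
        path = os.path.join(outdir, f"{ds.dataset_id}.soft")
        write_soft(ds, path)
        paths.append(path)
    annotations.to_tsv(os.path.join(outdir, "truth_annotations.tsv"))
    with open(os.path.join(outdir, "gene_info.tsv"), "wt", encoding="utf-8") as fh:
        fh.write(gene_info_text(spec))
    payload = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()
    }
    with open(os.path.join(outdir, "spec_echo.yaml"), "wt", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return paths
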