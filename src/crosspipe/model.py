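"""Model-style front end: build once from data, ``fit()`` to run everything.

:class:`PipelineConcordance` bundles the inputs (counts, sample sheet,
contrasts, gene-set collections) and parameters of a full concordance
analysis; :meth:`PipelineConcordance.fit` executes
filter -> normalize/DE -> enrich -> rank correlation -> top/bottom overlap
and returns a :class:`ConcordanceResults` carrying the four result tables,
per-contrast diagnostics and a text ``summary()``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import (
    ContrastSpec,
    CountMatrix,
    GeneSetCollection,
    PipelineID,
    SampleSheet,
    read_contrast_table,
    read_count_matrix,
    read_gene_sets,
    read_sample_sheet,
)
from .consistency import (
    TopBottomParams,
    aggregate_records,
    consistency_matrix,
    similarity_matrix,
)
from .diffexp import run_pipeline_grid
from .enrichment import enrich_all
from .errors import ComputationError, ValidationError
from .filtering import FilterParams, SignalFilterParams, contrast_signal_filter

__all__ = ["RunConfig", "PipelineConcordance", "ConcordanceResults"]


@dataclass
class RunConfig:
    """Flat, serializable run configuration.

    Defaults follow the documented conventions throughout the package:
    expression filter 10 / 15 counts, contrast signal threshold 30 DE genes
    at BH-adjusted p < 0.05, ulm minimum 5 genes per set, top/bottom N of
    15/5/3 by resource shape and 5% in gene space.
    """

    counts: str | None = None
    metadata: str | None = None
    contrasts: str | None = None
    genesets: dict = field(default_factory=dict)
    pipelines: list = field(default_factory=lambda: [p.label for p in PipelineID.full_grid()])
    contrast_mode: str = "all-pairwise"
    filter_params: dict = field(default_factory=lambda: dataclasses.asdict(FilterParams()))
    signal_params: dict = field(default_factory=lambda: dataclasses.asdict(SignalFilterParams()))
    top_n: dict = field(default_factory=lambda: {"tf": 15, "hallmark": 5, "pathway": 3})
    gene_top_frac: float = 0.05
    ulm_min_size: int = 5
    unsigned_weights: bool = False
    covariates: bool = False
    seed: int = 0
    outdir: str = "results"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineConcordance:
    """End-to-end concordance analysis of one count matrix.

    Parameters
    ----------
    counts, samples
        The dataset: a :class:`CountMatrix` and matching :class:`SampleSheet`.
    contrasts
        Explicit contrast list; defaults to all non-redundant pairwise
        comparisons in lexicographic orientation.
    collections
        Gene-set collections for the enrichment stage.
    pipelines
        Subset of the 12-member grid (default: full grid).
    """

    def __init__(
        self,
        counts: CountMatrix,
        samples: SampleSheet,
        contrasts: list[ContrastSpec] | None = None,
        collections: list[GeneSetCollection] | None = None,
        pipelines: list[PipelineID] | None = None,
        filter_params: FilterParams = FilterParams(),
        signal_params: SignalFilterParams = SignalFilterParams(),
        topbottom: TopBottomParams = TopBottomParams(),
        ulm_min_size: int = 5,
        contrast_mode: str = "all-pairwise",
        covariates: bool = False,
    ):
        from .core import enumerate_contrasts

        missing = set(counts.sample_ids) - set(samples.sample_ids)
        if missing:
            raise ValidationError(f"count columns without metadata: {sorted(missing)}")
        self.counts = counts
        self.samples = samples
        self.contrasts = contrasts or enumerate_contrasts(samples, mode=contrast_mode)
        self.collections = collections or []
        self.pipelines = pipelines or PipelineID.full_grid()
        self.filter_params = filter_params
        self.signal_params = signal_params
        self.topbottom = topbottom
        self.ulm_min_size = ulm_min_size
        self.covariates = covariates

    @classmethod
    def from_config(cls, config: RunConfig) -> "PipelineConcordance":
        """Build from file paths held in a :class:`RunConfig`."""
        if not config.counts or not config.metadata:
            raise ValidationError("config must provide counts and metadata paths")
        counts = read_count_matrix(config.counts)
        if counts.has_duplicate_genes:
            from .core import aggregate_gene_ids

            counts = aggregate_gene_ids(counts)
        samples = read_sample_sheet(config.metadata)
        contrasts = read_contrast_table(config.contrasts) if config.contrasts else None
        collections = [
            read_gene_sets(path, name=name) for name, path in config.genesets.items()
        ]
        if config.unsigned_weights:
            collections = [c.unsigned() for c in collections]
        return cls(
            counts,
            samples,
            contrasts=contrasts,
            collections=collections,
            pipelines=[PipelineID.from_label(p) for p in config.pipelines],
            filter_params=FilterParams(**config.filter_params),
            signal_params=SignalFilterParams(**config.signal_params),
            topbottom=TopBottomParams(
                n_by_resource=dict(config.top_n), gene_fraction=config.gene_top_frac
            ),
            ulm_min_size=config.ulm_min_size,
            contrast_mode=config.contrast_mode,
            covariates=config.covariates,
        )

    def fit(self) -> "ConcordanceResults":
        de = run_pipeline_grid(
            self.counts,
            self.samples,
            self.contrasts,
            self.pipelines,
            self.filter_params,
            self.covariates,
        )
        retained, de_counts = contrast_signal_filter(de, self.signal_params)
        if not retained:
            raise ComputationError(
                "no contrast passes the signal filter; lower min_de_genes or "
                "inspect the DE-gene count table"
            )
        de_retained = de[de["contrast"].isin(retained)]
        activity = enrich_all(de_retained, self.collections, self.ulm_min_size)
        correlation = consistency_matrix(activity, de_retained)
        similarity = similarity_matrix(activity, de_retained, self.topbottom)
        return ConcordanceResults(
            model=self,
            de_table=de,
            de_gene_counts=de_counts,
            retained_contrasts=retained,
            activity=activity,
            correlation=correlation,
            similarity=similarity,
        )


@dataclass
class ConcordanceResults:
    """Fitted results: the four result tables plus diagnostics."""

    model: PipelineConcordance
    de_table: pd.DataFrame
    de_gene_counts: pd.DataFrame
    retained_contrasts: list
    activity: pd.DataFrame
    correlation: pd.DataFrame
    similarity: pd.DataFrame

    def aggregated(self, metric: str = "spearman") -> tuple[pd.DataFrame, pd.DataFrame]:
        """(per-pair, per-pipeline) unweighted means over retained contrasts."""
        records = self.correlation if metric == "spearman" else self.similarity
        return aggregate_records(records)

    def summary(self) -> str:
        lines = [
            f"PipelineConcordance results (crosspipe {__version__})",
            f"  pipelines: {len(self.model.pipelines)}  "
            f"contrasts retained: {len(self.retained_contrasts)}/"
            f"{len(self.model.contrasts)}",
            f"  DE rows: {len(self.de_table)}   activity rows: {len(self.activity)}",
        ]
        for metric, records in (("spearman", self.correlation),
                                ("similarity", self.similarity)):
            if not len(records):
                continue
            lines.append(f"  mean {metric} by space:")
            means = records.groupby(["space", "resource"])["value"].mean()
            for (space, resource), v in means.items():
                lines.append(f"    {space:<5s} {resource:<16s} {v:7.3f}")
        return "\n".join(lines)

    def to_tsv(self, outdir) -> dict[str, Path]:
        """Write the four result files (plus diagnostics) as UTF-8 TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "de_results.tsv": self.de_table,
            "activity_scores.tsv": self.activity,
            "rank_correlation.tsv": self.correlation,
            "top_bottom_similarity.tsv": self.similarity,
            "de_gene_counts.tsv": self.de_gene_counts,
        }
        for name, table in tables.items():
            path = outdir / name
            table.to_csv(path, sep="\t", index=False)
            paths[name] = path
        return paths
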