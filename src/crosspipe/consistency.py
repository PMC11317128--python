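"""Cross-pipeline consistency metrics.

Two views of pipeline agreement are computed for every unordered pipeline
pair within each retained contrast:

* Spearman rank correlation of the full ranked lists (gene t-like
  statistics in gene space, set activity scores per resource in set space);
* a top/bottom similarity index — the fraction of shared items among the
  top-N and bottom-N of both rankings,
  ``(|top_a ∩ top_b| + |bottom_a ∩ bottom_b|) / (2N)``,
  which is 1 exactly when both tails coincide and 0 when they are disjoint.

N defaults per resource shape (TF-like 15, hallmark-like 5, pathway-like 3)
and to 5% of the shared gene universe in gene space. A one-sided Wilcoxon
rank-sum helper with BH correction supports filtered-vs-unfiltered style
group comparisons of the resulting values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .diffexp import bh_adjust

__all__ = [
    "TopBottomParams",
    "rank_correlation",
    "consistency_matrix",
    "top_bottom_similarity",
    "similarity_matrix",
    "group_difference_test",
    "group_difference_table",
    "aggregate_records",
]

DEFAULT_TOP_N = {"tf": 15, "hallmark": 5, "pathway": 3}


@dataclass(frozen=True)
class TopBottomParams:
    """Tail sizes for the similarity index."""

    n_by_resource: dict = field(default_factory=lambda: dict(DEFAULT_TOP_N))
    default_n: int = 5
    gene_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.gene_fraction < 0.5:
            raise ValidationError("gene_fraction must lie in (0, 0.5)")
        for n in self.n_by_resource.values():
            if n < 1:
                raise ValidationError("top/bottom N must be >= 1")

    def n_for(self, resource: str) -> int:
        for key, n in self.n_by_resource.items():
            if key in resource.lower():
                return n
        return self.default_n


def rank_correlation(values_a: pd.Series, values_b: pd.Series) -> float | None:
    """Spearman rho on the intersection of item ids (average ranks for ties).

    Returns None (with a warning) when fewer than 3 items are shared.
    """
    shared = values_a.index.intersection(values_b.index)
    if len(shared) < 3:
        warnings.warn("fewer than 3 shared items; correlation skipped", stacklevel=2)
        return None
    rho = stats.spearmanr(values_a.loc[shared], values_b.loc[shared]).statistic
    return float(rho)


def _ordered_items(values: pd.Series) -> np.ndarray:
    """Item ids sorted by descending score, ties broken by id ascending."""
    idx = np.lexsort((values.index.to_numpy(), -values.to_numpy()))
    return values.index.to_numpy()[idx]


def top_bottom_similarity(
    ranked_a: pd.Series, ranked_b: pd.Series, n: int
) -> float:
    """Overlap fraction of the two rankings' top-N and bottom-N tails."""
    universe = ranked_a.index.intersection(ranked_b.index)
    if 2 * n > len(universe):
        raise ValidationError(f"2N = {2 * n} exceeds the shared universe ({len(universe)})")
    a = _ordered_items(ranked_a.loc[universe])
    b = _ordered_items(ranked_b.loc[universe])
    top = len(set(a[:n]) & set(b[:n]))
    bottom = len(set(a[-n:]) & set(b[-n:]))
    return (top + bottom) / (2.0 * n)


def _pipeline_pairs(pipelines) -> list[tuple[str, str]]:
    return list(itertools.combinations(sorted(pipelines), 2))


def _iter_vectors(act: pd.DataFrame | None, de: pd.DataFrame | None, spaces):
    """Yield (contrast, resource/space label, pipeline -> Series of scores)."""
    if "set" in spaces and act is not None and len(act):
        for (contrast, resource), sub in act.groupby(["contrast", "resource"], sort=True):
            vectors = {
                p: pd.Series(s["score"].to_numpy(), index=s["set"].to_numpy())
                for p, s in sub.groupby("pipeline")
            }
            yield contrast, "set", resource, vectors
    if "gene" in spaces and de is not None and len(de):
        for contrast, sub in de.groupby("contrast", sort=True):
            vectors = {
                p: pd.Series(s["stat"].to_numpy(), index=s["gene"].to_numpy())
                for p, s in sub.groupby("pipeline")
            }
            yield contrast, "gene", "genes", vectors


def consistency_matrix(
    act: pd.DataFrame | None,
    de: pd.DataFrame | None = None,
    spaces: tuple[str, ...] = ("gene", "set"),
    pooled: bool = False,
) -> pd.DataFrame:
    """Spearman rho per contrast and unordered pipeline pair.

    Gene space correlates the t-like statistics over genes shared by each
    pair; set space correlates activity scores per resource. With
    ``pooled=True`` scores are concatenated across contrasts before
    correlating (one record per pair, contrast = "pooled").
    """
    records = []
    sources = list(_iter_vectors(act, de, spaces))
    if pooled:
        sources = _pool_sources(sources)
    for contrast, space, resource, vectors in sources:
        for pa, pb in _pipeline_pairs(vectors):
            rho = rank_correlation(vectors[pa], vectors[pb])
            if rho is not None:
                records.append((pa, pb, contrast, space, resource, "spearman", rho))
    return pd.DataFrame(
        records,
        columns=["pipeline_a", "pipeline_b", "contrast", "space", "resource",
                 "metric", "value"],
    )


def _pool_sources(sources):
    pooled: dict[tuple[str, str], dict] = {}
    for contrast, space, resource, vectors in sources:
        bucket = pooled.setdefault((space, resource), {})
        for p, vec in vectors.items():
            vec = vec.copy()
            vec.index = [f"{contrast}::{i}" for i in vec.index]
            bucket[p] = pd.concat([bucket[p], vec]) if p in bucket else vec
    return [("pooled", space, resource, vectors)
            for (space, resource), vectors in pooled.items()]


def similarity_matrix(
    act: pd.DataFrame | None,
    de: pd.DataFrame | None = None,
    p: TopBottomParams = TopBottomParams(),
    spaces: tuple[str, ...] = ("gene", "set"),
) -> pd.DataFrame:
    """Top/bottom similarity per contrast and unordered pipeline pair.

    Set space uses the resource-specific N; gene space uses
    ``floor(gene_fraction * |shared genes|)``. Pairs whose N resolves to 0
    (or whose universe cannot hold two tails) are skipped with a warning.
    """
    records = []
    for contrast, space, resource, vectors in _iter_vectors(act, de, spaces):
        for pa, pb in _pipeline_pairs(vectors):
            shared = vectors[pa].index.intersection(vectors[pb].index)
            if space == "gene":
                n = int(np.floor(p.gene_fraction * len(shared)))
            else:
                n = p.n_for(resource)
            if n < 1 or 2 * n > len(shared):
                warnings.warn(
                    f"{contrast}/{resource}: N={n} unusable for universe of "
                    f"{len(shared)}; pair skipped", stacklevel=2,
                )
                continue
            sim = top_bottom_similarity(vectors[pa], vectors[pb], n)
            records.append((pa, pb, contrast, space, resource, "similarity", sim))
    return pd.DataFrame(
        records,
        columns=["pipeline_a", "pipeline_b", "contrast", "space", "resource",
                 "metric", "value"],
    )


def aggregate_records(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unweighted means over contrasts: per pipeline pair, and per pipeline.

    The per-pipeline value is the mean over all pairs the pipeline takes
    part in (its average agreement with the rest of the grid).
    """
    per_pair = (
        records.groupby(["pipeline_a", "pipeline_b", "space", "resource", "metric"])[
            "value"
        ]
        .mean()
        .reset_index()
    )
    long = pd.concat(
        [
            per_pair.rename(columns={"pipeline_a": "pipeline"}).drop(columns="pipeline_b"),
            per_pair.rename(columns={"pipeline_b": "pipeline"}).drop(columns="pipeline_a"),
        ]
    )
    per_pipeline = (
        long.groupby(["pipeline", "space", "resource", "metric"])["value"]
        .mean()
        .reset_index()
    )
    return per_pair, per_pipeline


def group_difference_test(
    values_a, values_b, alternative: str = "greater"
) -> tuple[float, dict]:
    """One-sided Wilcoxon rank-sum p-value for values_a vs values_b.

    Exact when the combined sample is small (<= 20) and tie-free, normal
    approximation with tie correction otherwise. Identical constant samples
    yield p = 1 with a flag.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValidationError("alternative must be 'greater' or 'less'")
    annotations = {"n_a": int(a.size), "n_b": int(b.size), "flag": None}
    if np.all(a == a[0]) and np.all(b == a[0]):
        annotations["flag"] = "all values identical"
        return 1.0, annotations
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    annotations["method"] = method
    return float(res.pvalue), annotations


def group_difference_table(comparisons: dict[str, tuple]) -> pd.DataFrame:
    """Batch wrapper: run several one-sided tests and BH-adjust the family.

    ``comparisons`` maps a label to (values_a, values_b, alternative).
    """
    rows = []
    for label, (a, b, alternative) in comparisons.items():
        p, ann = group_difference_test(a, b, alternative)
        rows.append((label, alternative, ann["n_a"], ann["n_b"], p))
    out = pd.DataFrame(rows, columns=["comparison", "alternative", "n_a", "n_b", "p"])
    out["padj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
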