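"""Benchmark construction and AUROC/AUPRC scoring.

Three ground-truth constructions are supported:

* cell-type marker sets against one-vs-rest pseudobulk contrasts (the set
  matching the contrast's target cell type is the positive),
* TF-to-cell-type assignments from binding-affinity scores (greedy,
  uniqueness-constrained),
* perturbation-to-gene-set mappings (e.g. cytokine treatments linked to
  transcriptional hallmarks).

Instances are pooled across contrasts within a scope, ranked by activity
score, and scored by tie-aware AUROC (Mann-Whitney formulation) and AUPRC
(average precision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .core import CountMatrix, GeneSetCollection, SampleSheet
from .errors import ValidationError

__all__ = [
    "TFAssignment",
    "pseudobulk",
    "build_marker_truth",
    "assign_tf_markers",
    "perturbation_truth",
    "pooled_rank",
    "auroc",
    "auprc",
    "score_benchmark",
]


@dataclass(frozen=True)
class TFAssignment:
    """TFs linked to one cell type (each TF belongs to at most one list)."""

    cell_type: str
    tf_ids: tuple[str, ...]


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------


def pseudobulk(
    cell_counts: pd.DataFrame,
    cell_meta: pd.DataFrame,
    min_cells: int = 10,
    min_counts: int = 1000,
) -> tuple[CountMatrix, SampleSheet]:
    """Sum cell-level counts into per-(sample, cell type) pseudobulk profiles.

    Parameters
    ----------
    cell_counts
        cells x genes integer counts (index = cell ids).
    cell_meta
        Per-cell table with ``sample`` and ``cell_type`` columns; cells with
        missing labels are discarded.
    min_cells, min_counts
        Pseudobulks built from fewer than ``min_cells`` cells, or whose
        summed counts fall below ``min_counts``, are removed.

    Returns a genes x pseudobulks :class:`CountMatrix` (sample ids
    ``<sample>|<cell_type>``) and a :class:`SampleSheet` whose group is the
    cell type with the originating sample as a covariate.
    """
    for col in ("sample", "cell_type"):
        if col not in cell_meta.columns:
            raise ValidationError(f"cell metadata lacks a {col!r} column")
    meta = cell_meta.loc[cell_counts.index]
    labeled = meta["sample"].notna() & meta["cell_type"].notna()
    counts = cell_counts.loc[labeled]
    meta = meta.loc[labeled]

    key = meta["sample"].astype(str) + "|" + meta["cell_type"].astype(str)
    sums = counts.groupby(key.to_numpy()).sum()
    n_cells = key.value_counts()
    total = sums.sum(axis=1)
    keep = sums.index[(n_cells.loc[sums.index] >= min_cells) & (total >= min_counts)]
    if len(keep) == 0:
        raise ValidationError("no pseudobulk passes the cell/count thresholds")
    sums = sums.loc[keep].sort_index()

    sheet = pd.DataFrame(
        {
            "sample_id": sums.index,
            "group": [k.split("|", 1)[1] for k in sums.index],
            "source_sample": [k.split("|", 1)[0] for k in sums.index],
        }
    )
    return CountMatrix(sums.T), SampleSheet(sheet)


# ---------------------------------------------------------------------------
# truth builders
# ---------------------------------------------------------------------------


def build_marker_truth(
    contrasts, marker_sets: GeneSetCollection
) -> pd.DataFrame:
    """One-vs-rest marker truth: each contrast's positive is its own cell type.

    Every marker set is a candidate for every contrast; the label is 1 iff
    the set's cell type equals the contrast's numerator. Cell types without
    a marker set are an error.
    """
    set_ids = marker_sets.set_ids
    unmapped = [c.numerator for c in contrasts if c.numerator not in set_ids]
    if unmapped:
        raise ValidationError(f"cell types without marker sets: {sorted(set(unmapped))}")
    rows = [
        (c.id, set_id, int(set_id == c.numerator))
        for c in contrasts
        for set_id in set_ids
    ]
    return pd.DataFrame(rows, columns=["contrast", "candidate", "label"])


def assign_tf_markers(
    binding: pd.DataFrame, k: int = 10, coll: GeneSetCollection | None = None
) -> list[TFAssignment]:
    """Greedy uniqueness-constrained TF-to-cell-type assignment.

    ``binding`` has columns cell_type, tf, score. TFs absent from the
    regulon collection ``coll`` are discarded first. Rows are processed in
    descending score order (ties broken by tf id, then cell type); a TF goes
    to the first cell type claiming it, and each cell type keeps at most
    ``k`` TFs — cell types competing for shared TFs may end with fewer.
    """
    required = {"cell_type", "tf", "score"}
    if not required.issubset(binding.columns):
        raise ValidationError(f"binding table needs columns {sorted(required)}")
    if len(binding) == 0:
        raise ValidationError("binding table is empty")
    b = binding.copy()
    if coll is not None:
        b = b[b["tf"].isin(coll.set_ids)]
        if len(b) == 0:
            raise ValidationError("no binding TF is present in the regulon collection")
    b = b.sort_values(["score", "tf", "cell_type"],
                      ascending=[False, True, True], kind="mergesort")
    assigned: set[str] = set()
    lists: dict[str, list[str]] = {ct: [] for ct in sorted(b["cell_type"].unique())}
    for row in b.itertuples(index=False):
        if row.tf in assigned or len(lists[row.cell_type]) >= k:
            continue
        lists[row.cell_type].append(row.tf)
        assigned.add(row.tf)
    return [TFAssignment(ct, tuple(tfs)) for ct, tfs in lists.items()]


def perturbation_truth(
    mapping: pd.DataFrame, contrast_perturbations: pd.DataFrame
) -> pd.DataFrame:
    """Perturbation-linked gene-set truth.

    ``mapping`` has columns perturbation, gene_set (a perturbation may map
    to several sets); ``contrast_perturbations`` has columns contrast,
    perturbation. The candidate universe is the union of mapped sets; per
    contrast, mapped sets are positives and the remaining mapped sets are
    negatives. Contrasts whose perturbation is unmapped are excluded (listed
    in ``.attrs["excluded"]``).
    """
    for df, cols in ((mapping, {"perturbation", "gene_set"}),
                     (contrast_perturbations, {"contrast", "perturbation"})):
        if not cols.issubset(df.columns):
            raise ValidationError(f"table needs columns {sorted(cols)}")
    per_perturbation = mapping.groupby("perturbation")["gene_set"].apply(set)
    candidates = sorted(set(mapping["gene_set"]))
    rows = []
    excluded = []
    for row in contrast_perturbations.itertuples(index=False):
        if row.perturbation not in per_perturbation.index:
            excluded.append(row.contrast)
            continue
        positives = per_perturbation[row.perturbation]
        for cand in candidates:
            rows.append((row.contrast, cand, int(cand in positives)))
    if not rows:
        raise ValidationError("no contrast has a mapped perturbation")
    out = pd.DataFrame(rows, columns=["contrast", "candidate", "label"])
    out.attrs["excluded"] = excluded
    return out


# ---------------------------------------------------------------------------
# pooled ranking and scoring
# ---------------------------------------------------------------------------


def pooled_rank(
    act: pd.DataFrame,
    truth: pd.DataFrame,
    scope: pd.Series | None = None,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Attach labels to activity scores and pool instances across contrasts.

    ``act`` needs columns pipeline, contrast, set, score; ``truth`` columns
    contrast, candidate, label. ``scope`` optionally maps contrast id to a
    pooling scope (e.g. study); by default all contrasts pool together.
    Every (contrast, candidate) in the truth must have a score. Rows are
    ordered by descending score with ties broken by (contrast, candidate)
    id, so the ranking is independent of input row order.
    """
    merged = truth.merge(
        act.rename(columns={"set": "candidate"}),
        on=["contrast", "candidate"],
        how="left",
    )
    gaps = merged[merged["score"].isna()][["contrast", "candidate"]]
    if len(gaps):
        if on_missing == "drop":
            import warnings

            warnings.warn(
                f"dropping {len(gaps)} truth instances without scores", stacklevel=2
            )
            merged = merged.dropna(subset=["score"])
        else:
            raise ValidationError(
                f"missing activity scores for truth instances: "
                f"{gaps.values.tolist()[:5]}"
            )
    if scope is not None:
        merged["scope"] = merged["contrast"].map(scope)
    else:
        merged["scope"] = "all"
    merged = merged.sort_values(
        ["pipeline", "scope", "score", "contrast", "candidate"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return merged[["pipeline", "scope", "contrast", "candidate", "label", "score"]]


def _check_labels(labels: np.ndarray) -> None:
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be binary")
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValidationError("need at least one positive and one negative label")


def auroc(labels, scores) -> float:
    """Tie-aware AUROC: P(random positive outscores random negative), ties 1/2.

    Equals the Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    labels = np.asarray(labels)
    _check_labels(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve, average-precision formulation.

    Sums precision at each recall increment over a descending-score sweep;
    tied score blocks are processed atomically.
    """
    labels = np.asarray(labels)
    _check_labels(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def score_benchmark(ranked: pd.DataFrame, benchmark_id: str = "benchmark") -> pd.DataFrame:
    """AUROC/AUPRC per (pipeline, scope) of a :func:`pooled_rank` table."""
    rows = []
    for (pipeline, scope), sub in ranked.groupby(["pipeline", "scope"], sort=True):
        labels = sub["label"].to_numpy()
        scores = sub["score"].to_numpy()
        rows.append(
            (
                pipeline,
                benchmark_id,
                scope,
                auroc(labels, scores),
                auprc(labels, scores),
                int(labels.sum()),
                int(labels.size - labels.sum()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["pipeline", "benchmark", "scope", "auroc", "auprc", "n_pos", "n_neg"],
    )
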