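"""Expression-level and contrast-level filters.

Two filters are implemented:

* :func:`expression_filter` removes lowly expressed genes before DE analysis
  using the design-aware rule popularised by edgeR's ``filterByExpr``: a gene
  must exceed a CPM cutoff in at least as many samples as the smallest
  experimental group provides, and carry a minimum total count.
* :func:`contrast_signal_filter` removes contrasts whose DE signal is too
  weak to support downstream enrichment comparisons (fewer than
  ``min_de_genes`` genes at adjusted p < alpha).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix, SampleSheet
from .errors import ValidationError

__all__ = [
    "FilterParams",
    "SignalFilterParams",
    "expression_filter",
    "contrast_signal_filter",
]

# float-boundary guard used when comparing sample counts with the (possibly
# fractional) required number of samples
_TOL = 1e-14


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the expression filter (defaults match common practice)."""

    min_count: float = 10.0
    min_total_count: float = 15.0
    large_n: int = 10
    min_prop: float = 0.7

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.min_total_count < 0 or self.large_n < 0:
            raise ValidationError("filter parameters must be non-negative")
        if not 0.0 <= self.min_prop <= 1.0:
            raise ValidationError("min_prop must lie in [0, 1]")


@dataclass(frozen=True)
class SignalFilterParams:
    """Parameters of the contrast-level signal filter."""

    alpha: float = 0.05
    min_de_genes: int = 30

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.min_de_genes < 0:
            raise ValidationError("min_de_genes must be >= 0")


def expression_filter(
    m: CountMatrix, groups: SampleSheet, p: FilterParams = FilterParams()
) -> pd.Series:
    """Boolean keep-mask over genes.

    A gene is kept iff (a) its CPM exceeds ``min_count * 1e6 / median(lib)``
    in at least ``k`` samples, where ``k`` is the smallest group size with a
    large-group softening (``k = large_n + min_prop * (n_min - large_n)`` for
    ``n_min > large_n``), and (b) its total count is at least
    ``min_total_count``. Comparisons use a 1e-14 guard so that k values on an
    exact float boundary behave like integers. The mask is independent of
    sample and gene order.
    """
    missing = set(m.sample_ids) - set(groups.sample_ids)
    if missing:
        raise ValidationError(f"samples lacking a group assignment: {sorted(missing)}")
    grp = groups.groups.loc[m.sample_ids]
    n_min = grp.value_counts().min()
    k = float(n_min) if n_min <= p.large_n else p.large_n + p.min_prop * (n_min - p.large_n)

    lib = m.lib_sizes.to_numpy().astype(float)
    if (lib <= 0).any():
        raise ValidationError("samples with zero library size cannot be filtered")
    cpm_cutoff = p.min_count * 1e6 / np.median(lib)
    cpm = m.counts.to_numpy() / lib * 1e6
    keep_cpm = (cpm >= cpm_cutoff).sum(axis=1) >= k - _TOL
    keep_total = m.counts.sum(axis=1).to_numpy() >= p.min_total_count - _TOL
    mask = pd.Series(keep_cpm & keep_total, index=m.counts.index, name="kept")
    if not mask.any():
        import warnings

        warnings.warn("expression_filter removed every gene", stacklevel=2)
    return mask


def contrast_signal_filter(
    d: pd.DataFrame,
    p: SignalFilterParams = SignalFilterParams(),
    rule: str = "global-majority",
) -> tuple[list[str], pd.DataFrame]:
    """Retain contrasts with sufficient DE signal.

    ``d`` is a long-format DE table with at least columns ``pipeline``,
    ``contrast`` and ``padj``. A contrast passes in one pipeline when the
    number of genes at ``padj < alpha`` is >= ``min_de_genes``. Two retention
    rules are available:

    * ``"global-majority"`` (default): a contrast is retained iff it passes
      in more than half of the pipelines, so every pipeline shares one
      contrast set for pairwise comparison;
    * ``"per-pipeline"``: the per-(pipeline, contrast) pass flags are
      returned as-is and retained ids are contrasts passing in *any*
      pipeline.

    Returns the retained contrast ids (sorted) and a per-(pipeline, contrast)
    count table with columns pipeline, contrast, n_de_genes, passed.
    """
    required = {"pipeline", "contrast", "padj"}
    if not required.issubset(d.columns):
        raise ValidationError(f"DE table lacks columns {sorted(required - set(d.columns))}")
    if d["padj"].isna().any():
        raise ValidationError("DE table has missing adjusted p-values")

    counts = (
        d.assign(sig=d["padj"] < p.alpha)
        .groupby(["pipeline", "contrast"], sort=True)["sig"]
        .sum()
        .rename("n_de_genes")
        .reset_index()
    )
    counts["passed"] = counts["n_de_genes"] >= p.min_de_genes

    per_contrast = counts.groupby("contrast")["passed"]
    if rule == "global-majority":
        n_pipelines = counts["pipeline"].nunique()
        retained = per_contrast.sum()[lambda s: s > n_pipelines / 2].index
    elif rule == "per-pipeline":
        retained = per_contrast.any()[lambda s: s].index
    else:
        raise ValidationError(f"unknown retention rule {rule!r}")
    return sorted(retained), counts
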