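"""Univariate-linear-model (ulm) gene-set enrichment.

For each gene set, the per-gene t-like statistics are regressed on the set's
membership-weight vector (weight for member genes, 0 for the rest of the
gene universe) with an intercept. The t-value of the slope is the activity
score: its sign carries the direction of regulation and its magnitude the
significance, in a single number. Sets with fewer than ``min_size`` genes
present in the universe are skipped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneSetCollection
from .errors import ValidationError

__all__ = ["ulm_enrich", "enrich_all"]


def ulm_enrich(
    gene_stats: pd.Series,
    coll: GeneSetCollection,
    min_size: int = 5,
) -> pd.DataFrame:
    """Score every sufficiently represented set of ``coll`` against ``gene_stats``.

    Parameters
    ----------
    gene_stats
        t-like statistics indexed by gene id (the regression's response).
    coll
        Weighted gene sets; non-member genes enter with weight 0.
    min_size
        Minimum number of member genes present in ``gene_stats``.

    Returns a DataFrame with columns set, score (slope t-value), p
    (two-sided, |genes| - 2 df) and n_genes. A zero-variance membership
    vector yields score 0, p 1 (flagged via n_genes).
    """
    if len(gene_stats) <= 2:
        raise ValidationError("ulm needs more than 2 genes in the universe")
    y = gene_stats.to_numpy().astype(float)
    n = y.size
    gene_pos = {g: i for i, g in enumerate(gene_stats.index)}

    rows = []
    ybar = y.mean()
    syy = float(((y - ybar) ** 2).sum())
    for set_id, members in coll.sets.items():
        present = [(gene_pos[g], w) for g, w in members if g in gene_pos]
        if len(present) < min_size:
            continue
        x = np.zeros(n)
        for i, w in present:
            x[i] = w
        xbar = x.mean()
        sxx = float(((x - xbar) ** 2).sum())
        if sxx <= 0:
            rows.append((set_id, 0.0, 1.0, len(present)))
            continue
        sxy = float(((x - xbar) * (y - ybar)).sum())
        slope = sxy / sxx
        ss_res = syy - slope * sxy
        df = n - 2
        s2 = max(ss_res, 0.0) / df
        if s2 <= 0:
            score = np.sign(slope) * np.inf if slope != 0 else 0.0
            p = 0.0 if slope != 0 else 1.0
        else:
            score = slope / np.sqrt(s2 / sxx)
            p = 2.0 * stats.t.sf(abs(score), df)
        rows.append((set_id, float(score), float(p), len(present)))
    return pd.DataFrame(rows, columns=["set", "score", "p", "n_genes"])


def enrich_all(
    d: pd.DataFrame,
    collections: list[GeneSetCollection],
    min_size: int = 5,
) -> pd.DataFrame:
    """Apply :func:`ulm_enrich` per (pipeline, contrast, resource).

    ``d`` is the unified long-format DE table; the ``stat`` column (not lfc,
    not p) is the enrichment input. Genes absent from a pipeline (filtered
    out) simply do not contribute to that pipeline's gene universe, which is
    exactly the effect the consistency modules measure. Resources with no
    gene overlap are skipped with a warning.
    """
    if "stat" not in d.columns:
        raise ValidationError("DE table lacks a 'stat' column")
    blocks = []
    data_genes = set(d["gene"].unique())
    for coll in collections:
        coll_genes = {g for members in coll.sets.values() for g, _ in members}
        if not (coll_genes & data_genes):
            warnings.warn(f"resource {coll.name!r}: no genes overlap the data; skipped",
                          stacklevel=2)
            continue
        for (pipeline, contrast), sub in d.groupby(["pipeline", "contrast"], sort=True):
            gene_stats = pd.Series(
                sub["stat"].to_numpy(), index=sub["gene"].to_numpy()
            )
            res = ulm_enrich(gene_stats, coll, min_size)
            if res.empty:
                continue
            res.insert(0, "pipeline", pipeline)
            res.insert(1, "contrast", contrast)
            res.insert(2, "resource", coll.name)
            blocks.append(res)
    if not blocks:
        return pd.DataFrame(
            columns=["pipeline", "contrast", "resource", "set", "score", "p", "n_genes"]
        )
    return pd.concat(blocks, ignore_index=True)
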