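"""Count normalization transforms feeding the moderated-t engine.

Four transforms are provided, mirroring the common bulk RNA-seq choices:

* :func:`tmm_factors` + :func:`log_cpm` — trimmed-mean-of-M-values scaling
  factors applied inside a log-CPM transform;
* :func:`quantile_normalize_log` — log2(count+1) followed by quantile
  normalization across samples;
* :func:`glog_vst` — a variance-stabilizing generalized-log transform on
  median-of-ratios calibrated counts ("vsn-like"; the reference tool fits
  per-sample affine parameters by robust maximum likelihood, here a single
  glog scale is tuned to decorrelate row means and row standard deviations);
* :func:`voom_transform` — log-CPM plus per-observation precision weights
  from a lowess mean-variance trend.

All transforms are deterministic given their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .core import CountMatrix
from .errors import ComputationError, ValidationError

__all__ = [
    "NormalizedMatrix",
    "tmm_factors",
    "log_cpm",
    "quantile_normalize_log",
    "glog_vst",
    "voom_transform",
    "median_of_ratios_factors",
]


@dataclass
class NormalizedMatrix:
    """Real-valued genes x samples matrix, optionally with precision weights."""

    values: pd.DataFrame
    method: str
    weights: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError(f"{self.method}: non-finite normalized values")
        if self.weights is not None:
            w = self.weights.to_numpy()
            if not (np.isfinite(w).all() and (w > 0).all()):
                raise ValidationError(f"{self.method}: weights must be finite and > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Scaling factor of one sample against the reference column."""
    keep = (obs > 0) & (ref > 0)
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    log_r = np.log2((obs / n_obs) / (ref / n_ref))
    abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
    # asymptotic (delta-method) variance of the log-ratio -> precision weights
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_l = stats.rankdata(log_r)
    rank_s = stats.rankdata(abs_e)
    keep2 = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep2.any():
        return 1.0
    f = np.sum(log_r[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    m: CountMatrix,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    ref: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    The reference sample defaults to the column whose upper-quartile CPM is
    closest to the mean upper quartile. Log-ratios against the reference are
    doubly trimmed (``trim_m`` of each M tail, ``trim_a`` of each A tail) and
    combined by a precision-weighted mean. Factors are normalized so that
    their product is 1. TMM corrects composition bias, not sequencing depth —
    depth is absorbed by the library sizes in :func:`log_cpm`.
    """
    counts = m.counts.to_numpy().astype(float)
    lib = m.lib_sizes.to_numpy().astype(float)
    if counts.shape[1] < 2:
        raise ValidationError("TMM needs at least 2 samples")
    if (lib <= 0).any():
        raise ValidationError("TMM undefined for samples with zero library size")
    if ref is None:
        q75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = m.sample_ids.index(ref)
    ref_col = counts[:, ref_idx]
    f = np.array([
        _tmm_pair(counts[:, j], ref_col, lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(counts.shape[1])
    ])
    f = f / np.exp(np.mean(np.log(f)))  # product = 1
    return pd.Series(f, index=m.sample_ids, name="tmm_factor")


# ---------------------------------------------------------------------------
# log-CPM
# ---------------------------------------------------------------------------


def log_cpm(
    m: CountMatrix, factors: pd.Series | None = None, prior: float = 0.5
) -> NormalizedMatrix:
    """log2 counts per million with a prior count.

    value = log2((count + prior) / (lib * factor + 2 * prior) * 1e6).
    """
    if prior <= 0 and (m.counts.to_numpy() == 0).any():
        raise ValidationError("non-positive prior count with zero counts present")
    lib = m.lib_sizes.to_numpy().astype(float)
    f = np.ones_like(lib) if factors is None else factors.loc[m.sample_ids].to_numpy()
    if (f <= 0).any():
        raise ValidationError("scaling factors must be positive")
    eff = lib * f + 2.0 * prior
    vals = np.log2((m.counts.to_numpy() + prior) / eff * 1e6)
    return NormalizedMatrix(
        pd.DataFrame(vals, index=m.counts.index, columns=m.counts.columns),
        method="log-cpm",
    )


# ---------------------------------------------------------------------------
# quantile normalization on log2(count + 1)
# ---------------------------------------------------------------------------


def quantile_normalize_log(m: CountMatrix) -> NormalizedMatrix:
    """log2(count+1) then across-sample quantile normalization.

    Each column's sorted values are replaced by the across-sample mean of
    order statistics; tied entries receive the mean of their tied target
    quantiles (average ranks interpolated into the mean order statistics).
    Afterwards every column shares the same empirical distribution.
    """
    logc = np.log2(m.counts.to_numpy().astype(float) + 1.0)
    n_genes, n_samples = logc.shape
    if n_samples < 2:
        import warnings

        warnings.warn("single sample: quantile normalization is a no-op", stacklevel=2)
        out = logc
    else:
        mean_sorted = np.sort(logc, axis=0).mean(axis=1)
        positions = np.arange(1, n_genes + 1, dtype=float)
        out = np.empty_like(logc)
        for j in range(n_samples):
            ranks = stats.rankdata(logc[:, j], method="average")
            out[:, j] = np.interp(ranks, positions, mean_sorted)
    return NormalizedMatrix(
        pd.DataFrame(out, index=m.counts.index, columns=m.counts.columns),
        method="log2quant",
    )


# ---------------------------------------------------------------------------
# glog variance-stabilizing transform
# ---------------------------------------------------------------------------


def median_of_ratios_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    counts = m.counts.to_numpy().astype(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        # fall back to library-size factors when no gene is always detected
        lib = m.lib_sizes.to_numpy().astype(float)
        sf = lib / np.exp(np.mean(np.log(lib)))
        return pd.Series(sf, index=m.sample_ids, name="size_factor")
    logc = np.log(counts[positive])
    log_geo = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_geo, axis=0))
    return pd.Series(sf, index=m.sample_ids, name="size_factor")


def _glog(x: np.ndarray, c: float) -> np.ndarray:
    return np.log2((x + np.sqrt(x * x + c * c)) / 2.0)


def glog_vst(m: CountMatrix) -> NormalizedMatrix:
    """Calibrated generalized-log variance-stabilizing transform.

    Counts are first scaled by median-of-ratios size factors, then passed
    through ``h(x) = log2((x + sqrt(x^2 + c^2)) / 2)`` with a single scale
    ``c`` chosen by 1-D search to minimize the absolute Spearman correlation
    between row means and row standard deviations of the transformed matrix.
    The transform is strictly monotone within each sample.
    """
    if m.shape[0] < 2:
        raise ComputationError("glog VST needs at least 2 genes")
    if m.shape[1] < 2:
        raise ValidationError("glog VST needs at least 2 samples")
    sf = median_of_ratios_factors(m).to_numpy()
    x = m.counts.to_numpy().astype(float) / sf

    def objective(log_c: float) -> float:
        h = _glog(x, float(np.exp(log_c)))
        mu = h.mean(axis=1)
        sd = h.std(axis=1, ddof=1)
        ok = np.isfinite(mu) & np.isfinite(sd)
        if ok.sum() < 3 or np.allclose(sd[ok], sd[ok][0]):
            return 1.0
        rho = stats.spearmanr(mu[ok], sd[ok]).statistic
        return abs(rho) if np.isfinite(rho) else 1.0

    res = optimize.minimize_scalar(
        objective, bounds=(np.log(1e-3), np.log(1e4)), method="bounded",
        options={"xatol": 1e-3},
    )
    c = float(np.exp(res.x))
    vals = _glog(x, c)
    out = NormalizedMatrix(
        pd.DataFrame(vals, index=m.counts.index, columns=m.counts.columns),
        method="vsn-like",
    )
    out.glog_scale = c  # recorded for debugging dumps
    return out


# ---------------------------------------------------------------------------
# voom
# ---------------------------------------------------------------------------


def voom_transform(
    m: CountMatrix,
    design: np.ndarray,
    factors: pd.Series | None = None,
    span: float = 0.5,
) -> NormalizedMatrix:
    """log-CPM values plus inverse-variance observation weights.

    Per-gene square-root residual standard deviations from an ordinary
    least-squares fit on ``design`` are smoothed against average log2 count
    by lowess (fraction ``span``); each observation's weight is the predicted
    sqrt-sd at its fitted log-count raised to the power -4, with predictions
    clamped to the trend's support at the extremes.
    """
    n_genes, n_samples = m.shape
    p_rank = np.linalg.matrix_rank(design)
    df_resid = n_samples - p_rank
    if df_resid < 1:
        raise ValidationError("voom needs at least 1 residual degree of freedom")
    lib = m.lib_sizes.to_numpy().astype(float)
    f = np.ones_like(lib) if factors is None else factors.loc[m.sample_ids].to_numpy()
    eff = lib * f + 1.0
    y = np.log2((m.counts.to_numpy() + 0.5) / eff * 1e6)

    # OLS fit shared across genes (same design)
    pinv = np.linalg.pinv(design)
    beta = (pinv @ y.T).T  # (genes x p)
    fitted = beta @ design.T
    resid = y - fitted
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df_resid)
    sqrt_sd = np.sqrt(sigma)

    # mean-variance trend in average log2-count space
    sx = y.mean(axis=1) + np.mean(np.log2(eff)) - np.log2(1e6)
    trend = sm_lowess(sqrt_sd, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    tx, unique_idx = np.unique(tx, return_index=True)
    ty = ty[unique_idx]
    ty = np.maximum(ty, 1e-6)

    fitted_logcount = fitted + np.log2(eff) - np.log2(1e6)
    pred = np.interp(fitted_logcount, tx, ty)  # np.interp clamps at the edges
    w = pred ** -4.0
    return NormalizedMatrix(
        pd.DataFrame(y, index=m.counts.index, columns=m.counts.columns),
        method="voom",
        weights=pd.DataFrame(w, index=m.counts.index, columns=m.counts.columns),
    )
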