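"""Imputation, QC-anchored drift correction, CV filtering and normalization.

Stage order is fixed: KNN imputation -> LOESS drift correction -> QC-CV
feature filter -> (log-transform gated by Shapiro-Wilk, mean-centre, scale).
The drift correction is ratio-based QC-RLSC: per feature and batch, a locally
weighted regression of pooled-QC intensity on injection order is fitted, each
intensity is divided by its interpolated fit and re-anchored to the batch QC
median, so technical trends cancel while biological contrasts are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import FeatureTable, SpecificationError, check_no_missing

__all__ = [
    "PreprocessConfig",
    "impute_knn",
    "drift_correct_loess",
    "qc_cv_filter",
    "normalize",
    "NormalizeResult",
]

ScalingMode = Literal["unit_variance", "pareto", "level"]


@dataclass(frozen=True)
class PreprocessConfig:
    knn_k: int = 5
    qc_cv_limit: float = 0.30
    shapiro_alpha: float = 0.05
    loess_span: float = 0.75
    scaling_mode: ScalingMode = "unit_variance"

    def validate(self) -> None:
        if not (0 < self.qc_cv_limit < 1):
            raise SpecificationError("qc_cv_limit must lie in (0, 1)")
        if not (0 < self.shapiro_alpha < 1):
            raise SpecificationError("shapiro_alpha must lie in (0, 1)")
        if not (0 < self.loess_span <= 1):
            raise SpecificationError("loess_span must lie in (0, 1]")
        if self.knn_k < 1:
            raise SpecificationError("knn_k must be >= 1")
        if self.scaling_mode not in ("unit_variance", "pareto", "level"):
            raise SpecificationError(f"unknown scaling_mode {self.scaling_mode!r}")


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

def impute_knn(table: FeatureTable, k: int = 5) -> FeatureTable:
    """Complete missing cells from the k nearest complete samples.

    Distance is Euclidean over the features observed in the query row;
    neighbours are drawn from fully observed rows only and missing entries
    take the neighbour mean. Complete rows pass through bit-identical.
    """
    V = table.values
    isna = V.isna()
    if not isna.to_numpy().any():
        return table
    complete_mask = ~isna.any(axis=1)
    n_complete = int(complete_mask.sum())
    if n_complete < k:
        raise ValueError(
            f"KNN imputation with k={k} needs at least k complete samples; found {n_complete}"
        )
    comp = V.loc[complete_mask].to_numpy()
    out = V.to_numpy(copy=True)
    for i in np.flatnonzero(isna.any(axis=1).to_numpy()):
        row = out[i]
        obs = ~np.isnan(row)
        if not obs.any():
            raise ValueError(
                f"sample {V.index[i]!r} has no observed features; cannot impute"
            )
        d = np.sqrt(((comp[:, obs] - row[obs]) ** 2).sum(axis=1))
        nn = np.argsort(d, kind="stable")[:k]
        row[~obs] = comp[nn][:, ~obs].mean(axis=0)
    return FeatureTable(pd.DataFrame(out, index=V.index, columns=V.columns), table.meta.copy())


# ---------------------------------------------------------------------------
# LOESS drift correction
# ---------------------------------------------------------------------------

def drift_correct_loess(table: FeatureTable, span: float = 0.75) -> FeatureTable:
    """QC-anchored LOESS signal-drift correction, per feature per batch."""
    meta = table.meta
    if meta["injection_order"].isna().any():
        raise ValueError("drift correction requires an injection order for every row")
    qc = table.qc_mask.to_numpy()
    if qc.sum() == 0:
        raise ValueError("drift correction requires pooled-QC rows")

    V = table.values.to_numpy(dtype=float, copy=True)
    order = meta["injection_order"].to_numpy(dtype=float)
    batches = meta["batch"].to_numpy()

    for b in pd.unique(batches):
        in_batch = batches == b
        qc_b = in_batch & qc
        if qc_b.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 QC rows; cannot fit drift")
        qx = order[qc_b]
        sort = np.argsort(qx)
        qx_sorted = qx[sort]
        for j in range(V.shape[1]):
            qy = V[qc_b, j][sort]
            fit = lowess(qy, qx_sorted, frac=span, return_sorted=False)
            anchor = np.median(V[qc_b, j])
            fitted_at = np.interp(order[in_batch], qx_sorted, fit)
            floor = 1e-6 * max(abs(anchor), 1.0)
            fitted_at = np.where(np.abs(fitted_at) < floor, floor, fitted_at)
            V[in_batch, j] = V[in_batch, j] / fitted_at * anchor
    return FeatureTable(
        pd.DataFrame(V, index=table.values.index, columns=table.values.columns),
        meta.copy(),
    )


# ---------------------------------------------------------------------------
# QC coefficient-of-variation filter
# ---------------------------------------------------------------------------

def qc_cv_filter(
    table: FeatureTable, limit: float = 0.30
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop features undetected in any QC or with QC CV (sd/mean) >= limit.

    CV uses the sample standard deviation (n-1). Returns the filtered table
    and a report of removals (feature_id, reason, cv).
    """
    qc = table.qc_rows().values
    if len(qc) == 0:
        raise ValueError("QC-CV filtering requires pooled-QC rows")
    removed = []
    keep = []
    for fid in table.feature_ids:
        x = qc[fid].to_numpy(dtype=float)
        if np.isnan(x).any() or (x <= 0).any():
            removed.append((fid, "not detected in all QC samples", np.nan))
            continue
        mean = x.mean()
        cv = x.std(ddof=1) / mean if mean != 0 else np.inf
        if cv >= limit:
            removed.append((fid, "qc_cv_at_or_above_limit", cv))
        else:
            keep.append(fid)
    report = pd.DataFrame(removed, columns=["feature_id", "reason", "cv"])
    return table.select_features(keep), report


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class NormalizeResult(NamedTuple):
    table: FeatureTable
    log_transformed: list[str]


def _log_with_offset(x: np.ndarray) -> np.ndarray:
    """Natural log; when non-positive values exist the feature is shifted so
    its minimum sits half the smallest positive value above zero (rank order
    preserved, never a NaN)."""
    if (x <= 0).any():
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("feature selected for log transform has no positive values")
        x = x - x.min() + 0.5 * positive.min()
    return np.log(x)


def normalize(table: FeatureTable, cfg: PreprocessConfig | None = None) -> NormalizeResult:
    """Shapiro-Wilk-gated log transform, then mean-centre and scale.

    Features whose Shapiro-Wilk p-value is <= ``shapiro_alpha`` are natural-log
    transformed before centring. ``scaling_mode`` divides the centred feature
    by its sample SD (unit_variance), the square root of the SD (pareto) or
    the pre-centring mean (level).
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    check_no_missing(table, "normalization")
    V = table.values.to_numpy(dtype=float, copy=True)
    logged: list[str] = []
    for j, fid in enumerate(table.feature_ids):
        x = V[:, j]
        if np.ptp(x) > 0:
            p = stats.shapiro(x).pvalue
            if p <= cfg.shapiro_alpha:
                x = _log_with_offset(x)
                logged.append(fid)
        mean = x.mean()
        centred = x - mean
        sd = x.std(ddof=1)
        if cfg.scaling_mode == "unit_variance":
            scale = sd
        elif cfg.scaling_mode == "pareto":
            scale = np.sqrt(sd)
        else:  # level
            scale = abs(mean)
        V[:, j] = centred / scale if scale > 0 else centred
    out = FeatureTable(
        pd.DataFrame(V, index=table.values.index, columns=table.values.columns),
        table.meta.copy(),
    )
    return NormalizeResult(out, logged)
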