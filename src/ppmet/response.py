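"""Incremental AUC with peak rules, fold changes vs water control, gating.

The net incremental AUC of a postprandial time course is the trapezoidal
area *above* the fasted baseline contributed by kept peaks minus the whole
series' area *below* the baseline. A peak is a maximal run of consecutive
points strictly above baseline; it is kept only if it spans at least
``min_adjacent_points`` timepoints and its apex reaches at least
``height_fraction`` of the series' min-to-max range. Segments crossing the
baseline are split at the interpolated crossing, so areas are exact for
piecewise-linear series.

The baseline for a participant x feature is that participant's mean fasted
(T=0) intensity across their visits. Per-feature log2 fold changes compare
mean net areas of each whey-protein meal against the water control, and the
gate keeps features significant for both comparisons or for the high-protein
comparison alone; features significant for the low-protein comparison alone
are removed as likely screen false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FeatureTable, SpecificationError

__all__ = [
    "PeakParams",
    "Peak",
    "detect_peaks",
    "compute_iauc",
    "compute_auc_records",
    "compute_log2fc",
    "gate_features",
    "GATE_REMOVED_LP_ONLY",
    "GATE_SHORTLISTED_BOTH",
    "GATE_SHORTLISTED_HP_ONLY",
    "GATE_NOT_SHORTLISTED",
]

GATE_REMOVED_LP_ONLY = "removed_lp_only"
GATE_SHORTLISTED_BOTH = "shortlisted_both"
GATE_SHORTLISTED_HP_ONLY = "shortlisted_hp_only"
GATE_NOT_SHORTLISTED = "not_shortlisted"


@dataclass(frozen=True)
class PeakParams:
    height_fraction: float = 0.75
    min_adjacent_points: int = 3

    def validate(self) -> None:
        if not (0 < self.height_fraction < 1):
            raise SpecificationError("height_fraction must lie in (0, 1)")
        if self.min_adjacent_points < 1:
            raise SpecificationError("min_adjacent_points must be >= 1")


@dataclass(frozen=True)
class Peak:
    start: int        # index of first point above baseline
    end: int          # index of last point above baseline (inclusive)
    apex_value: float
    kept: bool


def _validate_series(times: np.ndarray, values: np.ndarray) -> None:
    if len(times) < 2:
        raise ValueError("series needs at least two timepoints")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")


def detect_peaks(
    times, values, baseline: float, params: PeakParams | None = None
) -> list[Peak]:
    """Locate above-baseline runs and apply the height / adjacency rules."""
    params = params or PeakParams()
    params.validate()
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    _validate_series(t, v)

    ymin, ymax = v.min(), v.max()
    height_cut = ymin + params.height_fraction * (ymax - ymin)

    peaks: list[Peak] = []
    above = v > baseline
    i = 0
    n = len(v)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        apex = v[i : j + 1].max()
        kept = (j - i + 1) >= params.min_adjacent_points and apex >= height_cut
        peaks.append(Peak(i, j, apex, kept))
        i = j + 1
    return [p for p in peaks if p.kept]


def _positive_area(t: np.ndarray, v: np.ndarray) -> float:
    """Trapezoidal integral of max(v, 0), splitting baseline crossings."""
    area = 0.0
    for a, b, ya, yb in zip(t[:-1], t[1:], v[:-1], v[1:]):
        if ya >= 0 and yb >= 0:
            area += (b - a) * (ya + yb) / 2.0
        elif ya < 0 and yb < 0:
            continue
        else:
            tc = a + (b - a) * (0.0 - ya) / (yb - ya)
            if ya >= 0:
                area += (tc - a) * ya / 2.0
            else:
                area += (b - tc) * yb / 2.0
    return area


def compute_iauc(
    times, values, baseline: float, params: PeakParams | None = None
) -> tuple[float, int]:
    """Net incremental area: kept-peak area above baseline minus the whole
    series' area below baseline. Returns ``(net_area, n_peaks_kept)``."""
    params = params or PeakParams()
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    _validate_series(t, v)
    kept = detect_peaks(t, v, baseline, params)

    excess = v - baseline
    above = 0.0
    n = len(v)
    for p in kept:
        lo = max(p.start - 1, 0)
        hi = min(p.end + 1, n - 1)
        above += _positive_area(t[lo : hi + 1], excess[lo : hi + 1])
    below = _positive_area(t, -excess)
    return above - below, len(kept)


# ---------------------------------------------------------------------------
# per participant x meal x feature records
# ---------------------------------------------------------------------------

def compute_auc_records(
    table: FeatureTable,
    feature_ids: list[str] | None = None,
    params: PeakParams | None = None,
) -> pd.DataFrame:
    """Net iAUC per participant x meal x feature on intensity-scale data.

    The baseline is the participant's mean T=0 intensity across their visits
    (a per-participant, per-feature constant). Visits with fewer than two
    timepoints are skipped.
    """
    params = params or PeakParams()
    params.validate()
    study = table.study_rows()
    fids = feature_ids if feature_ids is not None else study.feature_ids
    V = study.values[list(fids)]
    meta = study.meta

    records = []
    for pid, prows in meta.groupby("participant_id", sort=True):
        t0 = prows.index[prows["time_min"] == 0]
        if len(t0) == 0:
            continue
        baselines = V.loc[t0].mean(axis=0)
        for meal, vrows in prows.groupby("meal", sort=True):
            order = vrows["time_min"].sort_values().index
            t = vrows.loc[order, "time_min"].to_numpy(dtype=float)
            if len(t) < 2:
                continue
            block = V.loc[order].to_numpy(dtype=float)
            for j, fid in enumerate(fids):
                net, n_kept = compute_iauc(t, block[:, j], float(baselines.iloc[j]), params)
                records.append((pid, meal, fid, net, n_kept))
    return pd.DataFrame(
        records, columns=["participant_id", "meal", "feature_id", "net_area", "n_peaks_kept"]
    )


# ---------------------------------------------------------------------------
# fold changes and the gate
# ---------------------------------------------------------------------------

def compute_log2fc(
    auc: pd.DataFrame,
    comparisons: tuple[tuple[str, str], ...] = (("LP", "WC"), ("HP", "WC")),
    sig_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-feature log2 fold change of mean net area for each meal pair.

    A comparison is flagged significant when ``|log2fc| >= sig_threshold``
    (two-fold by default). When either group mean is non-positive the ratio
    is undefined: the feature gets ``sig=False`` and an ``indeterminate``
    flag instead of a pseudo-count.
    """
    out: dict[str, pd.Series] = {}
    suffix = {"LP": "lp", "HP": "hp"}
    for meal, ref in comparisons:
        tag = suffix.get(meal, meal.lower())
        sub = auc[auc["meal"].isin([meal, ref])]
        wide = (
            sub.pivot_table(index=["feature_id", "participant_id"], columns="meal", values="net_area")
            .reindex(columns=[meal, ref])
            .dropna()
        )
        if wide.empty:
            raise ValueError(f"comparison {meal}/{ref} has no shared participants")
        means = wide.groupby(level="feature_id").mean()
        num, den = means[meal], means[ref]
        valid = (num > 0) & (den > 0)
        fc = pd.Series(np.nan, index=means.index)
        fc[valid] = np.log2(num[valid] / den[valid])
        out[f"log2fc_{tag}"] = fc
        out[f"sig_{tag}"] = valid & (fc.abs() >= sig_threshold)
        out[f"indeterminate_{tag}"] = ~valid
    fcdf = pd.DataFrame(out)
    fcdf.index.name = "feature_id"
    return fcdf.reset_index()


def gate_features(fc: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Apply the shortlist truth table on the (sig_lp, sig_hp) flags.

    lp only -> removed; both -> shortlisted; hp only -> shortlisted;
    neither -> not shortlisted. Returns the table with a ``gate`` column and
    the shortlist.
    """
    lp = fc["sig_lp"].astype(bool)
    hp = fc["sig_hp"].astype(bool)
    gate = np.select(
        [lp & ~hp, lp & hp, ~lp & hp],
        [GATE_REMOVED_LP_ONLY, GATE_SHORTLISTED_BOTH, GATE_SHORTLISTED_HP_ONLY],
        default=GATE_NOT_SHORTLISTED,
    )
    out = fc.copy()
    out["gate"] = gate
    shortlist = out.loc[
        out["gate"].isin([GATE_SHORTLISTED_BOTH, GATE_SHORTLISTED_HP_ONLY]), "feature_id"
    ].tolist()
    return out, shortlist
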