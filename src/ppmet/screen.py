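"""Meal x Time interaction screen: mixed-model LRT, permutation p, BH q.

Each feature is fit with the linear mixed model

    intensity ~ Meal + Time + Meal:Time + Age + BMI + (1 | participant)

by maximum likelihood (ML, so the likelihood-ratio test between nested
fixed-effect structures is valid), and the screen statistic is
``2 * (loglik_full - loglik_without_interaction)``. Significance comes from a
permutation null: under "no meal effect" a participant's three visit curves
are exchangeable, so meal labels are permuted across whole visits within each
participant — preserving within-visit autocorrelation and the participant's
age/BMI — and the add-one estimator ``p = (1 + #{perm >= obs}) / (B + 1)``
never returns zero. Benjamini-Hochberg adjustment is applied across features
and the retained set is ``q < q_threshold`` (features at or above the
threshold are filtered out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import FeatureTable, SpecificationError
from .mixedlm import RandomInterceptModel

__all__ = [
    "ScreenConfig",
    "fit_lme_feature",
    "permutation_pvalue",
    "bh_adjust",
    "screen_features",
]


@dataclass(frozen=True)
class ScreenConfig:
    n_permutations: int = 10_000
    q_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise SpecificationError("n_permutations must be >= 1")
        if not (0 < self.q_threshold < 1):
            raise SpecificationError("q_threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _check_design(meta: pd.DataFrame) -> None:
    if meta["meal"].nunique() < 2:
        raise ValueError("design needs >= 2 meals (interaction is singular otherwise)")
    if meta["time_min"].nunique() < 2:
        raise ValueError("design needs >= 2 timepoints")
    if meta["participant_id"].nunique() < 2:
        raise ValueError("design needs >= 2 participants")


def build_design(
    meta: pd.DataFrame, meal: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-effect design for the full model.

    Returns ``(X_full, reduced_columns, groups)`` where ``reduced_columns``
    indexes the columns of the no-interaction model (Meal + Time + Age + BMI)
    within ``X_full``. Meal and Time are categorical factors, so with 3 meals
    and 5 timepoints the interaction block carries 8 degrees of freedom.
    """
    meal = np.asarray(meta["meal"] if meal is None else meal)
    time = meta["time_min"].to_numpy()
    meal_levels = sorted(pd.unique(meal))
    time_levels = sorted(pd.unique(time))
    n = len(meta)

    D_meal = np.column_stack([(meal == m).astype(float) for m in meal_levels[1:]])
    D_time = np.column_stack([(time == t).astype(float) for t in time_levels[1:]])
    inter = np.column_stack(
        [D_meal[:, i] * D_time[:, j] for i in range(D_meal.shape[1]) for j in range(D_time.shape[1])]
    )
    covars = []
    for c in ("age", "bmi"):
        if c in meta and meta[c].notna().all() and meta[c].nunique() > 1:
            x = meta[c].to_numpy(dtype=float)
            covars.append(x - x.mean())
    cov = np.column_stack(covars) if covars else np.empty((n, 0))

    X = np.column_stack([np.ones(n), D_meal, D_time, cov, inter])
    reduced_cols = np.arange(X.shape[1] - inter.shape[1])
    groups = pd.factorize(meta["participant_id"])[0]
    return X, reduced_cols, groups


def _lrt_from_models(
    full: RandomInterceptModel,
    reduced: RandomInterceptModel,
    stats_full,
    stats_reduced,
    f: int,
) -> float:
    lrt = 2.0 * (full.max_loglik(stats_full, f) - reduced.max_loglik(stats_reduced, f))
    return max(lrt, 0.0)


def fit_lme_feature(values: np.ndarray | pd.Series, meta: pd.DataFrame) -> float:
    """Likelihood-ratio statistic for the Meal:Time interaction of one feature."""
    y = np.asarray(values, dtype=float)
    if np.isnan(y).any():
        raise ValueError("feature values contain missing entries; impute first")
    _check_design(meta)
    X, rcols, groups = build_design(meta)
    full = RandomInterceptModel(X, groups)
    reduced = RandomInterceptModel(X[:, rcols], groups)
    return _lrt_from_models(full, reduced, full.prepare_y(y), reduced.prepare_y(y), 0)


# ---------------------------------------------------------------------------
# permutations
# ---------------------------------------------------------------------------

def _permute_meals(meta: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Relabel each participant's visits with a random permutation of their
    own meal labels (whole visit curves move together)."""
    meal = meta["meal"].to_numpy(dtype=object).copy()
    pid = meta["participant_id"].to_numpy()
    for p in pd.unique(pid):
        rows = pid == p
        visits = pd.unique(meal[rows])
        mapping = dict(zip(visits, rng.permutation(visits)))
        meal[rows] = [mapping[m] for m in meal[rows]]
    return meal


def permutation_pvalue(
    values: np.ndarray | pd.Series,
    meta: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
) -> float:
    """Add-one permutation p-value for one feature's interaction statistic."""
    if B < 1:
        raise SpecificationError("B must be >= 1")
    y = np.asarray(values, dtype=float)
    obs = fit_lme_feature(y, meta)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        meal_b = _permute_meals(meta, rng)
        X, rcols, groups = build_design(meta, meal=meal_b)
        full = RandomInterceptModel(X, groups)
        reduced = RandomInterceptModel(X[:, rcols], groups)
        stat = _lrt_from_models(full, reduced, full.prepare_y(y), reduced.prepare_y(y), 0)
        if stat >= obs:
            exceed += 1
    return (1 + exceed) / (B + 1)


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full screen
# ---------------------------------------------------------------------------

def screen_features(
    table: FeatureTable, cfg: ScreenConfig | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Screen every feature; returns (result table, retained feature list).

    The same B visit-relabelings are applied to every feature, which shares
    the per-permutation design factorization across the whole matrix and
    keeps feature-wise p-values comparable.
    """
    cfg = cfg or ScreenConfig()
    cfg.validate()
    study = table.study_rows()
    meta = study.meta
    _check_design(meta)
    Y = study.values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("screen requires a complete (imputed) table")
    F = Y.shape[1]

    X, rcols, groups = build_design(meta)
    full = RandomInterceptModel(X, groups)
    reduced = RandomInterceptModel(X[:, rcols], groups)
    sf, sr = full.prepare_y(Y), reduced.prepare_y(Y)
    obs = np.array([_lrt_from_models(full, reduced, sf, sr, f) for f in range(F)])

    rng = np.random.default_rng(cfg.seed)
    exceed = np.zeros(F)
    for _ in range(cfg.n_permutations):
        meal_b = _permute_meals(meta, rng)
        Xb, rcols_b, _ = build_design(meta, meal=meal_b)
        fb = RandomInterceptModel(Xb, groups)
        rb = RandomInterceptModel(Xb[:, rcols_b], groups)
        sfb, srb = fb.prepare_y(Y), rb.prepare_y(Y)
        stats_b = np.array([_lrt_from_models(fb, rb, sfb, srb, f) for f in range(F)])
        exceed += stats_b >= obs

    p = (1.0 + exceed) / (cfg.n_permutations + 1.0)
    q = bh_adjust(p)
    result = pd.DataFrame(
        {
            "feature_id": study.values.columns,
            "lrt_stat": obs,
            "p_perm": p,
            "q": q,
            "retained": q < cfg.q_threshold,
        }
    )
    result = result.sort_values(["q", "lrt_stat"], ascending=[True, False]).reset_index(drop=True)
    retained = result.loc[result["retained"], "feature_id"].tolist()
    return result, retained
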