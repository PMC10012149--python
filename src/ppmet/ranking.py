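"""SVM-RFE feature ranking with nested-CV generalized error estimation.

Within each outer training fold a linear max-margin classifier scores
surviving features by squared weight; elimination removes the worse half per
round while more than ``halving_floor`` features survive ("multiple RFE"),
then switches to one-by-one removal. Rank 1 is the last survivor and ranks
are averaged across folds (smaller average rank = stronger contribution).

The generalized error for a top-N panel is nested cross-validation: an RBF
SVM is tuned (cost x gamma grid) by inner CV on each outer training fold
only, refit on that fold, and scored on the held-out fold; the curve of mean
held-out misclassification over N supports picking the smallest N whose
error beats the acceptance threshold. Dummy (confusion) models re-run the
identical machinery against randomized class labels as a negative control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import SpecificationError

__all__ = [
    "RFEConfig",
    "RFEModel",
    "rank_features_linear_svm",
    "average_ranks",
    "generalized_error_curve",
    "select_optimal_n",
    "make_dummy_labels",
    "svm_rfe_model",
    "top_features_table",
]


def _default_cost_grid() -> tuple[float, ...]:
    return tuple(2.0 ** np.linspace(-5, 15, 8))


def _default_gamma_grid() -> tuple[float, ...]:
    return tuple(2.0 ** np.linspace(-15, 3, 8))


@dataclass(frozen=True)
class RFEConfig:
    n_outer_folds: int = 10
    halving_floor: int = 50
    linear_cost: float = 1.0
    cost_grid: tuple[float, ...] = field(default_factory=_default_cost_grid)
    gamma_grid: tuple[float, ...] = field(default_factory=_default_gamma_grid)
    n_inner_folds: int = 10
    error_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise SpecificationError("fold counts must be >= 2")
        if not self.cost_grid or not self.gamma_grid:
            raise SpecificationError("hyperparameter grids must be nonempty")
        if not (0 < self.error_threshold < 1):
            raise SpecificationError("error_threshold must lie in (0, 1)")
        if self.halving_floor < 1:
            raise SpecificationError("halving_floor must be >= 1")


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"labels must be binary; found classes {classes!r}")
    return y


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _rfe_rank_single(X: np.ndarray, y: np.ndarray, cfg: RFEConfig) -> tuple[np.ndarray, list[int]]:
    """RFE on one training set. Returns (ranks, per-round survivor counts)."""
    p = X.shape[1]
    surviving = list(range(p))
    ranks = np.zeros(p, dtype=float)
    next_rank = p
    round_sizes = [p]
    while surviving:
        if len(surviving) == 1:
            ranks[surviving[0]] = next_rank
            break
        clf = SVC(kernel="linear", C=cfg.linear_cost)
        clf.fit(X[:, surviving], y)
        w2 = np.ravel(np.asarray(clf.coef_)) ** 2
        n_remove = len(surviving) // 2 if len(surviving) > cfg.halving_floor else 1
        order = np.argsort(w2, kind="stable")  # ascending: weakest first
        for local in order[:n_remove]:
            ranks[surviving[local]] = next_rank
            next_rank -= 1
        surviving = [surviving[i] for i in sorted(order[n_remove:])]
        round_sizes.append(len(surviving))
    return ranks, round_sizes


def rank_features_linear_svm(
    X: np.ndarray, y: np.ndarray, cfg: RFEConfig | None = None
) -> np.ndarray:
    """Per-outer-fold RFE ranks; shape (n_folds, n_features), rank 1 best."""
    cfg = cfg or RFEConfig()
    cfg.validate()
    y = _check_binary(y)
    X = np.asarray(X, dtype=float)
    skf = StratifiedKFold(n_splits=cfg.n_outer_folds, shuffle=True, random_state=cfg.seed)
    fold_ranks = []
    for train, _test in skf.split(X, y):
        if len(np.unique(y[train])) < 2:
            raise ValueError("a training fold contains a single class")
        ranks, _ = _rfe_rank_single(X[train], y[train], cfg)
        fold_ranks.append(ranks)
    return np.vstack(fold_ranks)


def average_ranks(per_fold_ranks: np.ndarray) -> np.ndarray:
    """Arithmetic mean rank across folds (smaller = stronger contribution)."""
    R = np.asarray(per_fold_ranks, dtype=float)
    if R.ndim != 2:
        raise ValueError("expected a (n_folds, n_features) rank matrix")
    if np.any(R <= 0):
        raise ValueError("every fold must rank every feature")
    return R.mean(axis=0)


# ---------------------------------------------------------------------------
# nested-CV generalized error
# ---------------------------------------------------------------------------

def _tune_rbf(Xtr: np.ndarray, ytr: np.ndarray, cfg: RFEConfig) -> tuple[float, float]:
    """Grid-search (cost, gamma) by inner CV on the training fold only.

    Deterministic: ties break toward the smaller cost then smaller gamma.
    Never sees any row outside ``Xtr`` — the no-leakage contract of nested CV.
    """
    n_inner = min(cfg.n_inner_folds, int(np.bincount(pd.factorize(ytr)[0]).min()))
    n_inner = max(n_inner, 2)
    skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(Xtr, ytr))
    best = (np.inf, np.inf, np.inf)  # (error, cost, gamma)
    for C in cfg.cost_grid:
        for gamma in cfg.gamma_grid:
            errs = []
            for tr, va in splits:
                clf = SVC(kernel="rbf", C=C, gamma=gamma)
                clf.fit(Xtr[tr], ytr[tr])
                errs.append(np.mean(clf.predict(Xtr[va]) != ytr[va]))
            cand = (float(np.mean(errs)), C, gamma)
            if cand < best:
                best = cand
    return best[1], best[2]


def generalized_error_curve(
    X: np.ndarray,
    y: np.ndarray,
    ranks: np.ndarray,
    cfg: RFEConfig | None = None,
    n_values=None,
) -> dict[int, float]:
    """Mean held-out misclassification for each top-N feature panel.

    ``ranks`` may be the per-fold rank matrix from
    :func:`rank_features_linear_svm` (2-D, fold-aligned through the shared
    seeded stratified split) — then each outer fold selects its top-N from
    its *own* training-fold ranking, so feature selection never sees the
    held-out rows and dummy-label models stay at chance. A 1-D averaged
    ranking is also accepted (selection then reflects the full data; fine
    for reporting a fixed panel, biased as a generalization estimate).
    """
    cfg = cfg or RFEConfig()
    cfg.validate()
    y = _check_binary(y)
    X = np.asarray(X, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    p = X.shape[1]
    if n_values is None:
        n_values = range(1, p + 1)
    skf = StratifiedKFold(n_splits=cfg.n_outer_folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(X, y))
    if ranks.ndim == 2:
        if ranks.shape != (len(splits), p):
            raise ValueError(
                f"per-fold rank matrix must be ({len(splits)}, {p}); got {ranks.shape}"
            )
        fold_orders = [np.argsort(r, kind="stable") for r in ranks]
    else:
        fold_orders = [np.argsort(ranks, kind="stable")] * len(splits)
    curve: dict[int, float] = {}
    for N in n_values:
        if not (1 <= N <= p):
            raise ValueError(f"top-N value {N} outside 1..{p}")
        errs = []
        for (train, test), order in zip(splits, fold_orders):
            cols = order[:N]
            C, gamma = _tune_rbf(X[np.ix_(train, cols)], y[train], cfg)
            clf = SVC(kernel="rbf", C=C, gamma=gamma)
            clf.fit(X[np.ix_(train, cols)], y[train])
            errs.append(float(np.mean(clf.predict(X[np.ix_(test, cols)]) != y[test])))
        curve[int(N)] = float(np.mean(errs))
    return curve


def select_optimal_n(error_curve: dict[int, float], threshold: float = 0.05) -> int | None:
    """Smallest N with error strictly below the threshold, else None."""
    if not error_curve:
        raise ValueError("error_curve is empty")
    for n in sorted(error_curve):
        if error_curve[n] < threshold:
            return n
    return None


# ---------------------------------------------------------------------------
# dummy (confusion) labels
# ---------------------------------------------------------------------------

def make_dummy_labels(
    y: np.ndarray, mode: str = "permute_labels", seed: int = 0, n_features: int | None = None
):
    """Randomized labels for negative-control models.

    ``permute_labels`` returns one random permutation of y (class counts
    preserved, a single well-defined classification problem).  ``per_column``
    returns an (n_samples, n_features) matrix of independent random class
    draws, the literal per-feature-column reassignment.
    """
    y = _check_binary(y)
    rng = np.random.default_rng(seed)
    if mode == "permute_labels":
        return y[rng.permutation(len(y))]
    if mode == "per_column":
        if n_features is None:
            raise ValueError("per_column mode requires n_features")
        classes = np.unique(y)
        return classes[rng.integers(0, 2, size=(len(y), n_features))]
    raise ValueError(f"unknown dummy mode {mode!r}")


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------

@dataclass
class RFEModel:
    feature_ids: list[str]
    per_fold_ranks: np.ndarray
    avg_rank: np.ndarray
    error_curve: dict[int, float]
    optimal_n: int | None
    dummy_error_curve: dict[int, float] | None
    config: RFEConfig

    def top_features(self, n: int) -> list[str]:
        order = np.argsort(self.avg_rank, kind="stable")
        return [self.feature_ids[i] for i in order[:n]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_ids": self.feature_ids,
            "per_fold_ranks": self.per_fold_ranks.tolist(),
            "avg_rank": self.avg_rank.tolist(),
            "error_curve": {str(k): v for k, v in self.error_curve.items()},
            "optimal_n": self.optimal_n,
            "dummy_error_curve": (
                {str(k): v for k, v in self.dummy_error_curve.items()}
                if self.dummy_error_curve is not None
                else None
            ),
            "config": {
                **{k: getattr(self.config, k) for k in (
                    "n_outer_folds", "halving_floor", "linear_cost",
                    "n_inner_folds", "error_threshold", "seed",
                )},
                "cost_grid": list(self.config.cost_grid),
                "gamma_grid": list(self.config.gamma_grid),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def svm_rfe_model(
    X: np.ndarray,
    y: np.ndarray,
    cfg: RFEConfig | None = None,
    feature_ids: list[str] | None = None,
    n_values=None,
    with_dummy: bool = True,
) -> RFEModel:
    """Full procedure: rank, average, error curve, optimal N, dummy control."""
    cfg = cfg or RFEConfig()
    X = np.asarray(X, dtype=float)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(X.shape[1])]
    per_fold = rank_features_linear_svm(X, y, cfg)
    avg = average_ranks(per_fold)
    curve = generalized_error_curve(X, y, per_fold, cfg, n_values=n_values)
    opt = select_optimal_n(curve, cfg.error_threshold)
    dummy_curve = None
    if with_dummy:
        y_dummy = make_dummy_labels(y, "permute_labels", seed=cfg.seed)
        dummy_fold = rank_features_linear_svm(X, y_dummy, cfg)
        dummy_curve = generalized_error_curve(X, y_dummy, dummy_fold, cfg, n_values=n_values)
    return RFEModel(
        feature_ids=list(feature_ids),
        per_fold_ranks=per_fold,
        avg_rank=avg,
        error_curve=curve,
        optimal_n=opt,
        dummy_error_curve=dummy_curve,
        config=cfg,
    )


def top_features_table(
    model: RFEModel, q_values: pd.Series | None = None, n: int = 20
) -> pd.DataFrame:
    """Top-N panel (annotation placeholder, AvgRank, screen q-value)."""
    order = np.argsort(model.avg_rank, kind="stable")[:n]
    rows = []
    for i in order:
        fid = model.feature_ids[i]
        rows.append(
            {
                "annotation": f"Unk {fid}",
                "feature_id": fid,
                "avg_rank": model.avg_rank[i],
                "screen_q": q_values.get(fid, np.nan) if q_values is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
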