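"""PCA and PLS-DA with cross-validated Q2 and permutation testing.

PLS-DA regresses a centred 0/1 class indicator on the standardized feature
panel with a NIPALS latent-variable fit; R2X/R2Y are cumulative explained
fractions of X and of the indicator, Q2 is ``1 - PRESS/TSS`` accumulated
over held-out cross-validation folds, and the permutation check refits the
model under random label permutations: the model is called *valid* when the
unpermuted Q2 exceeds every permuted Q2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PCAResult",
    "PLSDAResult",
    "PermutationValidation",
    "fit_pca",
    "fit_plsda",
    "q2_crossval",
    "permutation_validate",
]


@dataclass
class PCAResult:
    scores: np.ndarray    # (n, k)
    loadings: np.ndarray  # (k, p) orthonormal rows
    r2x: np.ndarray       # (k,) per-component explained variance fraction
    mean: np.ndarray


@dataclass
class PLSDAResult:
    n_components: int
    r2x_cum: float
    r2y_cum: float
    r2y_per_component: np.ndarray
    scores: np.ndarray
    x_weights: np.ndarray
    q2_cum: float | None = None


@dataclass
class PermutationValidation:
    observed_r2y: float
    observed_q2: float
    perm_r2y: np.ndarray
    perm_q2: np.ndarray
    valid: bool


def _encode_binary(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("PLS-DA requires exactly two classes")
    return (y == classes[1]).astype(float)


def _standardize(X: np.ndarray, mean=None, sd=None):
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(X, n_components: int | None = None) -> PCAResult:
    """Successive orthogonal variance-maximizing components of a centred X."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    return PCAResult(
        scores=scores,
        loadings=pca.components_,
        r2x=pca.explained_variance_ratio_,
        mean=pca.mean_,
    )


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def fit_plsda(X, y, n_components: int = 2) -> PLSDAResult:
    """NIPALS PLS fit of the centred class indicator on standardized X."""
    X = np.asarray(X, dtype=float)
    if n_components > min(X.shape) or n_components > np.linalg.matrix_rank(X - X.mean(0)):
        raise ValueError("n_components exceeds the rank of X")
    yb = _encode_binary(y)
    Xs, _, _ = _standardize(X)
    yc = yb - yb.mean()

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, yc)

    T, P = pls.x_scores_, pls.x_loadings_
    ssx = (Xs**2).sum()
    r2x_cum = 1.0 - ((Xs - T @ P.T) ** 2).sum() / ssx if ssx > 0 else 0.0

    ssy = (yc**2).sum()
    r2y = []
    for k in range(1, n_components + 1):
        sub = PLSRegression(n_components=k, scale=False).fit(Xs, yc)
        resid = yc - sub.predict(Xs).ravel()
        r2y.append(1.0 - (resid**2).sum() / ssy)
    return PLSDAResult(
        n_components=n_components,
        r2x_cum=float(np.clip(r2x_cum, 0.0, 1.0)),
        r2y_cum=float(r2y[-1]),
        r2y_per_component=np.asarray(r2y),
        scores=T,
        x_weights=pls.x_weights_,
    )


def q2_crossval(X, y, n_components: int = 2, k_folds: int = 7, seed: int = 0) -> float:
    """Cross-validated predictive fraction Q2 = 1 - PRESS/TSS.

    Standardization statistics and the PLS fit come from the training folds
    only; PRESS accumulates squared prediction error on held-out samples.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    yb = _encode_binary(y)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    press = 0.0
    for train, test in skf.split(X, yb):
        Xtr, mean, sd = _standardize(X[train])
        ytr = yb[train]
        k = min(n_components, np.linalg.matrix_rank(Xtr), Xtr.shape[1])
        pls = PLSRegression(n_components=max(k, 1), scale=False)
        pls.fit(Xtr, ytr - ytr.mean())
        Xte = (X[test] - mean) / sd
        pred = pls.predict(Xte).ravel() + ytr.mean()
        press += float(((yb[test] - pred) ** 2).sum())
    tss = float(((yb - yb.mean()) ** 2).sum())
    return 1.0 - press / tss


def permutation_validate(
    X,
    y,
    n_components: int = 2,
    n_perm: int = 100,
    k_folds: int = 7,
    seed: int = 0,
) -> PermutationValidation:
    """Refit under random label permutations; valid iff the unpermuted Q2
    beats every permuted Q2."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    yb = _encode_binary(y)
    obs_r2y = fit_plsda(X, yb, n_components).r2y_cum
    obs_q2 = q2_crossval(X, yb, n_components, k_folds, seed)
    rng = np.random.default_rng(seed)
    perm_r2y = np.empty(n_perm)
    perm_q2 = np.empty(n_perm)
    for b in range(n_perm):
        yp = yb[rng.permutation(len(yb))]
        perm_r2y[b] = fit_plsda(X, yp, n_components).r2y_cum
        perm_q2[b] = q2_crossval(X, yp, n_components, k_folds, seed)
    return PermutationValidation(
        observed_r2y=obs_r2y,
        observed_q2=obs_q2,
        perm_r2y=perm_r2y,
        perm_q2=perm_q2,
        valid=bool(obs_q2 > perm_q2.max()),
    )
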