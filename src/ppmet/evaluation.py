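"""Study-condition evaluation runs: calibration, recovery and oracle checks.

These functions re-create the synthetic study conditions (cohort design,
planted effect sizes, permutation counts) and measure how each stage behaves
under them — type-I calibration and recall of the temporal screen, planted
recovery and dummy-control behaviour of SVM-RFE, PLS-DA permutation
validity, and agreement of the fast implementations with brute-force
oracles. The problem sizes used here are deliberate down-scalings of the
library defaults (see docs/methods.md); the defaults themselves stay at the
full study values.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats

from . import ranking, response, screen, simulate, validation
from . import network as net

__all__ = [
    "iauc_oracle_gap",
    "betweenness_oracle_gap",
    "ora_oracle_gap",
    "bh_oracle_gap",
    "screen_type1_rate",
    "screen_recall",
    "ranking_recovery_rate",
    "dummy_error_stats",
    "plsda_validity",
    "plsda_null_q2",
    "brute_force_betweenness",
    "enumerated_ora_pvalue",
    "reference_bh",
]


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _plain_net_trapezoid(t: np.ndarray, v: np.ndarray, baseline: float) -> float:
    """Net area above minus below baseline with exact crossing splits —
    the peak-filter-free reference for the incremental AUC."""
    area = 0.0
    e = v - baseline
    for a, b, ya, yb in zip(t[:-1], t[1:], e[:-1], e[1:]):
        if (ya >= 0) == (yb >= 0):
            area += (b - a) * (ya + yb) / 2.0
        else:
            tc = a + (b - a) * (0.0 - ya) / (yb - ya)
            area += (tc - a) * ya / 2.0 + (b - tc) * yb / 2.0
    return area


def iauc_oracle_gap(n_series: int = 1000, seed: int = 0) -> float:
    """Max |compute_iauc - brute trapezoid| with the peak filters disabled."""
    rng = np.random.default_rng(seed)
    params = response.PeakParams(height_fraction=1e-9, min_adjacent_points=1)
    worst = 0.0
    for _ in range(n_series):
        n = int(rng.integers(3, 9))
        t = np.sort(rng.choice(np.arange(0, 300), size=n, replace=False)).astype(float)
        v = rng.normal(0.0, 2.0, size=n)
        baseline = float(rng.normal(0.0, 1.0))
        got, _ = response.compute_iauc(t, v, baseline, params)
        want = _plain_net_trapezoid(t, v, baseline)
        worst = max(worst, abs(got - want))
    return worst


def brute_force_betweenness(G: nx.Graph) -> dict:
    """All-pairs shortest-path enumeration of relative betweenness,
    normalized per connected component like the implementation under test."""
    bc = {v: 0.0 for v in G.nodes}
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        n = len(nodes)
        sub = G.subgraph(comp)
        for s, t in combinations(nodes, 2):
            paths = list(nx.all_shortest_paths(sub, s, t))
            sigma = len(paths)
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                bc[v] += through / sigma
        norm = (n - 1) * (n - 2) / 2.0
        if norm > 0:
            for v in nodes:
                bc[v] /= norm
    return bc


def betweenness_oracle_gap(n_graphs: int = 200, max_nodes: int = 8, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_graphs):
        n = int(rng.integers(3, max_nodes + 1))
        p = float(rng.uniform(0.2, 0.8))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
        if G.number_of_edges() == 0:
            continue
        got = net.betweenness_centrality(G)
        want = brute_force_betweenness(G)
        worst = max(worst, max(abs(got[v] - want[v]) for v in G.nodes))
    return worst


def enumerated_ora_pvalue(universe_size: int, pathway_size: int, draws: int, hits: int) -> float:
    """P(X >= hits) by exhaustive enumeration of all draws from the universe."""
    universe = list(range(universe_size))
    pathway = set(range(pathway_size))
    total = 0
    ge = 0
    for combo in combinations(universe, draws):
        total += 1
        if len(pathway & set(combo)) >= hits:
            ge += 1
    return ge / total


def ora_oracle_gap(n_cases: int = 60, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        M = int(rng.integers(5, 13))
        K = int(rng.integers(1, M + 1))
        n_draw = int(rng.integers(1, M + 1))
        universe = {f"u{i}" for i in range(M)}
        pathway = {f"u{i}" for i in range(K)}
        query = set(rng.choice(sorted(universe), size=n_draw, replace=False))
        hits = len(query & pathway)
        row = net.ora_enrich(query, {"pw": pathway}, universe=universe)
        got = float(row.loc[0, "p_raw"])
        want = enumerated_ora_pvalue(M, K, n_draw, hits)
        worst = max(worst, abs(got - want))
    return worst


def reference_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bh_oracle_gap(n_vectors: int = 1000, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 40))
        p = rng.uniform(1e-6, 1.0, size=m)
        worst = max(worst, float(np.max(np.abs(screen.bh_adjust(p) - reference_bh(p)))))
    return worst


# ---------------------------------------------------------------------------
# temporal-screen calibration
# ---------------------------------------------------------------------------

def _cohort(seed: int):
    return simulate.generate_cohort(simulate.CohortSpec(seed=seed))


def screen_type1_rate(
    n_features: int = 200, B: int = 199, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Fraction of null features with permutation p <= 0.05 (and the p's)."""
    cohort = _cohort(seed)
    fx = simulate.EffectSpec(
        n_features=n_features, n_responsive=0, n_discriminative=0,
        missing_rate=0.0, seed=seed + 1,
    )
    table, _ = simulate.generate_feature_table(cohort, fx)
    res, _ = screen.screen_features(table, screen.ScreenConfig(n_permutations=B, seed=seed + 2))
    p = res["p_perm"].to_numpy()
    return float((p <= 0.05).mean()), p


def screen_recall(
    n_features: int = 100, n_responsive: int = 10, B: int = 399, seed: int = 0
) -> float:
    """Recall of planted responsive features (amplitude >= 3x noise SD)."""
    cohort = _cohort(seed)
    fx = simulate.EffectSpec(
        n_features=n_features, n_responsive=n_responsive, n_discriminative=0,
        dose_amplitudes=(0.0, 0.25, 0.5), class_effect_size=0.0,
        noise_sd=0.15, missing_rate=0.0, seed=seed + 1,
    )
    table, truth = simulate.generate_feature_table(cohort, fx)
    _, retained = screen.screen_features(table, screen.ScreenConfig(n_permutations=B, seed=seed + 2))
    return len(set(retained) & set(truth.responsive_ids)) / len(truth.responsive_ids)


# ---------------------------------------------------------------------------
# ranking behaviour under the planted conditions
# ---------------------------------------------------------------------------

def _reduced_rfe_config(seed: int) -> ranking.RFEConfig:
    # 3x3 grid / 5 inner folds: the down-scaled tuning budget used for
    # repeated-seed property runs (library default stays 8x8 / 10-fold)
    return ranking.RFEConfig(
        seed=seed,
        cost_grid=(0.5, 8.0, 128.0),
        gamma_grid=(2.0**-7, 2.0**-3, 2.0),
        n_inner_folds=5,
    )


def ranking_recovery_rate(
    n_seeds: int = 20, n_features: int = 100, n_informative: int = 5,
    effect_size: float = 1.5, seed: int = 0,
) -> float:
    """Fraction of seeds where all planted features make the top 10 by
    average rank."""
    hits = 0
    for s in range(n_seeds):
        X, y, informative = simulate.generate_classification_matrix(
            24, n_features, n_informative, effect_size, seed=seed + s
        )
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        cfg = ranking.RFEConfig(seed=seed + s)
        avg = ranking.average_ranks(ranking.rank_features_linear_svm(X, y, cfg))
        top10 = set(np.argsort(avg, kind="stable")[:10])
        hits += set(informative) <= top10
    return hits / n_seeds


def dummy_error_stats(
    n_seeds: int = 20, n_features: int = 100, seed: int = 0,
    n_values=(1, 2, 4, 8, 16, 32),
) -> tuple[float, float]:
    """(mean dummy error over seeds, fraction of seeds whose dummy curve
    never drops below the 0.05 acceptance threshold)."""
    means = []
    never_below = 0
    for s in range(n_seeds):
        X, y, _ = simulate.generate_classification_matrix(24, n_features, 5, 1.5, seed=seed + s)
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        yd = ranking.make_dummy_labels(y, "permute_labels", seed=seed + s)
        cfg = _reduced_rfe_config(seed + s)
        per_fold = ranking.rank_features_linear_svm(X, yd, cfg)
        curve = ranking.generalized_error_curve(X, yd, per_fold, cfg, n_values=n_values)
        errs = list(curve.values())
        means.append(float(np.mean(errs)))
        never_below += min(errs) >= 0.05
    return float(np.mean(means)), never_below / n_seeds


# ---------------------------------------------------------------------------
# multivariate validation behaviour
# ---------------------------------------------------------------------------

def plsda_validity(n_seeds: int = 20, n_perm: int = 100, seed: int = 0) -> float:
    """Fraction of separable synthetic panels judged valid by permutation."""
    valid = 0
    for s in range(n_seeds):
        X, y, _ = simulate.generate_classification_matrix(24, 10, 5, 2.0, seed=seed + s)
        pv = validation.permutation_validate(X, y, n_perm=n_perm, seed=seed + s)
        valid += pv.valid
    return valid / n_seeds


def plsda_null_q2(n_seeds: int = 20, seed: int = 0) -> float:
    """Mean cross-validated Q2 on label-free noise panels (should be <= 0)."""
    q2s = []
    for s in range(n_seeds):
        X, y, _ = simulate.generate_classification_matrix(24, 10, 0, 0.0, seed=seed + s)
        q2s.append(validation.q2_crossval(X, y, seed=seed + s))
    return float(np.mean(q2s))
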