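"""End-to-end orchestration: simulate -> preprocess -> screen -> gate ->
rank -> validate -> network -> enrich, with a reproducibility manifest.

Every stage reads its inputs from, and writes its outputs to, a run
directory, so any stage can be re-executed from persisted intermediates and
produce byte-identical results. The manifest records the config echo, the
per-stage derived seeds and the SHA-256 of every written file; two runs with
the same config and seed differ only in the manifest timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import ranking, response, screen, simulate, validation
from . import network as net
from .config import PipelineConfig
from .core import FeatureTable
from .preprocess import PreprocessConfig, drift_correct_loess, impute_knn, normalize, qc_cv_filter

log = logging.getLogger("ppmet")

STAGES = (
    "simulate",
    "preprocess",
    "screen",
    "gate",
    "rank",
    "validate",
    "network",
    "enrich",
)

# fixed per-stage seed offsets keep stages independently re-runnable
_SEED_OFFSET = {name: 1000 + 17 * i for i, name in enumerate(STAGES)}


def stage_seed(cfg: PipelineConfig, stage: str) -> int:
    return (cfg.seed + _SEED_OFFSET[stage]) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, cfg: PipelineConfig, outdir: str | Path):
        self.cfg = cfg
        self.dir = Path(outdir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {
                "config": cfg.model_dump(),
                "seed": cfg.seed,
                "stages": {},
                "timestamp": None,
            }

    def record(self, stage: str, outputs: list[Path], **info) -> None:
        self.manifest["stages"][stage] = {
            "seed": stage_seed(self.cfg, stage),
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
            **info,
        }
        self.flush()

    def flush(self) -> None:
        self.manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, default=str))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, rundir: Path) -> list[Path]:
    s = cfg.simulate
    seed = stage_seed(cfg, "simulate")
    cohort_spec = simulate.CohortSpec(
        n_participants=s.n_participants,
        class_sizes=tuple(s.class_sizes),
        subset_size=s.subset_size,
        subset_split=tuple(s.subset_split),
        seed=seed,
    )
    cohort = simulate.generate_cohort(cohort_spec)
    effects = simulate.EffectSpec(
        n_features=s.n_features,
        n_responsive=s.n_responsive,
        n_discriminative=s.n_discriminative,
        dose_amplitudes=tuple(s.dose_amplitudes),
        class_effect_size=s.class_effect_size,
        noise_sd=s.noise_sd,
        random_intercept_sd=s.random_intercept_sd,
        missing_rate=s.missing_rate,
        seed=seed + 1,
    )
    table, truth = simulate.generate_feature_table(cohort, effects)
    table = simulate.generate_qc_injections(
        table, n_qc=s.n_qc, drift=s.qc_drift, noise_sd=s.qc_noise_sd,
        n_batches=s.n_batches, seed=seed + 2,
    )
    vp, mp = table.write(rundir, "raw")
    cp = rundir / "cohort.csv"
    cohort.to_csv(cp)
    tp = rundir / "ground_truth.json"
    truth.to_json(tp)
    return [vp, mp, cp, tp]


def _load_raw(cfg: PipelineConfig, rundir: Path) -> FeatureTable:
    if cfg.features_csv and cfg.metadata_csv:
        return FeatureTable.read(cfg.features_csv, cfg.metadata_csv)
    return FeatureTable.read(rundir / "raw_features.csv", rundir / "raw_metadata.csv")


def stage_preprocess(cfg: PipelineConfig, rundir: Path) -> list[Path]:
    p = cfg.preprocess
    pcfg = PreprocessConfig(
        knn_k=p.knn_k, qc_cv_limit=p.qc_cv_limit, shapiro_alpha=p.shapiro_alpha,
        loess_span=p.loess_span, scaling_mode=p.scaling_mode,  # type: ignore[arg-type]
    )
    pcfg.validate()
    table = _load_raw(cfg, rundir)
    table = impute_knn(table, k=pcfg.knn_k)
    table = drift_correct_loess(table, span=pcfg.loess_span)
    table, report = qc_cv_filter(table, limit=pcfg.qc_cv_limit)

    filtered = table.study_rows()
    fvp, fmp = filtered.write(rundir, "filtered")

    norm = normalize(filtered, pcfg)
    nvp, nmp = norm.table.write(rundir, "normalized")

    rp = rundir / "removed_features.tsv"
    report.to_csv(rp, sep="\t", index=False)
    lp = rundir / "log_transformed.txt"
    lp.write_text("\n".join(norm.log_transformed) + "\n")
    return [fvp, fmp, nvp, nmp, rp, lp]


def stage_screen(cfg: PipelineConfig, rundir: Path) -> list[Path]:
    table = FeatureTable.read(rundir / "normalized_features.csv", rundir / "normalized_metadata.csv")
    scfg = screen.ScreenConfig(
        n_permutations=cfg.screen.n_permutations,
        q_threshold=cfg.screen.q_threshold,
        seed=stage_seed(cfg, "screen"),
    )
    result, retained = screen.screen_features(table, scfg)
    sp = rundir / "screen_results.tsv"
    result.to_csv(sp, sep="\t", index=False)
    rp = rundir / "screen_retained.txt"
    rp.write_text("\n".join(retained) + "\n")
    return [sp, rp]


def stage_gate(cfg: PipelineConfig, rundir: Path) -> list[Path]:
    table = FeatureTable.read(rundir / "filtered_features.csv", rundir / "filtered_metadata.csv")
    retained = [l for l in (rundir / "screen_retained.txt").read_text().splitlines() if l]
    if not retained:
        raise RuntimeError(
            "the screen retained no features; nothing to gate "
            "(permutation count may be too low for the q threshold)"
        )
    params = response.PeakParams(
        height_fraction=cfg.gate.height_fraction,
        min_adjacent_points=cfg.gate.min_adjacent_points,
    )
    auc = response.compute_auc_records(table, retained, params)
    fc = response.compute_log2fc(auc, sig_threshold=cfg.gate.fc_threshold)
    gated, shortlist = response.gate_features(fc)
    ap = rundir / "auc_records.tsv"
    auc.to_csv(ap, sep="\t", index=False)
    fp = rundir / "fold_changes.tsv"
    gated.to_csv(fp, sep="\t", index=False)
    sp = rundir / "shortlist.txt"
    sp.write_text("\n".join(shortlist) + "\n")
    return [ap, fp, sp]


def participant_response_matrix(
    auc: pd.DataFrame, feature_ids: list[str], mode: str = "hp_minus_wc"
) -> pd.DataFrame:
    """Participant x feature design for classification.

    ``hp_minus_wc`` (default): net iAUC under the 50 g meal minus net iAUC
    under water — the participant's dose response. ``stack_meals`` keeps one
    column per feature x WPI meal.
    """
    wide = auc.pivot_table(index="participant_id", columns=["feature_id", "meal"], values="net_area")
    if mode == "hp_minus_wc":
        cols = {fid: wide[fid]["HP"] - wide[fid]["WC"] for fid in feature_ids}
        return pd.DataFrame(cols).dropna()
    if mode == "stack_meals":
        cols = {
            f"{fid}:{meal}": wide[fid][meal]
            for fid in feature_ids
            for meal in ("LP", "HP")
        }
        return pd.DataFrame(cols).dropna()
    raise ValueError(f"unknown response mode {mode!r}")


def stage_rank(cfg: PipelineConfig, rundir: Path) -> list[Path]:
    auc = pd.read_csv(rundir / "auc_records.tsv", sep="\t")
    shortlist = [l for l in (rundir / "shortlist.txt").read_text().splitlines() if l]
    if len(shortlist) < 2:
        raise RuntimeError("fewer than 2 shortlisted features; cannot rank")
    cohort = pd.read_csv(rundir / "cohort.csv", index_col="participant_id")
    Xdf = participant_response_matrix(auc, shortlist, cfg.rank.response_mode)
    y = cohort.loc[Xdf.index, cfg.rank.class_column].to_numpy()
    X = Xdf.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    r = cfg.rank
    rcfg = ranking.RFEConfig(
        n_outer_folds=min(r.n_outer_folds, len(Xdf)),
        halving_floor=r.halving_floor,
        linear_cost=r.linear_cost,
        cost_grid=tuple(2.0 ** np.asarray(r.cost_exponents, dtype=float)),
        gamma_grid=tuple(2.0 ** np.asarray(r.gamma_exponents, dtype=float)),
        n_inner_folds=r.n_inner_folds,
        error_threshold=r.error_threshold,
        seed=stage_seed(cfg, "rank"),
    )
    n_values = r.n_values or list(range(1, min(20, X.shape[1]) + 1))
    n_values = [n for n in n_values if n <= X.shape[1]]
    model = ranking.svm_rfe_model(X, y, rcfg, feature_ids=list(Xdf.columns), n_values=n_values)

    mp = rundir / "rfe_model.json"
    model.to_json(mp)
    q = pd.read_csv(rundir / "screen_results.tsv", sep="\t").set_index("feature_id")["q"]
    tp = rundir / "top_features.tsv"
    ranking.top_features_table(model, q).to_csv(tp, sep="\t", index=False)
    return [mp, tp]


def _top_panel(rundir: Path, n: int | None = None, default_n: int = 20) -> list[str]:
    model = json.loads((rundir / "rfe_model.json").read_text())
    order = np.argsort(np.asarray(model["avg_rank"]), kind="stable")
    if n is None:
        n = model["optimal_n"] or min(default_n, len(order))
    return [model["feature_ids"][i] for i in order[: min(n, len(order))]]


def stage_validate(cfg: PipelineConfig, rundir: Path) -> list[Path]:
    table = FeatureTable.read(rundir / "normalized_features.csv", rundir / "normalized_metadata.csv")
    cohort = pd.read_csv(rundir / "cohort.csv", index_col="participant_id")
    v = cfg.multivariate
    # score plots use the ranked top panel (not just the optimal-N minimum)
    panel_n = v.top_n or 20
    panel = [f for f in _top_panel(rundir, n=panel_n) if f in table.values.columns]
    sub = table.values[panel]
    y = table.meta["participant_id"].map(cohort[cfg.rank.class_column]).to_numpy()

    k = max(1, min(v.n_components, len(panel), len(sub) - 1))
    pca = validation.fit_pca(sub.to_numpy() - sub.to_numpy().mean(axis=0), n_components=k)
    pls = validation.fit_plsda(sub.to_numpy(), y, n_components=k)
    perm = validation.permutation_validate(
        sub.to_numpy(), y, n_components=k,
        n_perm=v.n_permutations, k_folds=v.k_folds, seed=stage_seed(cfg, "validate"),
    )
    out = {
        "panel": panel,
        "pca_r2x": pca.r2x.tolist(),
        "plsda_r2x_cum": pls.r2x_cum,
        "plsda_r2y_cum": pls.r2y_cum,
        "q2_cum": perm.observed_q2,
        "perm_r2y": perm.perm_r2y.tolist(),
        "perm_q2": perm.perm_q2.tolist(),
        "valid": perm.valid,
    }
    vp = rundir / "multivariate.json"
    vp.write_text(json.dumps(out, indent=1))
    sp = rundir / "plsda_scores.tsv"
    pd.DataFrame(pls.scores, index=sub.index, columns=[f"t{i+1}" for i in range(pls.scores.shape[1])]).to_csv(sp, sep="\t")
    return [vp, sp]


def stage_network(cfg: PipelineConfig, rundir: Path) -> list[Path]:
    seed = stage_seed(cfg, "network")
    # interpretation uses the ranked top panel, not just the optimal-N minimum
    panel = _top_panel(rundir, n=cfg.enrich.top_n)
    edges, roles = simulate.generate_knowledge_base(seed=seed)
    compounds = sorted(n for n, r in roles.items() if r == "compound")
    mapping = simulate.annotate_features_synthetic(
        panel, compounds, cfg.enrich.mapped_fraction, seed=seed + 1
    )
    query = sorted(set(mapping.values()))
    network = net.build_network(query, edges, roles)
    metrics = network.metrics()
    hubs = net.identify_hubs(
        network,
        net.HubCriteria(cfg.enrich.min_degree, cfg.enrich.min_bc, cfg.enrich.comparison),
        metrics=metrics,
    )
    gp = rundir / "network.graphml"
    network.write_graphml(gp)
    tp = rundir / "topology.tsv"
    metrics.to_csv(tp, sep="\t", index=False)
    hp = rundir / "hubs.tsv"
    hubs.to_csv(hp, sep="\t", index=False)
    qp = rundir / "query_compounds.txt"
    qp.write_text("\n".join(query) + "\n")
    np_, ne = network.n_nodes, network.n_edges
    (rundir / "network_summary.json").write_text(
        json.dumps({"nodes": np_, "edges": ne, "components": network.n_components})
    )
    return [gp, tp, hp, qp, rundir / "network_summary.json"]


def stage_enrich(cfg: PipelineConfig, rundir: Path) -> list[Path]:
    seed = stage_seed(cfg, "enrich")
    query = [l for l in (rundir / "query_compounds.txt").read_text().splitlines() if l]
    library, graphs = simulate.generate_pathway_library(
        n_pathways=cfg.enrich.n_pathways, seed=seed
    )
    table = net.ora_enrich(query, library, adjust=cfg.enrich.adjust, pathway_graphs=graphs)
    ep = rundir / "enrichment.tsv"
    table.to_csv(ep, sep="\t", index=False)
    return [ep]


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "screen": stage_screen,
    "gate": stage_gate,
    "rank": stage_rank,
    "validate": stage_validate,
    "network": stage_network,
    "enrich": stage_enrich,
}


def run_stage(cfg: PipelineConfig, rundir: str | Path, stage: str) -> dict:
    """Execute one stage against a run directory and update the manifest."""
    run = _Run(cfg, rundir)
    fn = _STAGE_FN[stage]
    log.info("stage %s starting", stage)
    outputs = fn(cfg, run.dir)
    info = {}
    if stage == "screen":
        info["n_retained"] = len(
            [l for l in (run.dir / "screen_retained.txt").read_text().splitlines() if l]
        )
    if stage == "gate":
        info["n_shortlisted"] = len(
            [l for l in (run.dir / "shortlist.txt").read_text().splitlines() if l]
        )
    run.record(stage, outputs, **info)
    return run.manifest


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages; abort on failure naming the stage, keeping completed
    outputs on disk. Returns the manifest."""
    manifest = None
    for stage in STAGES:
        try:
            manifest = run_stage(cfg, outdir, stage)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    # audit: the feature funnel can only narrow
    n_screen = manifest["stages"]["screen"]["n_retained"]
    n_gate = manifest["stages"]["gate"]["n_shortlisted"]
    if n_gate > n_screen:
        raise RuntimeError("gate stage produced more features than the screen retained")
    return manifest
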