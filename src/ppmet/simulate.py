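"""Synthetic crossover-study generator with known ground truth.

Emulates a three-arm postprandial crossover: each participant consumes a
water control (WC), a low-protein (LP) and a high-protein (HP) beverage on
separate visits and is sampled at five nominal times (0, 30, 60, 120,
240 min). Feature intensities are log-normal around a per-feature baseline;
*responsive* features add a dose-scaled gamma-like rise-fall excursion on the
log scale, and *discriminative* features scale that excursion differently for
the two participant classes. Participant random intercepts, instrument drift,
pooled-QC injections and sporadic whole-row missingness reproduce the
nuisance structure the downstream stages must survive.

Everything here is deterministic under its seed, and the planted truth is
returned alongside the data so recall/type-I properties of every later stage
can be measured without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MEALS, TIMES, FeatureTable, SpecificationError

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_feature_table",
    "generate_qc_injections",
    "generate_classification_matrix",
    "generate_knowledge_base",
    "generate_pathway_library",
    "annotate_features_synthetic",
    "response_curve",
]


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Participant-level design of the crossover cohort.

    Defaults mirror a cohort of 24 overweight women with prediabetes split
    12/12 by ethnicity, of whom 20 carry an MRI-derived pancreas-fat label
    split 10/10 at the cohort median.
    """

    n_participants: int = 24
    class_name: str = "ethnicity"
    class_labels: tuple[str, str] = ("Caucasian", "Chinese")
    class_sizes: tuple[int, int] = (12, 12)
    subset_name: str | None = "ipfd"
    subset_labels: tuple[str, str] = ("low", "high")
    subset_size: int = 20
    subset_split: tuple[int, int] = (10, 10)
    age_mean_by_class: tuple[float, float] = (54.7, 42.0)
    age_sd: float = 12.0
    bmi_mean_by_class: tuple[float, float] = (31.4, 26.9)
    bmi_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if sum(self.class_sizes) != self.n_participants:
            raise SpecificationError(
                f"class_sizes {self.class_sizes} must sum to n_participants {self.n_participants}"
            )
        if self.subset_name is not None:
            if sum(self.subset_split) != self.subset_size:
                raise SpecificationError("subset_split must sum to subset_size")
            if self.subset_size > self.n_participants:
                raise SpecificationError("subset_size cannot exceed n_participants")
        if self.age_sd < 0 or self.bmi_sd < 0:
            raise SpecificationError("standard deviations must be non-negative")


@dataclass(frozen=True)
class EffectSpec:
    """Feature-level effect structure planted into the intensity matrix.

    ``dose_amplitudes`` are log-scale excursion amplitudes for WC < LP < HP.
    The water control keeps a small nonzero amplitude by default so that
    downstream incremental-AUC fold changes against it are well defined.
    ``class_effect_size`` multiplies the amplitude of discriminative features
    for the second class (amplitude ratio ``1 + class_effect_size``).
    """

    n_features: int = 300
    n_responsive: int = 40
    n_discriminative: int = 10
    dose_amplitudes: tuple[float, float, float] = (0.1, 0.4, 0.8)
    class_effect_size: float = 1.0
    peak_time_min: float = 60.0
    curve_sharpness: float = 2.0
    noise_sd: float = 0.15
    random_intercept_sd: float = 0.25
    batch_drift_slope: float = 0.0
    missing_rate: float = 0.006
    baseline_log_mean: float = 11.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_features <= 0:
            raise SpecificationError("n_features must be positive")
        if not (0 <= self.n_discriminative <= self.n_responsive <= self.n_features):
            raise SpecificationError(
                "need n_discriminative <= n_responsive <= n_features"
            )
        if any(b < a for a, b in zip(self.dose_amplitudes, self.dose_amplitudes[1:])):
            raise SpecificationError("dose_amplitudes must be non-decreasing (WC <= LP <= HP)")
        for name in ("noise_sd", "random_intercept_sd", "baseline_log_sd"):
            if getattr(self, name) < 0:
                raise SpecificationError(f"{name} must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise SpecificationError("missing_rate must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Planted truth: which features respond, which discriminate, and how."""

    responsive_ids: list[str]
    discriminative_ids: list[str]
    #: feature_id -> meal -> class label -> log-scale amplitude
    amplitudes: dict[str, dict[str, dict[str, float]]]

    def __post_init__(self) -> None:
        if not set(self.discriminative_ids) <= set(self.responsive_ids):
            raise SpecificationError("discriminative_ids must be a subset of responsive_ids")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# cohort and feature-table generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a participant table (id, class label, subset label, age, BMI)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pids = [f"P{i + 1:02d}" for i in range(spec.n_participants)]
    classes = np.repeat(list(spec.class_labels), list(spec.class_sizes))

    class_idx = np.array([spec.class_labels.index(c) for c in classes])
    ages = rng.normal(np.array(spec.age_mean_by_class)[class_idx], spec.age_sd)
    bmis = rng.normal(np.array(spec.bmi_mean_by_class)[class_idx], spec.bmi_sd)
    ages = np.clip(ages, 20.0, 69.0).round(1)
    bmis = np.clip(bmis, 19.6, 36.8).round(1)

    cohort = pd.DataFrame(
        {
            "participant_id": pids,
            spec.class_name: classes,
            "age": ages,
            "bmi": bmis,
        }
    ).set_index("participant_id")

    if spec.subset_name is not None:
        chosen = rng.choice(spec.n_participants, size=spec.subset_size, replace=False)
        order = rng.permutation(spec.subset_size)
        labels = np.repeat(list(spec.subset_labels), list(spec.subset_split))[order]
        col = pd.Series(pd.NA, index=cohort.index, dtype="object")
        col.iloc[np.sort(chosen)] = labels[np.argsort(np.argsort(chosen))]
        cohort[spec.subset_name] = col
    return cohort


def response_curve(t, peak_time_min: float = 60.0, sharpness: float = 2.0):
    """Gamma-like rise-fall excursion, 0 at t=0, maximum 1 at ``peak_time_min``.

    Postprandial metabolite excursions rise from the fasted baseline and
    relax back towards it; this two-parameter family reproduces that shape at
    the five design times without pretending to model absorption kinetics.
    """
    t = np.asarray(t, dtype=float)
    x = np.clip(t / peak_time_min, 0.0, None)
    with np.errstate(divide="ignore"):
        c = np.where(x > 0, np.exp(sharpness * (np.log(x) + 1.0 - x)), 0.0)
    return c


def _feature_ids(rng: np.random.Generator, n: int) -> list[str]:
    ids: list[str] = []
    seen: set[str] = set()
    while len(ids) < n:
        mz = rng.uniform(60, 1100)
        rt = rng.integers(30, 1020)
        fid = f"mz{mz:.3f}_rt{int(rt)}"
        if fid not in seen:
            seen.add(fid)
            ids.append(fid)
    return ids


def generate_feature_table(
    cohort: pd.DataFrame, effects: EffectSpec
) -> tuple[FeatureTable, GroundTruth]:
    """Simulate the full participant x meal x time intensity matrix.

    Returns the table (rows possibly dropped at ``missing_rate``) and the
    planted :class:`GroundTruth`.
    """
    if cohort.empty:
        raise SpecificationError("cohort must be nonempty")
    effects.validate()
    rng = np.random.default_rng(effects.seed)

    fids = _feature_ids(rng, effects.n_features)
    responsive = list(rng.choice(fids, size=effects.n_responsive, replace=False))
    discriminative = list(rng.choice(responsive, size=effects.n_discriminative, replace=False))

    class_col = next(
        (c for c in cohort.columns if c not in ("age", "bmi") and cohort[c].notna().all()),
        None,
    )
    class_labels = (
        list(pd.unique(cohort[class_col])) if class_col is not None else ["all"]
    )

    baselines = rng.normal(effects.baseline_log_mean, effects.baseline_log_sd, effects.n_features)
    curve = response_curve(np.array(TIMES), effects.peak_time_min, effects.curve_sharpness)

    # amplitude lookup: feature x meal x class
    amplitudes: dict[str, dict[str, dict[str, float]]] = {}
    for j, fid in enumerate(fids):
        if fid not in responsive:
            continue
        per_meal: dict[str, dict[str, float]] = {}
        for m, meal in enumerate(MEALS):
            base_amp = effects.dose_amplitudes[m]
            per_class = {}
            for k, lab in enumerate(class_labels):
                mult = 1.0 + effects.class_effect_size if (
                    fid in discriminative and k == 1
                ) else 1.0
                per_class[str(lab)] = base_amp * mult
            per_meal[meal] = per_class
        amplitudes[fid] = per_meal

    participants = list(cohort.index)
    n_p = len(participants)
    intercepts = rng.normal(0.0, effects.random_intercept_sd, size=(n_p, effects.n_features))

    amp_vec = {
        (meal, str(lab)): np.array(
            [amplitudes.get(fid, {}).get(meal, {}).get(str(lab), 0.0) for fid in fids]
        )
        for meal in MEALS
        for lab in class_labels
    }

    rows = []
    meta_rows = []
    index = []
    for i, pid in enumerate(participants):
        lab = str(cohort.loc[pid, class_col]) if class_col is not None else "all"
        for m, meal in enumerate(MEALS):
            for ti, t in enumerate(TIMES):
                log_y = baselines + intercepts[i] + amp_vec[(meal, lab)] * curve[ti]
                if effects.noise_sd > 0:
                    log_y = log_y + rng.normal(0.0, effects.noise_sd, effects.n_features)
                rows.append(np.exp(log_y))
                index.append(f"{pid}_{meal}_{t}")
                meta_rows.append(
                    {
                        "participant_id": pid,
                        "meal": meal,
                        "time_min": t,
                        "age": cohort.loc[pid, "age"],
                        "bmi": cohort.loc[pid, "bmi"],
                        "batch": 1,
                        "injection_order": pd.NA,
                        "is_qc": False,
                    }
                )

    values = pd.DataFrame(np.asarray(rows), index=index, columns=fids)
    meta = pd.DataFrame(meta_rows, index=index)
    for col in cohort.columns:
        if col in ("age", "bmi"):
            continue
        meta[col] = meta["participant_id"].map(cohort[col]).to_numpy()

    if effects.missing_rate > 0:
        keep = rng.random(len(values)) >= effects.missing_rate
        values, meta = values.loc[keep], meta.loc[keep]

    truth = GroundTruth(
        responsive_ids=responsive,
        discriminative_ids=discriminative,
        amplitudes=amplitudes,
    )
    return FeatureTable(values, meta), truth


def generate_qc_injections(
    table: FeatureTable,
    n_qc: int = 10,
    drift: float = 0.0,
    noise_sd: float = 0.0,
    n_batches: int = 1,
    seed: int = 0,
) -> FeatureTable:
    """Interleave pooled-QC injections and assign batch/injection order.

    QC intensities are the pooled per-feature mean of all study samples,
    multiplied by the drift factor ``1 + drift * position`` at the QC's
    injection position within its batch (plus log-normal noise). The same
    drift factor is applied to study samples, so the QC series carries
    exactly the technical trend that :func:`ppmet.preprocess.drift_correct_loess`
    must remove.
    """
    if n_qc < 2:
        raise SpecificationError(
            "n_qc must be >= 2 per batch: LOESS drift correction needs at least two QC anchors"
        )
    if n_batches < 1:
        raise SpecificationError("n_batches must be >= 1")
    rng = np.random.default_rng(seed)

    study = table.study_rows()
    pooled = study.values.mean(axis=0).to_numpy()
    n_study = len(study.values)
    batch_sizes = [len(b) for b in np.array_split(np.arange(n_study), n_batches)]

    v_blocks, m_blocks = [], []
    start = 0
    for b, size in enumerate(batch_sizes, start=1):
        sample_idx = np.arange(start, start + size)
        start += size
        n_slots = size + n_qc
        qc_pos = np.unique(np.round(np.linspace(0, n_slots - 1, n_qc)).astype(int))
        factor_all = 1.0 + drift * np.arange(n_slots, dtype=float)
        if np.any(factor_all <= 0):
            raise SpecificationError("drift slope drives intensities non-positive")

        sample_pos = np.setdiff1d(np.arange(n_slots), qc_pos)
        sv = study.values.iloc[sample_idx].to_numpy() * factor_all[sample_pos][:, None]
        sm = study.meta.iloc[sample_idx].copy()
        sm["batch"] = b
        sm["injection_order"] = sample_pos
        v_blocks.append(pd.DataFrame(sv, index=study.values.index[sample_idx], columns=table.feature_ids))
        m_blocks.append(sm)

        qv = pooled[None, :] * factor_all[qc_pos][:, None]
        if noise_sd > 0:
            qv = qv * np.exp(rng.normal(0.0, noise_sd, size=qv.shape))
        qidx = [f"QC_b{b}_{i + 1}" for i in range(len(qc_pos))]
        qm = pd.DataFrame(
            {
                "participant_id": "QC",
                "meal": pd.NA,
                "time_min": pd.NA,
                "age": np.nan,
                "bmi": np.nan,
                "batch": b,
                "injection_order": qc_pos,
                "is_qc": True,
            },
            index=qidx,
        )
        for col in study.meta.columns:
            if col not in qm.columns:
                qm[col] = pd.NA
        v_blocks.append(pd.DataFrame(qv, index=qidx, columns=table.feature_ids))
        m_blocks.append(qm[study.meta.columns])

    values = pd.concat(v_blocks)
    meta = pd.concat(m_blocks)
    meta["injection_order"] = meta["injection_order"].astype("Int64")
    meta["batch"] = meta["batch"].astype("Int64")
    return FeatureTable(values, meta)


# ---------------------------------------------------------------------------
# classification-matrix shortcut for the ranking stage
# ---------------------------------------------------------------------------

def generate_classification_matrix(
    n_samples: int = 24,
    n_features: int = 100,
    n_informative: int = 5,
    effect_size: float = 1.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Participant-level matrix with planted class-discriminating columns.

    Informative columns have class means separated by ``effect_size`` standard
    deviations; the rest are pure noise. Returns ``(X, y, informative_idx)``
    with ``y`` a balanced 0/1 vector.
    """
    rng = np.random.default_rng(seed)
    y = np.zeros(n_samples, dtype=int)
    y[n_samples // 2 :] = 1
    X = rng.normal(size=(n_samples, n_features))
    informative = list(rng.choice(n_features, size=n_informative, replace=False))
    X[:, informative] += np.outer(y, np.full(n_informative, effect_size))
    return X, y, informative


# ---------------------------------------------------------------------------
# toy knowledge base and pathway library for the network/enrichment stage
# ---------------------------------------------------------------------------

def generate_knowledge_base(
    n_compounds: int = 120,
    n_reactions: int = 90,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Small compound/reaction/enzyme/gene graph standing in for a metabolic
    knowledge base (synthetic; real databases are inputs, not bundled).

    Each reaction links 2-3 compounds and hangs an enzyme and a gene off it,
    mimicking the compound-reaction-enzyme-gene expansion a pathway-based
    network build performs.
    """
    rng = np.random.default_rng(seed)
    compounds = [f"C{i:04d}" for i in range(1, n_compounds + 1)]
    edges: list[tuple[str, str]] = []
    roles: dict[str, str] = {c: "compound" for c in compounds}
    for r in range(1, n_reactions + 1):
        rid, eid, gid = f"R{r:04d}", f"E{r:04d}", f"G{r:04d}"
        roles[rid], roles[eid], roles[gid] = "reaction", "enzyme", "gene"
        k = int(rng.integers(2, 4))
        for c in rng.choice(compounds, size=k, replace=False):
            edges.append((str(c), rid))
        edges.append((rid, eid))
        edges.append((eid, gid))
    return edges, roles


def generate_pathway_library(
    compounds: list[str] | None = None,
    n_pathways: int = 80,
    min_size: int = 5,
    max_size: int = 40,
    seed: int = 0,
) -> tuple[dict[str, set[str]], dict[str, list[tuple[str, str]]]]:
    """Pathway name -> compound set, plus a connected edge list per pathway
    (for topology-based impact). Sized to mirror an 80-pathway backend."""
    rng = np.random.default_rng(seed)
    if compounds is None:
        compounds = [f"C{i:04d}" for i in range(1, 121)]
    sets: dict[str, set[str]] = {}
    graphs: dict[str, list[tuple[str, str]]] = {}
    for i in range(1, n_pathways + 1):
        size = int(rng.integers(min_size, max_size + 1))
        members = [str(c) for c in rng.choice(compounds, size=min(size, len(compounds)), replace=False)]
        name = f"pathway_{i:02d}"
        sets[name] = set(members)
        # random spanning tree plus a few chords keeps the pathway connected
        order = list(rng.permutation(members))
        edges = [(order[j], order[int(rng.integers(0, j))]) for j in range(1, len(order))]
        for _ in range(len(members) // 4):
            u, v = rng.choice(members, size=2, replace=False)
            if u != v:
                edges.append((str(u), str(v)))
        graphs[name] = edges
    return sets, graphs


def annotate_features_synthetic(
    feature_ids: list[str],
    compounds: list[str],
    mapped_fraction: float = 0.8,
    seed: int = 0,
) -> dict[str, str]:
    """Synthetic feature -> compound annotation map.

    Real annotation (library/HMDB matching) is upstream of this package; this
    stand-in deterministically maps a fraction of features onto knowledge-base
    compounds so the network stage can be exercised end to end.
    """
    rng = np.random.default_rng(seed)
    n_map = min(int(round(mapped_fraction * len(feature_ids))), len(compounds))
    chosen = rng.choice(len(feature_ids), size=n_map, replace=False)
    targets = rng.choice(compounds, size=n_map, replace=False)
    return {feature_ids[i]: str(t) for i, t in zip(chosen, targets)}
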