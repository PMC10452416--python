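"""End-to-end screening pipeline, group statistics, and PSD reports.

``run_pipeline`` chains the full protocol on a cohort manifest: feature
extraction per modality and task, EEG band selection, RFECV subset
selection per modality, repeated-LOOCV evaluation of every classifier on
every modality combination, cross-task feature concatenation, and
accuracy-weighted decision voting.  The report replicates the layout of a
modality-combination results table (classifier x combination x task /
all-tasks / weighted-voting) and embeds the resolved configuration, its
hash, the seed and the package version, so equal hashes imply identical
reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations as _combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as spst
from statsmodels.stats.multitest import multipletests

from . import __version__
from .classify import (
    ClassifierSpec,
    compute_task_weights,
    encode_labels,
    fuse_features,
    loocv_evaluate,
    weighted_vote,
    _metrics,
)
from .cohort import (
    CohortManifest,
    read_audio,
    read_digital,
    read_eeg_csv,
    read_manifest,
    read_transcript,
)
from .digital import clean_digital, extract_digital_features
from .eeg import (
    BAND_ORDER,
    DEFAULT_BANDS,
    band_power,
    bandpass_filter,
    clean_artifacts,
    extract_eeg_features,
)
from .features import FeatureVector
from .selection import band_of_feature, rfecv_select, select_bands
from .speech import SpeechConfig, extract_speech_features

__all__ = [
    "PipelineConfig",
    "extract_cohort_features",
    "run_pipeline",
    "group_stats",
    "psd_report",
]

log = logging.getLogger("mciscreen")

MODALITY_COMBOS: tuple[tuple[str, ...], ...] = tuple(
    combo
    for k in (1, 2, 3)
    for combo in _combinations(("eeg", "speech", "digital"), k)
)


@dataclass
class PipelineConfig:
    """Everything a run needs; fully serializable, embedded in every report."""

    manifest: str = "manifest.csv"
    seed: int = 0
    classifiers: tuple[str, ...] = ("DT", "RF", "SVM", "XGB")
    evaluation_repeats: int = 1
    band_selection_repeats: int = 5
    band_selection_classifier: str = "SVM"
    rfecv_estimator: str = "RF"
    rfecv_cv: int = 5
    selection_mode: str = "global"  # or "nested"
    artifact_method: str = "none"  # "none" | "amplitude_reject" | "ica"
    eeg_bandpass: tuple[float, float] = (0.1, 45.0)

    def __post_init__(self) -> None:
        if self.selection_mode not in ("global", "nested"):
            raise ValueError("selection_mode must be 'global' or 'nested'")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Cohort-level feature extraction


def extract_cohort_features(
    manifest: CohortManifest,
    cfg: PipelineConfig | None = None,
    speech_cfg: SpeechConfig | None = None,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Extract all three modality tables for every task.

    Returns ``{task: {"eeg": df, "speech": df, "digital": df}}`` with rows
    indexed by participant id.  EEG traces are band-passed (and optionally
    artifact-cleaned) before the 80-feature bank; digital parameters are
    cleaned cohort-wide per task before featurization.  Incomplete
    participant-task cells are skipped (they were flagged at read time).
    """
    cfg = cfg or PipelineConfig()
    speech_cfg = speech_cfg or SpeechConfig()
    labels = manifest.labels()
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for task in manifest.tasks:
        eeg_rows: dict[str, FeatureVector] = {}
        speech_rows: dict[str, FeatureVector] = {}
        digital_raw: list[dict] = []
        for pid, t in manifest.complete_cells():
            if t != task:
                continue
            rec = read_eeg_csv(manifest.path(pid, task, "eeg_task"), state="task",
                               task_id=task)
            rec = bandpass_filter(rec, *cfg.eeg_bandpass)
            if cfg.artifact_method != "none":
                rec, _ = clean_artifacts(rec, method=cfg.artifact_method)
            eeg_rows[pid] = extract_eeg_features(rec)

            audio = read_audio(manifest.path(pid, task, "audio"), task_id=task)
            transcript = read_transcript(manifest.path(pid, task, "transcript"),
                                         task_id=task)
            speech_rows[pid] = extract_speech_features(audio, transcript, speech_cfg)

            dp = read_digital(manifest.path(pid, task, "digital"), task_id=task)
            digital_raw.append(
                {
                    "participant_id": pid,
                    "group": labels[pid],
                    "task_id": task,
                    "total_test_time": np.nan if dp.total_test_time is None
                    else dp.total_test_time,
                    "recording_duration": np.nan if dp.recording_duration is None
                    else dp.recording_duration,
                }
            )
        digital_df = pd.DataFrame(digital_raw).set_index("participant_id")
        cleaned, _report = clean_digital(digital_df, group_cols=("group", "task_id"))
        digital_features = pd.DataFrame(
            {
                pid: extract_digital_features(cleaned.loc[pid]).to_series()
                for pid in cleaned.index
            }
        ).T
        out[task] = {
            "eeg": pd.DataFrame({p: v.to_series() for p, v in eeg_rows.items()}).T,
            "speech": pd.DataFrame({p: v.to_series() for p, v in speech_rows.items()}).T,
            "digital": digital_features,
        }
    return out


# ---------------------------------------------------------------------------
# The full protocol


def _select_subsets(
    tables: dict[str, pd.DataFrame],
    y: pd.Series,
    cfg: PipelineConfig,
) -> tuple[dict[str, list[str]], dict]:
    """Band selection on the EEG table, then RFECV per modality."""
    band_clf = ClassifierSpec(cfg.band_selection_classifier, seed=cfg.seed)
    band_result = select_bands(
        tables["eeg"], y, clf=band_clf, repeats=cfg.band_selection_repeats
    )
    eeg_cols = [
        c for c in tables["eeg"].columns if band_of_feature(c) in band_result.chosen
    ]
    subsets: dict[str, list[str]] = {}
    est = ClassifierSpec(cfg.rfecv_estimator, seed=cfg.seed)
    for modality, table in (
        ("eeg", tables["eeg"][eeg_cols]),
        ("speech", tables["speech"]),
        ("digital", tables["digital"]),
    ):
        sub = rfecv_select(table, y, estimator=est, cv=cfg.rfecv_cv)
        subsets[modality] = sub.features
    audit = {
        "chosen_bands": list(band_result.chosen),
        "band_accuracies": {"+".join(c): a for c, a in band_result.accuracies.items()},
        "tie_break": band_result.tie_break,
        "subset_sizes": {m: len(f) for m, f in subsets.items()},
    }
    return subsets, audit


def _nested_loocv(
    tables: dict[str, pd.DataFrame],
    combo: tuple[str, ...],
    y: pd.Series,
    clf: ClassifierSpec,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """LOOCV with band/RFECV selection redone inside each training fold."""
    fused_all, _ = fuse_features({m: tables[m] for m in combo})
    ids = list(fused_all.index)
    yb = pd.Series(encode_labels(y.loc[ids]), index=ids)
    proba = pd.DataFrame(0.0, index=ids, columns=["HC", "MCI"])
    labels = pd.Series(0, index=ids)
    from .classify import make_estimator

    for pid in ids:
        train = [i for i in ids if i != pid]
        sub_tables = {m: tables[m].loc[train] for m in combo}
        if "eeg" in combo:
            fold_cfg = PipelineConfig(**{**cfg.to_dict(), "band_selection_repeats": 1})
        else:
            fold_cfg = cfg
        full = {m: tables[m] for m in ("eeg", "speech", "digital")}
        train_full = {m: t.loc[train] for m, t in full.items()}
        subsets, _ = _select_subsets(train_full, y.loc[train], fold_cfg)
        X_train, _ = fuse_features(sub_tables, {m: subsets[m] for m in combo})
        X_test, _ = fuse_features(
            {m: tables[m].loc[[pid]] for m in combo}, {m: subsets[m] for m in combo}
        )
        est = make_estimator(clf, probability=True)
        est.fit(X_train.to_numpy(float), yb.loc[train].to_numpy())
        p = est.predict_proba(X_test.to_numpy(float))[0]
        classes = list(est.classes_)
        proba.loc[pid, "HC"] = p[classes.index(0)]
        proba.loc[pid, "MCI"] = p[classes.index(1)]
        labels.loc[pid] = int(proba.loc[pid, "MCI"] >= proba.loc[pid, "HC"])
    proba["label"] = labels
    return proba


def run_pipeline(
    cfg: PipelineConfig,
    manifest: CohortManifest | None = None,
    features: dict[str, dict[str, pd.DataFrame]] | None = None,
) -> dict:
    """Execute extract -> select -> evaluate -> fuse -> weighted vote.

    ``features`` may be passed to reuse already-extracted tables (the CLI
    caches them); otherwise the manifest is read and extracted.  Returns a
    JSON-serializable report with one row per classifier x modality
    combination x (task..., all_tasks, weighted_voting).
    """
    t0 = time.time()
    if features is None:
        if manifest is None:
            manifest = read_manifest(cfg.manifest)
        log.info("extracting features for %d participants", len(manifest.participants))
        features = extract_cohort_features(manifest, cfg)
    if manifest is None:
        raise ValueError("need a manifest (or pass features extracted from one)")
    labels = pd.Series(manifest.labels())

    # --- selection (global mode: once, on the full cohort) ---
    subsets: dict[str, dict[str, list[str]]] = {}
    selection_audit: dict[str, dict] = {}
    if cfg.selection_mode == "global":
        for task, tables in features.items():
            y = labels.loc[tables["eeg"].index]
            try:
                subsets[task], selection_audit[task] = _select_subsets(tables, y, cfg)
            except Exception as exc:
                raise RuntimeError(f"[selection stage, {task}] {exc}") from exc
            log.info("task %s: chosen bands %s, subset sizes %s", task,
                     selection_audit[task]["chosen_bands"],
                     selection_audit[task]["subset_sizes"])

    rows: list[dict] = []
    decisions: dict[str, dict[tuple[str, tuple[str, ...]], pd.DataFrame]] = {}
    task_acc: dict[tuple[str, tuple[str, ...]], dict[str, float]] = {}

    for kind in cfg.classifiers:
        clf = ClassifierSpec(kind, seed=cfg.seed)
        for combo in MODALITY_COMBOS:
            per_task_fused: dict[str, pd.DataFrame] = {}
            for task, tables in features.items():
                y = labels.loc[tables["eeg"].index]
                if cfg.selection_mode == "nested":
                    scores = _nested_loocv(tables, combo, y, clf, cfg)
                    fused = None
                    res_metrics = _metrics(
                        encode_labels(y.loc[scores.index]),
                        scores["label"].to_numpy(),
                    )
                    acc = res_metrics["accuracy"]
                    rows.append(
                        {"classifier": kind, "modalities": "+".join(combo),
                         "task": task, **res_metrics}
                    )
                else:
                    sub = {m: subsets[task][m] for m in combo}
                    fused, _ = fuse_features({m: tables[m] for m in combo}, sub)
                    res = loocv_evaluate(
                        fused, y.loc[fused.index], clf,
                        repeats=cfg.evaluation_repeats, probability=True,
                    )
                    acc = res.accuracy
                    rows.append(
                        {"classifier": kind, "modalities": "+".join(combo),
                         "task": task, **res.summary()}
                    )
                    scores = res.scores
                    per_task_fused[task] = fused.add_prefix(f"{task}.")
                decisions.setdefault(task, {})[(kind, combo)] = scores
                task_acc.setdefault((kind, combo), {})[task] = acc

            if cfg.selection_mode == "global" and len(per_task_fused) >= 2:
                # all-tasks row: concatenate the tasks' fused vectors
                concat, _ = fuse_features(per_task_fused)
                res = loocv_evaluate(
                    concat, labels.loc[concat.index], clf,
                    repeats=cfg.evaluation_repeats, probability=True,
                )
                rows.append(
                    {"classifier": kind, "modalities": "+".join(combo),
                     "task": "all_tasks", **res.summary()}
                )

            if len(features) >= 2:
                accs = task_acc[(kind, combo)]
                if sum(accs.values()) > 0:
                    weights = compute_task_weights(accs)
                else:  # every task at accuracy 0: weights undefined, vote uniformly
                    log.warning("all task accuracies 0 for %s/%s; uniform weights",
                                kind, "+".join(combo))
                    weights = {t: 1.0 / len(accs) for t in accs}
                votes, _ = weighted_vote(
                    {t: decisions[t][(kind, combo)] for t in features}, weights
                )
                ids = votes.index
                vote_metrics = _metrics(
                    encode_labels(labels.loc[ids]), encode_labels(votes)
                )
                rows.append(
                    {"classifier": kind, "modalities": "+".join(combo),
                     "task": "weighted_voting", **vote_metrics,
                     "weights": {t: round(w, 5) for t, w in weights.items()}}
                )

    report = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "selection_mode": cfg.selection_mode,
        "selection": selection_audit,
        "subsets": subsets,
        "metrics": rows,
        "n_participants": len(manifest.participants),
        "tasks": list(features),
        "runtime_s": round(time.time() - t0, 2),
    }
    return report


def metrics_frame(report: dict) -> pd.DataFrame:
    """The report's metric rows as a tidy DataFrame."""
    return pd.DataFrame(report["metrics"])


# ---------------------------------------------------------------------------
# Group statistics (demographics table / speech bar-chart style)


def group_stats(
    features: pd.DataFrame,
    labels: pd.Series,
    categorical: tuple[str, ...] = (),
    alpha_variance: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-group comparison with significance stars.

    Continuous features get a two-sample t-test -- Student's when an
    F-test accepts equal variances, Welch's (the heterogeneity-corrected
    t'-test) when it rejects at ``alpha_variance``.  Categorical features
    get a chi-square test on the contingency table.  Raw p-values carry
    stars at 0.05 (*) and 0.01 (**); a Benjamini-Hochberg adjusted column
    is reported alongside.
    """
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    g1, g2 = sorted(groups, reverse=True)  # MCI first when present
    rows = []
    for col in features.columns:
        x = features.loc[labels == g1, col]
        z = features.loc[labels == g2, col]
        if col in categorical:
            table = pd.crosstab(labels, features[col])
            chi2, p, _, _ = spst.chi2_contingency(table)
            rows.append(
                {"feature": col, "test": "chi2", "statistic": float(chi2), "p": float(p),
                 f"{g1}_mean": np.nan, f"{g1}_std": np.nan,
                 f"{g2}_mean": np.nan, f"{g2}_std": np.nan}
            )
            continue
        x = pd.to_numeric(x, errors="coerce").dropna()
        z = pd.to_numeric(z, errors="coerce").dropna()
        if len(x) < 2 or len(z) < 2:
            rows.append(
                {"feature": col, "test": "skipped_n_lt_2", "statistic": np.nan,
                 "p": np.nan, f"{g1}_mean": x.mean(), f"{g1}_std": x.std(),
                 f"{g2}_mean": z.mean(), f"{g2}_std": z.std()}
            )
            continue
        vx, vz = x.var(ddof=1), z.var(ddof=1)
        if vx > 0 and vz > 0:
            f_stat = vx / vz
            p_var = 2 * min(
                spst.f.cdf(f_stat, len(x) - 1, len(z) - 1),
                spst.f.sf(f_stat, len(x) - 1, len(z) - 1),
            )
            equal_var = p_var >= alpha_variance
        else:
            equal_var = True
        t, p = spst.ttest_ind(x, z, equal_var=equal_var)
        rows.append(
            {"feature": col, "test": "t" if equal_var else "t_welch",
             "statistic": float(t), "p": float(p),
             f"{g1}_mean": float(x.mean()), f"{g1}_std": float(x.std(ddof=1)),
             f"{g2}_mean": float(z.mean()), f"{g2}_std": float(z.std(ddof=1))}
        )
    out = pd.DataFrame(rows).set_index("feature")
    tested = out["p"].notna()
    out["stars"] = ""
    out.loc[tested & (out["p"] < 0.05), "stars"] = "*"
    out.loc[tested & (out["p"] < 0.01), "stars"] = "**"
    out["p_bh"] = np.nan
    if tested.any():
        out.loc[tested, "p_bh"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Band-wise PSD report


def psd_report(recordings: dict[tuple[str, str], list]) -> pd.DataFrame:
    """Per band x group x state mean band power, with task-minus-rest contrasts.

    ``recordings`` maps (group, state) -> list of EEGRecording; the mean
    is over recordings and channels.  The returned frame has one row per
    (band, group, state) plus contrast rows (state="task_minus_rest")
    whenever a group has both states.
    """
    rows = []
    by_group_state: dict[tuple[str, str], dict[str, float]] = {}
    for (group, state), recs in recordings.items():
        if not recs:
            continue
        band_means = {}
        for band in DEFAULT_BANDS:
            vals = [
                band_power(rec.channel(ch), rec.fs, band)
                for rec in recs
                for ch in rec.channels
            ]
            band_means[band.name] = float(np.mean(vals))
        by_group_state[(group, state)] = band_means
        for b in BAND_ORDER:
            rows.append(
                {"band": b, "group": group, "state": state,
                 "mean_band_power": band_means[b]}
            )
    groups = {g for g, _ in by_group_state}
    for g in sorted(groups):
        if (g, "task") in by_group_state and (g, "resting") in by_group_state:
            for b in BAND_ORDER:
                rows.append(
                    {"band": b, "group": g, "state": "task_minus_rest",
                     "mean_band_power": by_group_state[(g, "task")][b]
                     - by_group_state[(g, "resting")][b]}
                )
        else:
            log.warning("group %s missing a state; contrast omitted", g)
    return pd.DataFrame(rows)
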