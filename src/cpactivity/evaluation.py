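"""Cross-validation, free-living evaluation, and stratified reporting.

Group (G) and group-personalized (GP) models are evaluated with
leave-one-subject-out cross-validation -- GP within each GMFCS level, the
held-out child being predicted by the model of their own level trained on
that level's remaining children.  Fully-personalized (FP) models are
evaluated with 10-fold cross-validation within each subject.  Feature
selection (and any hyperparameter tuning) is refit inside each fold's
training data.

Confusion matrices follow the rows-predicted / columns-observed convention
with the fixed class order (SED, SUM, WALK); column-normalized percentages
sum to 100 per observed class.  Overall accuracy is window-pooled within each
stratum; per-class recalls are additionally reported as across-subject
mean (SD, n-1 denominator).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .cohort import CLASSES
from .models import ModelConfig, TrainedModel

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = ("subject_id", "gmfcs_level", "model_type",
                      "placement_set", "truth", "pred")


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Splitters
# ---------------------------------------------------------------------------

def loso_split(table: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-subject-out folds; test sets partition the table rows."""
    subjects = sorted(pd.unique(table["subject_id"]))
    if len(subjects) < 2:
        raise EvaluationError(
            "LOSO requires >= 2 subjects; use kfold_split for a single "
            "subject")
    idx = np.arange(len(table))
    sid = table["subject_id"].to_numpy()
    folds = []
    for s in subjects:
        mask = sid == s
        folds.append((idx[~mask], idx[mask]))
    return folds


def kfold_split(subject_table: pd.DataFrame, k: int = 10,
                seed: int = 0, max_retries: int = 20
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random near-equal k-fold partition of one subject's windows.

    Deterministic given ``seed``.  Partitions are re-drawn (bounded retries)
    until every fold's training portion contains >= 2 classes.
    """
    n = len(subject_table)
    if n < k:
        raise EvaluationError(f"subject has {n} rows, fewer than k={k}")
    labels = subject_table["label"].to_numpy()
    for attempt in range(max_retries):
        rng = np.random.default_rng([int(seed), attempt])
        perm = rng.permutation(n)
        parts = np.array_split(perm, k)
        ok = all(len(np.unique(labels[np.setdiff1d(perm, p)])) >= 2
                 for p in parts)
        if ok:
            idx = np.arange(n)
            folds = []
            for p in parts:
                mask = np.zeros(n, dtype=bool)
                mask[p] = True
                folds.append((idx[~mask], idx[mask]))
            return folds
    raise EvaluationError(
        "could not build k folds whose training splits all contain >= 2 "
        "classes (class scarcity)")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _fit_predict_fold(train: pd.DataFrame, test: pd.DataFrame,
                      config: ModelConfig, scope: str) -> np.ndarray:
    model = _models.train(train, config, training_scope=scope)
    # Leakage guard: the model must never have seen test rows.
    overlap = set(train.index) & set(test.index)
    if overlap:
        raise EvaluationError(f"train/test row overlap: {sorted(overlap)[:5]}")
    return _models.predict(model, test)


def _collect(test: pd.DataFrame, pred: np.ndarray, model_type: str,
             placement_set: str) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": test["subject_id"].to_numpy(),
        "gmfcs_level": test["gmfcs_level"].to_numpy(),
        "model_type": model_type,
        "placement_set": placement_set,
        "truth": test["label"].to_numpy(),
        "pred": pred,
    }, index=test.index)


def run_cross_validation(table: pd.DataFrame, model_type: str,
                         config: ModelConfig,
                         placement_set: str | None = None,
                         kfold_k: int = 10) -> pd.DataFrame:
    """Pooled out-of-fold window predictions for one model type.

    G: LOSO over the whole cohort.  GP: LOSO within each GMFCS level.
    FP: k-fold within each subject.  Row identity (the table index) is
    preserved in the returned prediction frame.
    """
    if model_type not in _models.MODEL_TYPES:
        raise EvaluationError(f"unknown model type {model_type!r}")
    pset = placement_set or config.placement_set
    cfg = ModelConfig(**{**config.__dict__, "personalization": model_type,
                         "placement_set": pset})
    out: list[pd.DataFrame] = []
    if model_type == "G":
        for tr, te in loso_split(table):
            train, test = table.iloc[tr], table.iloc[te]
            pred = _fit_predict_fold(train, test, cfg, "cohort")
            out.append(_collect(test, pred, model_type, pset))
    elif model_type == "GP":
        for level, sub in table.groupby("gmfcs_level", sort=True):
            for tr, te in loso_split(sub):
                train, test = sub.iloc[tr], sub.iloc[te]
                pred = _fit_predict_fold(train, test, cfg, str(level))
                out.append(_collect(test, pred, model_type, pset))
    else:  # FP
        for sid, sub in table.groupby("subject_id", sort=True):
            if sub["label"].nunique() < 2:
                logger.warning("subject %s has < 2 classes; skipped in FP CV",
                               sid)
                continue
            stable = zlib.crc32(str(sid).encode()) % (2**31)
            subject_seed = int(np.random.SeedSequence(
                entropy=int(cfg.rng_seed),
                spawn_key=(stable,)).generate_state(1)[0] % (2**31))
            for tr, te in kfold_split(sub, k=min(kfold_k, len(sub)),
                                      seed=subject_seed):
                train, test = sub.iloc[tr], sub.iloc[te]
                pred = _fit_predict_fold(train, test, cfg, str(sid))
                out.append(_collect(test, pred, model_type, pset))
    preds = pd.concat(out)
    _assert_partition(table, preds, model_type)
    return preds.sort_index()


def _assert_partition(table: pd.DataFrame, preds: pd.DataFrame,
                      model_type: str) -> None:
    if model_type == "FP":
        # FP may legitimately skip single-class subjects.
        evaluated = preds.index
        if evaluated.has_duplicates:
            raise EvaluationError("a row was predicted in more than one fold")
        return
    if len(preds) != len(table) or preds.index.has_duplicates:
        raise EvaluationError("out-of-fold test sets do not partition the "
                              "table")


# ---------------------------------------------------------------------------
# Free-living evaluation
# ---------------------------------------------------------------------------

def train_scope_models(table: pd.DataFrame, model_type: str,
                       config: ModelConfig) -> dict[str, TrainedModel]:
    """Train deployment models on the full structured-trial table."""
    cfg = ModelConfig(**{**config.__dict__, "personalization": model_type})
    scopes = _models.build_training_scopes(table, model_type)
    return {scope: _models.train(sub, cfg, training_scope=scope)
            for scope, sub in scopes}


def resolve_model(scope_models: Mapping[str, TrainedModel], model_type: str,
                  subject_id: str, gmfcs_level: str) -> TrainedModel | None:
    if model_type == "G":
        return scope_models.get("cohort")
    if model_type == "GP":
        return scope_models.get(gmfcs_level)
    return scope_models.get(subject_id)


def evaluate_free_living(scope_models: Mapping[str, TrainedModel],
                         free_table: pd.DataFrame, model_type: str,
                         placement_set: str) -> pd.DataFrame:
    """Predict free-living windows with each subject's applicable model."""
    out = []
    skipped: list[str] = []
    for (sid, level), sub in free_table.groupby(
            ["subject_id", "gmfcs_level"], sort=True):
        model = resolve_model(scope_models, model_type, str(sid), str(level))
        if model is None:
            skipped.append(str(sid))
            continue
        pred = _models.predict(model, sub)
        out.append(_collect(sub, pred, model_type, placement_set))
    if skipped:
        logger.warning("no applicable %s model for subjects %s; excluded",
                       model_type, ", ".join(skipped))
    if not out:
        raise EvaluationError("no subject could be evaluated")
    return pd.concat(out).sort_index()


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Stratified accuracy report.

    ``overall``: window-pooled accuracy per (model_type, placement_set,
    gmfcs_level) plus pooled rows with gmfcs_level = "all".
    ``per_class``: per-class recall, across-subject mean (SD) and pooled.
    ``confusion``: stratum -> 3x3 count matrix (rows predicted, columns
    observed) and the column-normalized percentage matrix.
    """

    overall: pd.DataFrame
    per_class: pd.DataFrame
    confusion: dict[tuple[str, str, str], dict[str, pd.DataFrame]] = field(
        default_factory=dict)

    def to_dir(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.overall.to_csv(out_dir / "overall_accuracy.csv", index=False,
                            float_format="%.1f")
        self.per_class.to_csv(out_dir / "class_accuracy.csv", index=False,
                              float_format="%.1f")
        rows = []
        for (mt, ps, lvl), mats in sorted(self.confusion.items()):
            for kind in ("counts", "column_pct"):
                mat = mats[kind]
                for pred_cls in CLASSES:
                    row = {"model_type": mt, "placement_set": ps,
                           "gmfcs_level": lvl, "matrix": kind,
                           "predicted": pred_cls}
                    for obs_cls in CLASSES:
                        row[f"obs_{obs_cls}"] = mat.loc[pred_cls, obs_cls]
                    rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / "confusion_matrices.csv",
                                  index=False, float_format="%.1f")


def confusion_matrix(truth: np.ndarray, pred: np.ndarray) -> pd.DataFrame:
    """3x3 counts, rows = predicted class, columns = observed class."""
    mat = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES),
                       dtype=int)
    for t, p in zip(truth, pred):
        mat.loc[p, t] += 1
    return mat


def column_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    colsum = mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = mat / colsum * 100.0
    return pct.fillna(0.0)


def overall_accuracy(mat: pd.DataFrame) -> float:
    total = mat.to_numpy().sum()
    return float(np.trace(mat.to_numpy()) / total * 100.0) if total else 0.0


def summarize(predictions: pd.DataFrame) -> EvaluationReport:
    """Stratified report from pooled predictions.

    Requires the columns subject_id, gmfcs_level, model_type, placement_set,
    truth, pred.
    """
    missing = [c for c in PREDICTION_COLUMNS if c not in predictions.columns]
    if missing:
        raise EvaluationError(f"predictions lack stratum keys: {missing}")

    overall_rows, class_rows = [], []
    confusion: dict[tuple[str, str, str], dict[str, pd.DataFrame]] = {}
    for (mt, ps), group in predictions.groupby(
            ["model_type", "placement_set"], sort=True):
        strata = [(str(lvl), sub) for lvl, sub in
                  group.groupby("gmfcs_level", sort=True)]
        strata.append(("all", group))
        for lvl, sub in strata:
            truth = sub["truth"].to_numpy()
            pred = sub["pred"].to_numpy()
            mat = confusion_matrix(truth, pred)
            confusion[(str(mt), str(ps), lvl)] = {
                "counts": mat, "column_pct": column_normalize(mat)}
            overall_rows.append({
                "model_type": mt, "placement_set": ps, "gmfcs_level": lvl,
                "n_windows": len(sub),
                "accuracy_pct": round(overall_accuracy(mat), 1),
            })
            for cls in CLASSES:
                cls_mask = truth == cls
                pooled = (float((pred[cls_mask] == cls).mean() * 100.0)
                          if cls_mask.any() else np.nan)
                per_subject = [
                    float((s_pred == cls).mean() * 100.0)
                    for _, s in sub.groupby("subject_id")
                    if (s_mask := (s["truth"].to_numpy() == cls)).any()
                    for s_pred in [s["pred"].to_numpy()[s_mask]]
                ]
                mean = float(np.mean(per_subject)) if per_subject else np.nan
                sd = (float(np.std(per_subject, ddof=1))
                      if len(per_subject) > 1 else np.nan)
                class_rows.append({
                    "model_type": mt, "placement_set": ps,
                    "gmfcs_level": lvl, "class": cls,
                    "n_windows": int(cls_mask.sum()),
                    "recall_pooled_pct": (round(pooled, 1)
                                          if pooled == pooled else np.nan),
                    "recall_mean_pct": (round(mean, 1)
                                        if mean == mean else np.nan),
                    "recall_sd_pct": round(sd, 1) if sd == sd else np.nan,
                })
    return EvaluationReport(overall=pd.DataFrame(overall_rows),
                            per_class=pd.DataFrame(class_rows),
                            confusion=confusion)


def accuracy_by_model_and_level(report: EvaluationReport) -> pd.DataFrame:
    """Placement-averaged overall accuracy per model type x GMFCS level."""
    df = report.overall
    df = df[df["gmfcs_level"] != "all"]
    return (df.groupby(["model_type", "gmfcs_level"])["accuracy_pct"]
            .mean().round(1).reset_index())


def tidy_accuracy_table(report: EvaluationReport) -> pd.DataFrame:
    """Long-format accuracy table suitable for external statistical testing."""
    return report.overall.copy()
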