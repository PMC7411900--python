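"""Random-Forest activity classifiers at three personalization levels.

* G  (group): one model trained on the whole cohort;
* GP (group-personalized): one model per GMFCS level, trained only on data
  from subjects at that level;
* FP (fully-personalized): one model per subject, trained on that subject's
  own windows.

Forests are bagged decision-tree ensembles (bootstrap sample per tree,
``features_per_node`` random candidate features at each split) with a fixed
tree count, and predictions aggregate per-tree hard votes by majority; vote
ties break by the fixed class order SED < SUM < WALK.  mRMR feature selection
(and, when enabled, joint tuning of the selected-feature count and
features-per-node over a small grid) is refit on each training table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn import config_context
from sklearn.tree import DecisionTreeClassifier

from . import mrmr
from .cohort import CLASSES
from .features import feature_columns

logger = logging.getLogger(__name__)

MODEL_TYPES = ("G", "GP", "FP")
DEFAULT_MTRY_GRID = (3, 7, 11)


class ModelError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Training configuration.

    ``features_per_node=None`` tunes over ``mtry_grid`` (within the 3-11
    range) jointly with k by cross-validated accuracy; a single candidate_k
    with a fixed features_per_node skips tuning entirely.
    """

    n_trees: int = 500
    features_per_node: int | None = None
    mtry_grid: tuple[int, ...] = DEFAULT_MTRY_GRID
    candidate_k: tuple[int, ...] = mrmr.DEFAULT_CANDIDATE_K
    personalization: str = "G"
    placement_set: str = "A"
    rng_seed: int = 0
    n_bins: int = mrmr.DEFAULT_N_BINS

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ModelError("n_trees must be >= 1")
        if self.personalization not in MODEL_TYPES:
            raise ModelError(f"unknown personalization {self.personalization!r}")
        if self.features_per_node is not None and not (
                1 <= self.features_per_node):
            raise ModelError("features_per_node must be >= 1")


class BaggedForest:
    """Bootstrap-aggregated decision trees (the RF ensemble).

    Each tree is fit on a bootstrap sample of the training data — expressed,
    as in standard RF implementations, through per-row multiplicity sample
    weights, so every tree sees all classes — with ``max_features`` random
    candidate features at each split.  Prediction aggregates per-tree hard
    votes (see :func:`_forest_predict`).
    """

    def __init__(self, estimators: list[DecisionTreeClassifier],
                 classes: np.ndarray):
        self.estimators_ = estimators
        self.classes_ = classes

    @property
    def n_trees(self) -> int:
        return len(self.estimators_)


@dataclass
class TrainedModel:
    config: ModelConfig
    selected_features: list[str]
    forest: BaggedForest
    training_scope: str
    selection: mrmr.SelectionResult | None = None
    features_per_node: int | None = None


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int,
                seed: int) -> BaggedForest:
    if not np.all(np.isfinite(X)):
        raise ModelError("training features contain non-finite values")
    X = np.ascontiguousarray(X, dtype=np.float32)
    classes, y_enc = np.unique(y, return_inverse=True)
    y_enc = np.ascontiguousarray(y_enc)
    n = X.shape[0]
    ss = np.random.SeedSequence(int(seed) % (2**31))
    boot_rng = np.random.default_rng(ss)
    tree_seeds = ss.generate_state(int(n_trees)) % (2**31)
    trees: list[DecisionTreeClassifier] = []
    # Inputs are validated once above; per-tree re-validation is skipped.
    with config_context(skip_parameter_validation=True):
        for t in range(int(n_trees)):
            weights = np.bincount(boot_rng.integers(0, n, n),
                                  minlength=n).astype(np.float64)
            tree = DecisionTreeClassifier(
                max_features=min(int(mtry), X.shape[1]),
                random_state=int(tree_seeds[t]))
            tree.fit(X, y_enc, sample_weight=weights, check_input=False)
            trees.append(tree)
    return BaggedForest(trees, classes)


def _majority_vote(votes: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Aggregate per-tree hard votes (n_trees, n_rows) of class indices.

    Ties break toward the earlier class index (np.argmax returns the first
    maximum), i.e. SED < SUM < WALK under the fixed class order.
    """
    if n_classes is None:
        n_classes = len(CLASSES)
    counts = np.stack([(votes == c).sum(axis=0) for c in range(n_classes)])
    return counts.argmax(axis=0)


def _forest_predict(forest: BaggedForest, X: np.ndarray) -> np.ndarray:
    # Vote ties break toward the earliest label in sorted order, which for
    # the activity classes is the fixed SED < SUM < WALK convention.
    # Per-tree hard votes are read off the leaf class-count argmax, which is
    # exactly the tree's own prediction rule.
    X = np.ascontiguousarray(X, dtype=np.float32)
    ordered = sorted(forest.classes_)
    class_order = {c: i for i, c in enumerate(ordered)}
    lut = np.array([class_order[c] for c in forest.classes_])
    votes = np.empty((len(forest.estimators_), X.shape[0]), dtype=np.int64)
    for t, est in enumerate(forest.estimators_):
        leaves = est.tree_.apply(X)
        value = est.tree_.value[leaves, 0, :]         # (n_rows, n_classes)
        votes[t] = lut[value.argmax(axis=1)]
    idx = _majority_vote(votes, len(ordered))
    return np.asarray(ordered, dtype=object)[idx]


def _simple_trainer(n_trees: int, mtry: int | None, seed: int):
    """Trainer callable used during k/mtry tuning."""
    def trainer(train: pd.DataFrame, feats: list[str]):
        m = mtry if mtry is not None else max(3, int(np.sqrt(len(feats))))
        forest = _fit_forest(train[feats].to_numpy(),
                             train["label"].to_numpy(), n_trees, m, seed)

        def predict(test: pd.DataFrame) -> np.ndarray:
            return _forest_predict(forest, test[feats].to_numpy())
        return predict
    return trainer


def _tuning_folds(table: pd.DataFrame, seed: int,
                  n_folds: int = 3) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-grouped folds when >= n_folds subjects, else window folds."""
    rng = np.random.default_rng([int(seed), 777])
    subjects = pd.unique(table["subject_id"])
    idx = np.arange(len(table))
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if len(subjects) >= n_folds:
        perm = rng.permutation(len(subjects))
        groups = np.array_split(perm, n_folds)
        for g in groups:
            test_subj = set(subjects[g])
            mask = table["subject_id"].isin(test_subj).to_numpy()
            folds.append((idx[~mask], idx[mask]))
    else:
        perm = rng.permutation(idx)
        for part in np.array_split(perm, n_folds):
            mask = np.zeros(len(table), dtype=bool)
            mask[part] = True
            folds.append((idx[~mask], idx[mask]))
    # Keep only folds whose training split retains >= 2 classes.
    return [(tr, te) for tr, te in folds
            if table.iloc[tr]["label"].nunique() >= 2 and len(te) > 0]


def train(table: pd.DataFrame, config: ModelConfig,
          training_scope: str | None = None) -> TrainedModel:
    """Select features on ``table`` (mRMR) and fit the forest.

    Deterministic given ``config.rng_seed``.  With several candidate k or an
    unset features_per_node, both are tuned by cross-validated accuracy on
    the training table (ties toward the smaller value).
    """
    if len(table) == 0:
        raise ModelError("cannot train on an empty table")
    labels = pd.unique(table["label"])
    if len(labels) < 2:
        raise ModelError("cannot train on a single-class table")

    feats = feature_columns(table)
    cands = sorted({k for k in config.candidate_k if k <= len(feats)})
    if not cands:
        cands = [len(feats)]

    mtry_grid: Sequence[int]
    if config.features_per_node is not None:
        mtry_grid = [config.features_per_node]
    else:
        mtry_grid = sorted(config.mtry_grid)

    if len(cands) == 1 and len(mtry_grid) == 1:
        ranking = mrmr.mrmr_rank(table, cands[0], n_bins=config.n_bins)
        chosen_k, chosen_mtry = cands[0], mtry_grid[0]
        selection = ranking
    else:
        folds = _tuning_folds(table, config.rng_seed)
        best = None
        selection = None
        for m in mtry_grid:
            res = mrmr.tune_k(table, cands,
                              _simple_trainer(config.n_trees, m,
                                              config.rng_seed),
                              folds, n_bins=config.n_bins)
            acc = res.per_k_cv_accuracy[res.chosen_k]
            key = (-acc, res.chosen_k, m)     # ties -> smaller k, smaller mtry
            if best is None or key < best[0]:
                best = (key, res, m)
        assert best is not None
        _, selection, chosen_mtry = best
        chosen_k = selection.chosen_k

    selected = selection.ranked_features[:chosen_k]
    forest = _fit_forest(table[selected].to_numpy(),
                         table["label"].to_numpy(),
                         config.n_trees, chosen_mtry, config.rng_seed)
    return TrainedModel(
        config=config,
        selected_features=list(selected),
        forest=forest,
        training_scope=training_scope or config.personalization,
        selection=selection,
        features_per_node=chosen_mtry,
    )


def build_training_scopes(
    table: pd.DataFrame, personalization: str
) -> list[tuple[str, pd.DataFrame]]:
    """Split a cohort table into training scopes.

    G -> one scope with every row; GP -> one per GMFCS level present;
    FP -> one per subject.  FP subjects with < 2 classes are skipped with a
    warning (a personalized model cannot be trained for them).
    """
    if personalization not in MODEL_TYPES:
        raise ModelError(f"unknown personalization {personalization!r}")
    for col in ("subject_id", "gmfcs_level", "label"):
        if col not in table.columns:
            raise ModelError(f"table lacks metadata column {col!r}")
    if personalization == "G":
        return [("cohort", table)]
    if personalization == "GP":
        return [(level, sub) for level, sub in table.groupby("gmfcs_level",
                                                             sort=True)
                if len(sub) > 0]
    scopes = []
    for sid, sub in table.groupby("subject_id", sort=True):
        if sub["label"].nunique() < 2:
            logger.warning("subject %s has < 2 classes; FP scope skipped", sid)
            continue
        scopes.append((str(sid), sub))
    return scopes


def predict(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """Window-level class predictions using only the selected features."""
    for col in model.selected_features:
        if col not in table.columns:
            raise ModelError(f"table lacks required feature column {col!r}")
    X = table[model.selected_features].to_numpy()
    return _forest_predict(model.forest, X)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a versioned archive: JSON sidecar (config + selection) plus
    the fitted forest."""
    path = Path(path)
    meta = {
        "format_version": 1,
        "config": asdict(model.config),
        "selected_features": model.selected_features,
        "training_scope": model.training_scope,
        "features_per_node": model.features_per_node,
    }
    joblib.dump({"meta": meta, "forest": model.forest}, path)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, default=list))


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    meta = blob["meta"]
    cfg_kwargs = dict(meta["config"])
    for key in ("mtry_grid", "candidate_k"):
        cfg_kwargs[key] = tuple(cfg_kwargs[key])
    return TrainedModel(
        config=ModelConfig(**cfg_kwargs),
        selected_features=list(meta["selected_features"]),
        forest=blob["forest"],
        training_scope=meta["training_scope"],
        features_per_node=meta.get("features_per_node"),
    )
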