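"""Splitters, cross-validation integrity, free-living evaluation plumbing,
and report arithmetic."""

import numpy as np
import pandas as pd
import pytest

from cpactivity.cohort import CLASSES
from cpactivity.evaluation import (EvaluationError, accuracy_by_model_and_level,
                                   column_normalize, confusion_matrix,
                                   evaluate_free_living, kfold_split,
                                   loso_split, overall_accuracy,
                                   run_cross_validation, summarize,
                                   train_scope_models)
from cpactivity.models import ModelConfig


def _cohort_table(rng, n_per_level=(2, 2, 2), per_class=12, noise=0.3):
    rows = []
    centers = {"SED": 0.0, "SUM": 2.0, "WALK": 4.0}
    s = 0
    for lvl, n in zip(("I", "II", "III"), n_per_level):
        for _ in range(n):
            s += 1
            for cls, c in centers.items():
                for i in range(per_class):
                    rows.append({
                        "subject_id": f"S{s:02d}", "gmfcs_level": lvl,
                        "trial_id": "t", "window_index": i, "label": cls,
                        "ankle_y_var": c + rng.normal(0, noise),
                        "ankle_y_domfreq": rng.normal(2, 0.5),
                    })
    return pd.DataFrame(rows)


def _cfg(**kw):
    base = dict(n_trees=25, features_per_node=2, candidate_k=(2,), rng_seed=3)
    base.update(kw)
    return ModelConfig(**base)


class TestSplitters:
    def test_loso_one_fold_per_subject_no_leakage(self, rng):
        table = _cohort_table(rng)
        folds = loso_split(table)
        assert len(folds) == 6
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(len(table)))
        for tr, te in folds:
            train_subj = set(table.iloc[tr]["subject_id"])
            test_subj = set(table.iloc[te]["subject_id"])
            assert len(test_subj) == 1
            assert not train_subj & test_subj

    def test_loso_needs_two_subjects(self, rng):
        table = _cohort_table(rng, n_per_level=(1, 0, 0))
        table = table[table.subject_id == "S01"]
        with pytest.raises(EvaluationError, match="kfold"):
            loso_split(table)

    def test_kfold_partitions_windows_deterministically(self, rng):
        table = _cohort_table(rng, n_per_level=(1, 0, 0), per_class=60)
        sub = table[table.subject_id == "S01"]
        folds = kfold_split(sub, k=10, seed=4)
        assert len(folds) == 10
        sizes = sorted(len(te) for _, te in folds)
        assert sizes == [18] * 10
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(180))
        folds2 = kfold_split(sub, k=10, seed=4)
        for (_, a), (_, b) in zip(folds, folds2):
            np.testing.assert_array_equal(a, b)

    def test_kfold_rejects_too_few_rows(self, rng):
        table = _cohort_table(rng, n_per_level=(1, 0, 0), per_class=3)
        sub = table[table.subject_id == "S01"]
        with pytest.raises(EvaluationError):
            kfold_split(sub, k=10)


class TestCrossValidation:
    def test_g_and_gp_predictions_partition_table(self, rng):
        table = _cohort_table(rng)
        for mt in ("G", "GP"):
            preds = run_cross_validation(table, mt, _cfg(), placement_set="A")
            assert len(preds) == len(table)
            assert sorted(preds.index) == sorted(table.index)

    def test_fp_uses_within_subject_folds(self, rng):
        table = _cohort_table(rng, per_class=12)
        preds = run_cross_validation(table, "FP", _cfg(), placement_set="A",
                                     kfold_k=6)
        assert len(preds) == len(table)

    def test_separable_cohort_reaches_high_accuracy(self, rng):
        table = _cohort_table(rng, noise=0.2)
        preds = run_cross_validation(table, "FP", _cfg(), placement_set="A",
                                     kfold_k=6)
        acc = (preds.truth == preds.pred).mean()
        assert acc >= 0.99


class TestFreeLiving:
    def test_each_subject_resolved_to_its_model(self, rng):
        table = _cohort_table(rng)
        free = _cohort_table(rng)
        for mt in ("G", "GP", "FP"):
            models = train_scope_models(table, mt, _cfg())
            preds = evaluate_free_living(models, free, mt, "A")
            assert len(preds) == len(free)
            assert (preds.model_type == mt).all()

    def test_subject_without_model_is_excluded_with_warning(self, rng, caplog):
        table = _cohort_table(rng)
        free = _cohort_table(rng, n_per_level=(3, 2, 2))
        models = train_scope_models(table, "FP", _cfg())
        with caplog.at_level("WARNING"):
            preds = evaluate_free_living(models, free, "FP", "A")
        assert set(preds.subject_id) < set(free.subject_id)

    def test_perfect_predictions_give_100(self, rng):
        table = _cohort_table(rng, noise=0.1)
        models = train_scope_models(table, "G", _cfg())
        preds = evaluate_free_living(models, table, "G", "A")
        rep = summarize(preds)
        assert (rep.overall.accuracy_pct == 100.0).all()


def test_personalization_recovery_under_high_heterogeneity():
    """With strongly dispersed subject parameters, fully-personalized models
    beat group and group-personalized models, and the FP-G differential is
    at least 5 points in the most heterogeneous (GMFCS III) stratum."""
    from cpactivity.config import config_from_dict
    from cpactivity.pipeline import (build_tables, model_config_from,
                                     simulate_cohort_windows)
    cfg = config_from_dict({
        "master_seed": 5,
        "cohort": {"n_per_level": {"I": 4, "II": 4, "III": 4},
                   "heterogeneity": 2.0},
        "protocol": {"trial_duration_s": 120, "free_living_duration_s": 60},
        "model": {"n_trees": 50, "features_per_node": 5},
        "selection": {"candidate_k": [10]},
        "evaluation": {"placement_sets": ["W"],
                       "model_types": ["G", "GP", "FP"], "kfold_k": 5},
    })
    _, structured, _ = simulate_cohort_windows(cfg)
    table = build_tables(structured, ["W"])["W"]
    acc = {}
    acc3 = {}
    for mt in ("G", "GP", "FP"):
        mc = model_config_from(cfg, mt, "W")
        preds = run_cross_validation(table, mt, mc, placement_set="W",
                                     kfold_k=5)
        acc[mt] = (preds.truth == preds.pred).mean() * 100
        sub = preds[preds.gmfcs_level == "III"]
        acc3[mt] = (sub.truth == sub.pred).mean() * 100
    assert acc["FP"] >= acc["GP"]
    assert acc["FP"] >= acc["G"]
    assert acc3["FP"] - acc3["G"] >= 5.0, acc3


def _toy_predictions():
    """The printed toy contingency: counts [[30,5,0],[5,25,0],[0,0,35]]
    with rows = predicted, columns = observed."""
    rows = []
    counts = {("SED", "SED"): 30, ("SED", "SUM"): 5,
              ("SUM", "SED"): 5, ("SUM", "SUM"): 25,
              ("WALK", "WALK"): 35}
    for (pred, obs), c in counts.items():
        for _ in range(c):
            rows.append({"subject_id": "S01", "gmfcs_level": "I",
                         "model_type": "G", "placement_set": "A",
                         "truth": obs, "pred": pred})
    return pd.DataFrame(rows)


class TestSummarize:
    def test_toy_contingency_arithmetic(self):
        rep = summarize(_toy_predictions())
        row = rep.overall[rep.overall.gmfcs_level == "I"].iloc[0]
        assert row.accuracy_pct == pytest.approx(90.0)
        assert row.n_windows == 100
        sed = rep.per_class[(rep.per_class.gmfcs_level == "I")
                            & (rep.per_class["class"] == "SED")].iloc[0]
        assert sed.recall_pooled_pct == pytest.approx(
            round(30 / 35 * 100, 1))
        mat = rep.confusion[("G", "A", "I")]["counts"]
        assert mat.loc["SED", "SUM"] == 5
        assert np.trace(mat.to_numpy()) == 90
        assert mat.to_numpy().sum() == 100

    def test_column_normalized_columns_sum_to_100(self):
        rep = summarize(_toy_predictions())
        pct = rep.confusion[("G", "A", "I")]["column_pct"]
        np.testing.assert_allclose(pct.sum(axis=0), 100.0, atol=0.1)

    def test_identity_predictions_are_diagonal(self):
        df = _toy_predictions()
        df["pred"] = df["truth"]
        rep = summarize(df)
        mat = rep.confusion[("G", "A", "I")]["column_pct"]
        assert np.allclose(np.diag(mat.to_numpy()), 100.0)
        assert rep.overall.accuracy_pct.iloc[0] == 100.0

    def test_across_subject_recall_mean_and_sd(self):
        """Two subjects with WALK recall 80% and 100%: mean 90.0, sample SD
        (n-1) = 14.1."""
        rows = []
        for sid, correct in (("S01", 8), ("S02", 10)):
            for i in range(10):
                rows.append({"subject_id": sid, "gmfcs_level": "I",
                             "model_type": "G", "placement_set": "A",
                             "truth": "WALK",
                             "pred": "WALK" if i < correct else "SED"})
        rep = summarize(pd.DataFrame(rows))
        walk = rep.per_class[rep.per_class["class"] == "WALK"].iloc[0]
        assert walk.recall_mean_pct == pytest.approx(90.0)
        assert walk.recall_sd_pct == pytest.approx(
            round(np.std([80.0, 100.0], ddof=1), 1))

    def test_missing_stratum_key_rejected(self):
        with pytest.raises(EvaluationError):
            summarize(_toy_predictions().drop(columns=["gmfcs_level"]))

    def test_placement_averaged_accuracy(self):
        df = pd.concat([_toy_predictions(),
                        _toy_predictions().assign(placement_set="W")])
        rep = summarize(df)
        avg = accuracy_by_model_and_level(rep)
        assert avg.accuracy_pct.iloc[0] == pytest.approx(90.0)

    def test_confusion_helpers(self):
        truth = np.array(["SED"] * 3 + ["WALK"] * 2)
        pred = np.array(["SED", "SED", "SUM", "WALK", "WALK"])
        mat = confusion_matrix(truth, pred)
        assert overall_accuracy(mat) == pytest.approx(80.0)
        assert column_normalize(mat)["SED"].tolist() == pytest.approx(
            [200 / 3, 100 / 3, 0.0])
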