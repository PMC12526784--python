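"""Classification metrics, SVM CV protocol and logistic regression."""

import numpy as np
import pandas as pd
import pytest

from gaitsev.models import (
    CLASS_ORDER,
    _irls_logit,
    cv_logistic_accuracy,
    dementia_outcome,
    fit_logistic,
    multiclass_metrics,
    train_eval_svm,
)

FIXED_CONFUSION = np.array(
    [[50, 4, 0, 0], [5, 27, 2, 0], [0, 3, 20, 2], [0, 0, 4, 22]]
)


def test_diagonal_confusion_gives_perfect_panel():
    panel = multiclass_metrics(np.diag([10, 20, 5, 7]))
    for key in ("accuracy", "precision_ppv", "recall_sensitivity", "specificity", "f1", "npv"):
        assert panel[key] == pytest.approx(100.0)


def test_two_class_symmetric_confusion():
    panel = multiclass_metrics(np.array([[1, 1], [1, 1]]))
    assert panel["accuracy"] == pytest.approx(50.0)
    assert panel["precision_ppv"] == pytest.approx(50.0)
    assert panel["recall_sensitivity"] == pytest.approx(50.0)


def test_fixed_confusion_hand_arithmetic():
    """trace 119 of 139 -> 85.61%; macro sensitivity mean(50/54, 27/34,
    20/25, 22/26) = 84.16%."""
    panel = multiclass_metrics(FIXED_CONFUSION)
    assert panel["accuracy"] == pytest.approx(100 * 119 / 139, abs=1e-9)
    assert panel["accuracy"] == pytest.approx(85.61, abs=0.005)
    expected_sens = 100 * np.mean([50 / 54, 27 / 34, 20 / 25, 22 / 26])
    assert panel["recall_sensitivity"] == pytest.approx(expected_sens, abs=1e-9)
    assert panel["recall_sensitivity"] == pytest.approx(84.155, abs=0.005)
    # F1 is the harmonic mean of macro PPV and macro sensitivity
    hm = 2 * panel["precision_ppv"] * panel["recall_sensitivity"] / (
        panel["precision_ppv"] + panel["recall_sensitivity"]
    )
    assert panel["f1"] == pytest.approx(hm)


def test_confusion_validation_and_zero_denominator():
    with pytest.raises(ValueError):
        multiclass_metrics(np.array([[1, 2, 3]]))
    with pytest.raises(ValueError):
        multiclass_metrics(np.array([[-1, 0], [0, 1]]))
    with pytest.warns(UserWarning, match="zero denominator"):
        panel = multiclass_metrics(np.array([[2, 0], [2, 0]]))  # no predicted class 1
    assert panel["accuracy"] == pytest.approx(50.0)


def _cluster_table(scale=0.0, n_per=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    centers = {g: (i * 10.0, -i * 5.0) for i, g in enumerate(CLASS_ORDER)}
    for g, (cx, cy) in centers.items():
        for j in range(n_per):
            rows.append(
                {
                    "subject_id": f"{g}{j}",
                    "group": g,
                    "a": cx + rng.normal(0, scale),
                    "b": cy + rng.normal(0, scale),
                }
            )
    return pd.DataFrame(rows)


def test_separable_clusters_classified_perfectly():
    table = _cluster_table(scale=0.0)
    rep = train_eval_svm(table, ["a", "b"], folds=4, seed=0)
    assert rep.accuracy == pytest.approx(100.0)
    assert rep.auc == pytest.approx(1.0)
    assert np.trace(rep.confusion) == len(table)


def test_confusion_conservation_across_kernels():
    table = _cluster_table(scale=6.0, seed=3)
    for kernel in ("rbf", "linear"):
        rep = train_eval_svm(table, ["a", "b"], folds=4, seed=1, kernel=kernel)
        assert rep.confusion.sum() == len(table)
        assert rep.confusion.sum(axis=1).tolist() == [12, 12, 12, 12]


def test_permuted_labels_fall_to_chance(small_table):
    """Random labels destroy the real-label accuracy, down to chance level."""
    real = train_eval_svm(small_table, folds=4, seed=0).accuracy
    rng = np.random.default_rng(0)
    null_accs = []
    for s in range(5):
        shuffled = small_table.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        null_accs.append(train_eval_svm(shuffled, folds=4, seed=s).accuracy)
    assert real > 50.0
    assert np.mean(null_accs) < 50.0
    assert real > np.mean(null_accs) + 20.0


def test_stratification_and_input_errors(small_table):
    with pytest.raises(ValueError, match="folds"):
        train_eval_svm(small_table, folds=1)
    with pytest.raises(ValueError, match="stratification"):
        train_eval_svm(small_table, folds=10)
    bad = small_table.copy()
    bad.loc[bad.index[0], "velocity"] = np.nan
    with pytest.raises(ValueError, match=str(bad.loc[bad.index[0], "subject_id"])):
        train_eval_svm(bad, folds=3)


def _binary_table(counts):
    """2x2 design: outcome x binary predictor with the given cell counts."""
    (a, b), (c, d) = counts  # rows: outcome 0/1; cols: predictor 0/1
    rows = []
    for y, x, m in ((0, 0, a), (0, 1, b), (1, 0, c), (1, 1, d)):
        rows += [{"outcome": y, "x": float(x)}] * m
    return pd.DataFrame(rows)


def test_contingency_odds_ratio_reproduced_exactly():
    """Logistic on a 2x2 reproduces the cross-product OR (30*30)/(10*10) = 9."""
    fit = fit_logistic(_binary_table([[30, 10], [10, 30]]), ["x"])
    assert fit.odds_ratios["x"][0] == pytest.approx(9.0, rel=1e-6)
    assert not fit.separation_flag


def test_null_model_has_zero_max_rescaled_r_square():
    table = _binary_table([[20, 20], [20, 20]])
    fit = fit_logistic(table, [])
    assert fit.max_rescaled_r_square == pytest.approx(0.0, abs=1e-9)
    assert fit.r_square == pytest.approx(0.0, abs=1e-9)


def test_irls_matches_statsmodels_oracle():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(4)
    n = 200
    X = rng.normal(size=(n, 2))
    eta = 0.5 + 1.2 * X[:, 0] - 0.7 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    beta, cov, ll, conv = _irls_logit(np.column_stack([np.ones(n), X]), y)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert conv
    assert np.allclose(beta, ref.params, atol=1e-6)
    assert np.allclose(np.sqrt(np.diag(cov)), ref.bse, atol=1e-5)
    assert ll == pytest.approx(ref.llf, abs=1e-6)
    # Nagelkerke via the closed formulas against statsmodels' likelihoods
    table = pd.DataFrame({"outcome": y, "x0": X[:, 0], "x1": X[:, 1]})
    fit = fit_logistic(table, ["x0", "x1"])
    cs = 1 - np.exp(2 * (ref.llnull - ref.llf) / n)
    assert fit.r_square == pytest.approx(cs, abs=1e-8)
    assert fit.max_rescaled_r_square == pytest.approx(
        cs / (1 - np.exp(2 * ref.llnull / n)), abs=1e-8
    )


def test_perfect_separation_is_flagged_not_silent():
    table = pd.DataFrame(
        {"outcome": [0] * 10 + [1] * 10, "x": list(range(10)) + list(range(20, 30))}
    )
    with pytest.warns(UserWarning, match="separation"):
        fit = fit_logistic(table, ["x"])
    assert fit.separation_flag
    assert fit.classification_accuracy == pytest.approx(100.0)


def test_singular_design_names_predictors():
    table = _binary_table([[15, 5], [5, 15]])
    table["x2"] = 2 * table["x"]
    with pytest.raises(ValueError, match="singular"):
        fit_logistic(table, ["x", "x2"])


def test_dementia_outcome_grouping(small_table):
    sub = dementia_outcome(small_table)
    assert set(sub["group"]) == {"healthy_control", "mild_dementia", "moderate_dementia"}
    assert sub["outcome"].sum() == (sub["group"] != "healthy_control").sum()
    with_mci = dementia_outcome(small_table, include_mci=True)
    assert "mci" in set(with_mci["group"])
    assert with_mci["outcome"].sum() > sub["outcome"].sum()


def test_cv_logistic_accuracy_on_separable_groups(small_table):
    sub = dementia_outcome(small_table)
    acc = cv_logistic_accuracy(sub, ["knee_rom", "hip_rom"], folds=3, seed=0)
    assert 50.0 <= acc <= 100.0
    assert acc > 80.0  # knee/hip ROM separate healthy from dementia strongly
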