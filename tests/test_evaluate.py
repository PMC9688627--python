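import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegdep.evaluate import (
    ConfusionCounts,
    SummaryStats,
    confusion_from_predictions,
    evaluate_predictions,
    external_validate,
    f1_from_precision_recall,
    metrics_from_counts,
    roc_auc,
    two_sample_t,
)
from oracles import auc_pairs_naive


def test_perfect_classifier_all_metrics_one():
    m = metrics_from_counts(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
    assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)
    assert m.undefined == ()


def test_metrics_direct_arithmetic():
    m = metrics_from_counts(ConfusionCounts(tp=30, fn=10, fp=5, tn=55))
    assert m.accuracy == pytest.approx(0.85)
    assert m.precision == pytest.approx(30 / 35)
    assert m.recall == pytest.approx(0.75)
    assert m.f1 == pytest.approx(0.8)


def test_undefined_metrics_flagged_not_zero():
    m = metrics_from_counts(ConfusionCounts(tp=0, tn=10, fp=0, fn=5))
    assert math.isnan(m.precision) and "precision" in m.undefined
    m2 = metrics_from_counts(ConfusionCounts(tp=0, tn=10, fp=5, fn=0))
    assert math.isnan(m2.recall) and "recall" in m2.undefined
    with pytest.raises(ValueError):
        metrics_from_counts(ConfusionCounts(0, 0, 0, 0))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    tp=st.integers(0, 40),
    tn=st.integers(0, 40),
    fp=st.integers(0, 40),
    fn=st.integers(0, 40),
)
def test_metric_class_swap_consistency(tp, tn, fp, fn):
    """Relabeling positives maps precision to TN/(TN+FN) as algebra dictates."""
    if tp + tn + fp + fn == 0:
        return
    orig = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
    swapped = metrics_from_counts(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
    assert swapped.accuracy == pytest.approx(orig.accuracy)
    if tn + fn > 0:
        assert swapped.precision == pytest.approx(tn / (tn + fn))


def test_f1_from_precision_recall_formula():
    assert f1_from_precision_recall(1.0, 1.0) == 1.0
    assert f1_from_precision_recall(0.5, 1.0) == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        f1_from_precision_recall(0.0, 0.0)


def test_confusion_from_predictions_convention():
    y = np.array([1, 1, 0, 0, 1])
    p = np.array([1, 0, 0, 1, 1])
    c = confusion_from_predictions(y, p, positive=1)
    assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def test_roc_endpoints_and_perfect_auc():
    roc, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)
    assert auc == 1.0


def test_auc_chance_level(rng):
    scores = rng.uniform(size=10_000)
    labels = rng.integers(0, 2, size=10_000)
    _, auc = roc_auc(scores, labels)
    assert auc == pytest.approx(0.5, abs=0.02)


@pytest.mark.parametrize("seed", range(5))
def test_auc_equals_concordant_pair_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 200))
    labels = rng.integers(0, 2, n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    scores = np.round(rng.uniform(size=n), 2)  # coarse grid -> ties occur
    _, auc = roc_auc(scores, labels)
    assert auc == pytest.approx(auc_pairs_naive(scores, labels), abs=1e-12)


def test_roc_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([0.1, 0.9], [1, 1])


# ---------------------------------------------------------------------------
# summary-statistic t-test
# ---------------------------------------------------------------------------

def test_two_sample_t_depression_inventory_contrast():
    t, df = two_sample_t(SummaryStats(24, 3.87, 2.32), SummaryStats(26, 32.92, 5.96))
    assert df == 48
    assert t == pytest.approx(-22.35, abs=0.01)


def test_two_sample_t_matches_scipy_from_raw_data(rng):
    a = rng.normal(0, 1, 40)
    b = rng.normal(0.7, 1.3, 55)
    t, df = two_sample_t(
        SummaryStats(40, a.mean(), a.std(ddof=1)),
        SummaryStats(55, b.mean(), b.std(ddof=1)),
    )
    from scipy import stats

    ref = stats.ttest_ind(a, b, equal_var=True)
    assert t == pytest.approx(ref.statistic, abs=1e-10)
    assert df == 93


def test_two_sample_t_identical_groups_zero():
    t, _ = two_sample_t(SummaryStats(10, 5.0, 1.0), SummaryStats(10, 5.0, 1.0))
    assert t == 0.0


def test_two_sample_t_degenerate_variance():
    with pytest.raises(ValueError, match="pooled variance"):
        two_sample_t(SummaryStats(10, 1.0, 0.0), SummaryStats(10, 2.0, 0.0))


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def trained_setup(separated_cohort):
    from eegdep.pipeline import _selected_matrix
    from eegdep.select import SelectionConfig, run_selection
    from eegdep.classify import ModelSpec, build_model

    config = SelectionConfig(seed=0, k_folds=5, spans=(1, 3, 5))
    selection = run_selection(separated_cohort, config)
    X, y = _selected_matrix(separated_cohort, selection, selection.combination_features)
    model = build_model(ModelSpec("LR")).fit(X, y)
    return model, selection


def test_external_validate_self_consistency(trained_setup, separated_cohort):
    model, selection = trained_setup
    report = external_validate(model, separated_cohort, selection)
    assert report.accuracy >= 0.9
    assert report.n_windows == len(separated_cohort) * selection.span


def test_external_validate_fresh_cohort_generalizes(trained_setup):
    from conftest import SMALL_MONTAGE

    from eegdep.synth import CohortSpec, generate_cohort

    model, selection = trained_setup

    fresh = generate_cohort(
        CohortSpec(
            n_ctl=4, n_dep=4, channels=SMALL_MONTAGE, duration=20.0,
            beta_ctl=1.0, beta_dep=1.5, seed=99,
        )
    )
    report = external_validate(model, fresh, selection)
    assert report.accuracy >= 0.9
    assert report.auc >= 0.9


def test_external_validate_missing_electrode_named(trained_setup, separated_cohort):
    model, selection = trained_setup
    stripped = [r.pick(["Cz", "Pz"]) for r in separated_cohort[:2]]
    with pytest.raises(ValueError, match="FC2|AFz|F2"):
        external_validate(model, stripped, selection)


def test_eval_report_json(tmp_path):
    report = evaluate_predictions([1, 0, 1, 0], [0.9, 0.1, 0.8, 0.3])
    path = report.to_json(tmp_path / "eval.json")
    import json

    data = json.loads(path.read_text())
    assert data["accuracy"] == 1.0
    assert data["counts"]["tp"] == 2
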