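"""Correlation scoring, ROC evaluation, and the stratified drug screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from iraps import (
    DrugResponseTable,
    ExpressionMatrix,
    Signature,
    call_single,
    evaluate,
    score,
    stratified_drug_screen,
)
from iraps.errors import EvaluationError, ScoringError


def _calls_from_labels(labels):
    # responder iff z < -1, non-responder iff z > 0
    z = pd.Series(
        [-2.0 if lab == "R" else 1.0 for lab in labels.values()],
        index=list(labels.keys()),
    )
    return call_single(z)


# ---------------------------------------------------------------- score

def test_score_perfect_correlation_is_plus_minus_one():
    w = pd.Series({"g0": 1.0, "g1": -1.0, "g2": 2.0, "g3": 0.5, "g4": -0.3})
    base = pd.Series(5.0, index=w.index)
    cohort = pd.DataFrame(
        {"up": base + w, "mid": base, "down": base - w}
    )
    m = ExpressionMatrix(cohort, scale="log2")
    sv = score(Signature(weights=w), m)
    assert sv.scores["up"] == pytest.approx(1.0)
    assert sv.scores["down"] == pytest.approx(-1.0)
    assert sv.n_genes_used == 5


def test_score_direct_pearson_arithmetic():
    # centered=False exposes the raw correlation for a hand-checked fixture
    w = np.array([1.0, -1.0, 2.0])
    x = np.array([0.5, -0.2, 1.0])
    m = ExpressionMatrix(
        pd.DataFrame({"s": x}, index=["g0", "g1", "g2"]), scale="log2"
    )
    sv = score(Signature(weights=pd.Series(w, index=["g0", "g1", "g2"])), m,
               center=False)
    wc, xc = w - w.mean(), x - x.mean()
    expected = (wc @ xc) / np.sqrt((wc @ wc) * (xc @ xc))
    assert sv.scores["s"] == pytest.approx(expected)


def test_score_requires_min_overlap():
    w = pd.Series({"absent1": 1.0, "absent2": -1.0, "g0": 0.5})
    m = ExpressionMatrix(
        pd.DataFrame({"s": [1.0], "t": [2.0]}, index=["g0"]), scale="log2"
    )
    with pytest.raises(ScoringError, match="absent"):
        score(Signature(weights=w), m)


def test_score_affine_invariance_positive_slope(rng):
    w = pd.Series(rng.normal(size=8), index=[f"g{i}" for i in range(8)])
    x = rng.normal(size=8)
    m1 = ExpressionMatrix(pd.DataFrame({"s": x}, index=w.index), scale="log2")
    m2 = ExpressionMatrix(
        pd.DataFrame({"s": 3.7 * x + 11.0}, index=w.index), scale="log2"
    )
    s1 = score(Signature(weights=w), m1, center=False).scores["s"]
    s2 = score(Signature(weights=w), m2, center=False).scores["s"]
    assert s1 == pytest.approx(s2)


def test_score_drops_missing_genes_symmetrically(rng):
    w = pd.Series(rng.normal(size=6), index=[f"g{i}" for i in range(6)])
    full = pd.DataFrame(
        rng.normal(size=(6, 4)), index=w.index,
        columns=[f"s{i}" for i in range(4)],
    )
    m_full = ExpressionMatrix(full, scale="log2")
    m_missing = ExpressionMatrix(full.drop(index=["g5"]), scale="log2")
    sv = score(Signature(weights=w), m_missing)
    assert sv.missing_genes == ("g5",)
    assert sv.n_genes_used == 5
    ref = score(Signature(weights=w.drop("g5")), m_full.subset_samples(full.columns))
    # scoring with the truncated signature on the truncated matrix agrees
    sv_ref = score(Signature(weights=w.drop("g5")), m_missing)
    pd.testing.assert_series_equal(sv.scores, sv_ref.scores)


# ---------------------------------------------------------------- evaluate

def test_evaluate_concordant_pair_auc():
    # scores (.9,.8,.3,.2) with labels (R,N,R,N): 3 of 4 R/N pairs concordant
    scores = pd.Series({"a": 0.9, "b": 0.8, "c": 0.3, "d": 0.2})
    calls = _calls_from_labels({"a": "R", "b": "N", "c": "R", "d": "N"})
    rep = evaluate(scores, calls)
    assert rep.auc == pytest.approx(0.75)


def test_evaluate_perfect_separation():
    scores = pd.Series({"a": 0.9, "b": 0.8, "c": 0.3, "d": 0.2})
    calls = _calls_from_labels({"a": "R", "b": "R", "c": "N", "d": "N"})
    rep = evaluate(scores, calls)
    assert rep.auc == 1.0
    assert rep.accuracy == 1.0
    assert rep.confusion == {"tp": 2, "fp": 0, "tn": 2, "fn": 0}


def test_evaluate_all_tied_scores_is_chance():
    scores = pd.Series({"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.5})
    calls = _calls_from_labels({"a": "R", "b": "N", "c": "R", "d": "N"})
    assert evaluate(scores, calls).auc == pytest.approx(0.5)


def test_evaluate_roc_curve_is_monotone(rng):
    scores = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
    labels = {f"s{i}": ("R" if rng.random() < 0.4 else "N") for i in range(40)}
    rep = evaluate(scores, _calls_from_labels(labels))
    assert (np.diff(rep.roc_points["fpr"]) >= 0).all()
    assert (np.diff(rep.roc_points["tpr"]) >= 0).all()
    assert rep.roc_points[["fpr", "tpr"]].iloc[0].tolist() == [0.0, 0.0]
    assert rep.roc_points[["fpr", "tpr"]].iloc[-1].tolist() == [1.0, 1.0]


def test_evaluate_one_class_input_is_error():
    scores = pd.Series({"a": 0.9, "b": 0.8})
    calls = _calls_from_labels({"a": "R", "b": "R"})
    with pytest.raises(EvaluationError):
        evaluate(scores, calls)


def test_evaluate_neither_samples_are_excluded():
    scores = pd.Series({"a": 0.9, "b": 0.8, "c": 0.3, "d": 0.2, "e": 0.6})
    z = pd.Series({"a": -2.0, "b": 1.0, "c": -2.0, "d": 1.0, "e": -0.5})
    rep = evaluate(scores, call_single(z))
    assert sum(rep.confusion.values()) == 4  # "e" is neither and dropped


@given(st.integers(0, 10_000))
def test_auc_complement_under_score_negation(seed):
    rng = np.random.default_rng(seed)
    scores = pd.Series(
        np.round(rng.normal(size=30), 1), index=[f"s{i}" for i in range(30)]
    )
    labels = {f"s{i}": ("R" if rng.random() < 0.5 else "N") for i in range(30)}
    calls = _calls_from_labels(labels)
    if len(set(labels.values())) < 2:
        return
    a1 = evaluate(scores, calls).auc
    a2 = evaluate(-scores, calls).auc
    assert a1 + a2 == pytest.approx(1.0)


def test_frozen_threshold_policy():
    scores = pd.Series({"a": 0.9, "b": 0.8, "c": 0.3, "d": 0.2})
    calls = _calls_from_labels({"a": "R", "b": "R", "c": "N", "d": "N"})
    rep = evaluate(scores, calls, threshold_policy=0.85)
    assert rep.threshold_used == 0.85
    assert rep.confusion["tp"] == 1 and rep.confusion["fn"] == 1


# ---------------------------------------------------------------- screen

def _screen_fixture(rng):
    n = 60
    samples = [f"c{i}" for i in range(n)]
    scores = pd.Series(rng.standard_normal(n), index=samples)
    rows = []
    for s in samples:
        # monotone drug: sensitivity value falls as score rises
        rows.append((s, "hit", 6.0 - 2.0 * scores[s] + 0.1 * rng.standard_normal(), "auc"))
        rows.append((s, "null", 6.0 + rng.standard_normal(), "auc"))
        rows.append((s, "toxic_free", 12.0 + rng.standard_normal(), "auc"))
    d = DrugResponseTable(
        pd.DataFrame(rows, columns=["sample_id", "drug_id", "value", "metric"])
    )
    return scores, d


def test_stratified_screen_ranks_monotone_drug_first(rng):
    scores, d = _screen_fixture(rng)
    table = stratified_drug_screen(scores, d)
    assert table.index[0] == "hit"
    assert table.loc["hit", "effect"] < 0  # high stratum is more sensitive
    assert table.loc["hit", "p_value"] < 1e-4


def test_stratified_screen_null_drug_shows_no_effect(rng):
    scores, d = _screen_fixture(rng)
    table = stratified_drug_screen(scores, d)
    assert abs(table.loc["null", "effect"]) < 1.0
    assert table.loc["null", "p_value"] > 0.001


def test_stratified_screen_toxicity_filter(rng):
    scores, d = _screen_fixture(rng)
    table = stratified_drug_screen(scores, d, exclude_auc_above=10.0)
    assert bool(table.loc["toxic_free", "excluded"])
    assert table.loc["toxic_free", "reason"] == "not_cytotoxic"
    # the filter threshold is configurable (the response-AUC scale is
    # dataset specific)
    table2 = stratified_drug_screen(scores, d, exclude_auc_above=20.0)
    assert not bool(table2.loc["toxic_free", "excluded"])


def test_stratified_screen_small_strata_are_flagged(rng):
    scores = pd.Series(rng.standard_normal(8), index=[f"c{i}" for i in range(8)])
    rows = [(f"c{i}", "d", float(i), "auc") for i in range(8)]
    d = DrugResponseTable(
        pd.DataFrame(rows, columns=["sample_id", "drug_id", "value", "metric"])
    )
    with pytest.warns(UserWarning, match="no drug survived"):
        table = stratified_drug_screen(scores, d)
    assert bool(table.loc["d", "excluded"])
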