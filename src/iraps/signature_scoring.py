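"""Correlation-based signature scoring, ROC evaluation, stratified drug screen.

A sample's signature score is the Pearson correlation between the
signature's gene weights and the sample's expression over the signature
genes, after centering each gene at its cohort median.  Centering is the
single largest interpretive choice here: without it, absolute expression
scale dominates the correlation.  Scores therefore live in [-1, 1], with
high scores indicating expression patterns resembling a responder profile.

``evaluate`` turns scores plus responder labels into a ROC curve (tie
groups collapsed), trapezoid AUC, and an accuracy at a threshold chosen by
policy (Youden point by default).  ``stratified_drug_screen`` implements
score-stratified differential drug sensitivity: samples more than one
standard deviation above the mean score form the high stratum, samples
below the mean the low stratum, and each drug surviving a toxicity filter
is tested high vs low with a Welch t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .core_io import (
    NON_RESPONDER,
    RESPONDER,
    DrugResponseTable,
    ExpressionMatrix,
    Signature,
)
from .errors import EvaluationError, ScoringError
from .response_classification import SensitivityCalls

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    """Per-sample signature scores in [-1, 1]."""

    scores: pd.Series
    n_genes_used: int
    missing_genes: tuple[str, ...] = ()
    low_overlap: bool = False


@dataclass
class EvalReport:
    """ROC evaluation of signature scores against responder labels."""

    auc: float
    roc_points: pd.DataFrame  # columns fpr, tpr, threshold
    accuracy: float
    threshold_used: float
    confusion: dict  # keys tp, fp, tn, fn


def score(
    sig: Signature,
    m: ExpressionMatrix,
    min_overlap: int = 3,
    center: bool = True,
    method: str = "pearson",
) -> ScoreVector:
    """Correlate signature weights with each sample's (centered) expression.

    Genes are centered across the cohort by their median; signature genes
    absent from the matrix are dropped symmetrically and reported.  With
    fewer than ``min_overlap`` genes in common a :class:`ScoringError` is
    raised.  ``method`` may be ``"pearson"`` (default) or ``"spearman"``
    (rank-transform both vectors first).
    """
    common = sig.weights.index.intersection(m.gene_ids)
    missing = tuple(sig.weights.index.difference(m.gene_ids))
    if len(common) < min_overlap:
        raise ScoringError(
            f"only {len(common)} signature genes present in matrix "
            f"(need {min_overlap}); missing: {list(missing)[:10]}"
        )
    X = m.values.loc[common].to_numpy(dtype=float)
    if center:
        X = X - np.median(X, axis=1, keepdims=True)
    w = sig.weights.loc[common].to_numpy(dtype=float)
    if method == "spearman":
        w = stats.rankdata(w)
        X = np.apply_along_axis(stats.rankdata, 0, X)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    wc = w - w.mean()
    Xc = X - X.mean(axis=0, keepdims=True)
    wn = np.linalg.norm(wc)
    Xn = np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (wc @ Xc) / (wn * Xn)
    n_flat = int(np.sum(~np.isfinite(r)))
    if n_flat:
        logger.warning("score: %d samples with zero-variance expression set to 0", n_flat)
        r = np.where(np.isfinite(r), r, 0.0)
    return ScoreVector(
        scores=pd.Series(np.clip(r, -1.0, 1.0), index=m.sample_ids),
        n_genes_used=len(common),
        missing_genes=missing,
        low_overlap=len(common) < len(sig.weights),
    )


def _binary_labels(scores: pd.Series, calls: SensitivityCalls) -> tuple[np.ndarray, np.ndarray]:
    labeled = calls.labels[calls.labels.isin((RESPONDER, NON_RESPONDER))]
    common = scores.index.intersection(labeled.index)
    if len(common) == 0:
        raise EvaluationError("no scored samples carry responder labels")
    y = (labeled.loc[common] == RESPONDER).to_numpy()
    s = scores.loc[common].to_numpy(dtype=float)
    if y.all() or not y.any():
        raise EvaluationError("evaluation needs both responders and non-responders")
    return y, s


def auc_from_scores(scores: pd.Series, calls: SensitivityCalls) -> float:
    """ROC AUC with responder as the positive class (trapezoid rule)."""
    y, s = _binary_labels(scores, calls)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return float(_trapezoid_auc(fpr, tpr))


def evaluate(
    scores: ScoreVector | pd.Series,
    calls: SensitivityCalls,
    threshold_policy="youden",
) -> EvalReport:
    """ROC curve, AUC, and accuracy at a policy-chosen score threshold.

    ``threshold_policy`` is ``"youden"`` (maximize TPR - FPR), a float (a
    frozen threshold, e.g. a Youden point carried over from training), or
    ``"prevalence"`` (predicted-positive rate closest to the prevalence).
    Samples labeled "neither" are excluded.
    """
    s_series = scores.scores if isinstance(scores, ScoreVector) else scores
    y, s = _binary_labels(s_series, calls)
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc_val = float(_trapezoid_auc(fpr, tpr))

    if isinstance(threshold_policy, (int, float)) and not isinstance(
        threshold_policy, bool
    ):
        t = float(threshold_policy)
    elif threshold_policy == "youden":
        t = float(thr[np.argmax(tpr - fpr)])
    elif threshold_policy == "prevalence":
        prevalence = y.mean()
        rates = np.array([(s >= c).mean() for c in thr])
        t = float(thr[np.argmin(np.abs(rates - prevalence))])
    else:
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")

    pred = s >= t
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    return EvalReport(
        auc=auc_val,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        accuracy=(tp + tn) / len(y),
        threshold_used=t,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


def stratified_drug_screen(
    scores: ScoreVector | pd.Series,
    d: DrugResponseTable,
    exclude_auc_above: float = 10.0,
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Score-stratified differential drug-sensitivity screen.

    Strata: *high* = score more than one standard deviation above the mean,
    *low* = score below the mean.  Drugs whose mean sensitivity value in the
    high stratum exceeds ``exclude_auc_above`` (a response-AUC toxicity
    filter: large values mean the drug kills nothing) are excluded, as are
    drugs with fewer than ``min_group_size`` samples in either stratum.
    Surviving drugs are tested high vs low with a two-sided Welch t-test;
    ``effect = mean(high) - mean(low)``, so a *negative* effect means the
    high-scoring stratum is more sensitive.  The table is sorted for a
    volcano-style ranking (usable drugs first, then ascending p).
    """
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    s = s.astype(float)
    mean, sd = s.mean(), s.std(ddof=1)
    high = s.index[s > mean + sd]
    low = s.index[s < mean]
    rows = []
    for drug in d.drug_ids:
        vals = d.values_for(drug)
        hi = vals.loc[vals.index.intersection(high)].to_numpy(dtype=float)
        lo = vals.loc[vals.index.intersection(low)].to_numpy(dtype=float)
        if len(hi) < min_group_size or len(lo) < min_group_size:
            rows.append((drug, len(hi), len(lo), np.nan, np.nan, np.nan, np.nan,
                         True, "too_few_samples"))
            continue
        mean_hi = hi.mean()
        mean_lo = lo.mean()
        if mean_hi > exclude_auc_above:
            rows.append((drug, len(hi), len(lo), mean_hi, mean_lo,
                         mean_hi - mean_lo, np.nan, True, "not_cytotoxic"))
            continue
        with np.errstate(invalid="ignore"):
            _, p = stats.ttest_ind(hi, lo, equal_var=False)
        rows.append((drug, len(hi), len(lo), mean_hi, mean_lo,
                     mean_hi - mean_lo, float(p), False, "ok"))
    out = pd.DataFrame(
        rows,
        columns=["drug_id", "n_high", "n_low", "mean_high", "mean_low",
                 "effect", "p_value", "excluded", "reason"],
    ).set_index("drug_id")
    if out["excluded"].all():
        warnings.warn(
            "stratified_drug_screen: no drug survived the stratum-size and "
            "toxicity filters; the table lists the reason per drug"
        )
    return out.sort_values(["excluded", "p_value"], na_position="last")
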