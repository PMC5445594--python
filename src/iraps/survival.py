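"""Score-based survival stratification: log-rank test, optimal cutpoint, Cox.

Patients are split into two groups at a signature-score cutpoint chosen to
*maximize* the two-group log-rank statistic over all admissible splits (the
minimum-p-value split).  Because the cutpoint is optimized, the reported
p-value at the chosen split is optimistic; the result carries an explicit
flag saying so, and no correction is applied.

The log-rank statistic is computed from the standard observed-minus-expected
table with the hypergeometric variance; simultaneous events at a time all
count within that time's risk set.  Hazard-ratio estimation with covariate
adjustment is delegated to lifelines' Cox proportional-hazards fitter —
plumbing, not re-derived math.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SurvivalTable
from .errors import DegenerateInputError, EvaluationError

logger = logging.getLogger(__name__)


@dataclass
class CutpointResult:
    cutpoint: float
    logrank_statistic: float
    p_value: float
    n_low: int
    n_high: int
    candidates: pd.DataFrame  # all scanned cutpoints with statistics
    p_value_is_optimistic: bool = True  # maximized over cutpoints, uncorrected


def _records(group) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(group, SurvivalTable):
        df = group.data
    else:
        df = group
    return (
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=int),
    )


def logrank(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic (1 df) and its p-value.

    Accepts :class:`SurvivalTable` or DataFrames with ``time``/``event``
    columns.  Raises when there is no event in either group (the statistic
    is undefined).
    """
    ta, ea = _records(group_a)
    tb, eb = _records(group_b)
    if len(ta) == 0 or len(tb) == 0:
        raise EvaluationError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise DegenerateInputError("log-rank undefined with zero events")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    observed = 0.0
    expected = 0.0
    variance = 0.0
    for t in event_times:
        n1 = np.sum(ta >= t)
        n2 = np.sum(tb >= t)
        n = n1 + n2
        d1 = np.sum((ta == t) & (ea == 1))
        d2 = np.sum((tb == t) & (eb == 1))
        d = d1 + d2
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0, 1.0
    statistic = (observed - expected) ** 2 / variance
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def optimal_cutpoint(
    s: SurvivalTable, min_group_frac: float = 0.2
) -> CutpointResult:
    """Scan score cutpoints and return the one maximizing the log-rank statistic.

    Every midpoint between consecutive distinct sorted scores whose split
    leaves at least ``min_group_frac`` of the patients on each side is a
    candidate.  The returned p-value is the *unadjusted* one at the maximum
    and is anti-conservative; ``p_value_is_optimistic`` flags this.
    """
    if "score" not in s.data.columns:
        raise EvaluationError("survival table has no score column")
    if len(s) < 10:
        raise DegenerateInputError("cutpoint scan needs at least 10 patients")
    scores = s.data["score"].to_numpy(dtype=float)
    distinct = np.unique(scores)
    if len(distinct) < 2:
        raise DegenerateInputError("all scores equal: no admissible split")
    n = len(s)
    min_n = min_group_frac * n
    rows = []
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = (lo + hi) / 2.0
        low_mask = scores <= cut
        n_low = int(low_mask.sum())
        n_high = n - n_low
        if n_low < min_n or n_high < min_n:
            continue
        stat, p = logrank(s.data[low_mask], s.data[~low_mask])
        rows.append((cut, n_low, n_high, stat, p))
    if not rows:
        raise DegenerateInputError(
            f"no split leaves at least {min_group_frac:.0%} of patients per group"
        )
    candidates = pd.DataFrame(
        rows, columns=["cutpoint", "n_low", "n_high", "statistic", "p_value"]
    )
    best = candidates.loc[candidates["statistic"].idxmax()]
    return CutpointResult(
        cutpoint=float(best["cutpoint"]),
        logrank_statistic=float(best["statistic"]),
        p_value=float(best["p_value"]),
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
        candidates=candidates,
    )


def cox_adjusted(
    s: SurvivalTable,
    covariates: tuple[str, ...] = (),
    score_col: str = "score",
) -> pd.DataFrame:
    """Covariate-adjusted hazard ratios via a proportional-hazards fit.

    Delegated to :class:`lifelines.CoxPHFitter`.  Rows with missing values
    in the used columns are dropped (count logged).  Returns a table with
    one row per term: ``hr``, ``ci_lower``, ``ci_upper`` (95%), ``p``.
    """
    from lifelines import CoxPHFitter

    cols = [score_col, *covariates]
    missing = [c for c in cols if c not in s.data.columns]
    if missing:
        raise EvaluationError(f"survival table lacks columns: {missing}")
    df = s.data[["time", "event", *cols]].astype(float)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("cox_adjusted: dropped %d incomplete rows", n0 - len(df))
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summ = cph.summary
    return pd.DataFrame(
        {
            "hr": summ["exp(coef)"],
            "ci_lower": summ["exp(coef) lower 95%"],
            "ci_upper": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
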