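"""Grid search over p-value / fold-change / conservation thresholds.

A candidate signature at grid point ``(p_thr, fc_thr, cons_thr)`` consists
of every gene whose *conservation fraction* — the fraction of resampling
iterations in which it reached ``p < p_thr`` and ``|fold change| > fc_thr``
with a direction matching its majority sign — is at least ``cons_thr``.
The gene's weight is its mean log2 fold change over the iterations in which
it qualified.  Candidates are scored on the training tissue by correlation
scoring + ROC AUC (responder = positive class), and the signature with the
best training AUC wins.  Ties — common when the training panel is cleanly
separable, since many threshold combinations then reach the same AUC — are
broken toward the *most conserved* candidate (largest conservation
threshold) and then the most *complete* one (most genes): at equal
training accuracy a stricter conservation requirement buys stability
across resamples, and keeping all qualifying genes rather than a minimal
subset preserves redundancy that helps the signature transfer to cohorts
profiled on other platforms or with missing genes.  Remaining ties go to
the smaller p threshold.

The majority-sign requirement is a deliberate refinement of plain
"altered at threshold" counting: a signed weight is meaningless for a gene
that flips direction between iterations.  It can be switched off with
``direction_consistent=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, Signature
from .errors import OptimizationError
from .iterative_resampling import ResamplingArchive
from .response_classification import SensitivityCalls
from . import signature_scoring

DEFAULT_P_GRID = (1e-2, 1e-3, 1e-4, 1e-5)
DEFAULT_FC_GRID = (1.1, 1.25, 1.5, 2.0)
DEFAULT_CONS_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95)
MIN_GENES = 5


@dataclass
class GridPoint:
    p_threshold: float
    fc_threshold: float
    conservation_threshold: float
    n_genes: int
    train_auc: float | None


def _qualify(
    archive: ResamplingArchive,
    p_thr: float,
    fc_thr: float,
    direction_consistent: bool = True,
) -> tuple[pd.Series, pd.Series]:
    """Conservation fraction and mean qualifying log2 fold change per gene.

    ``fc_thr`` is on the ratio scale (>= 1); a gene qualifies in an
    iteration when ``p < p_thr`` and ``|log2_fc| > log2(fc_thr)``.  With
    direction consistency, only iterations matching the gene's majority
    sign count (ties broken by the sign of the summed qualifying fold
    change).
    """
    if fc_thr < 1:
        raise ValueError("fold-change threshold is a ratio and must be >= 1")
    p = archive.pvals
    fc = archive.log2fc
    q = (p < p_thr) & (np.abs(fc) > np.log2(fc_thr))
    if direction_consistent:
        up = q & (fc > 0)
        dn = q & (fc < 0)
        n_up = up.sum(axis=0)
        n_dn = dn.sum(axis=0)
        fc_sum = np.where(q, fc, 0.0).sum(axis=0)
        use_up = (n_up > n_dn) | ((n_up == n_dn) & (fc_sum >= 0))
        sel = np.where(use_up[None, :], up, dn)
    else:
        sel = q
    n_sel = sel.sum(axis=0)
    with np.errstate(invalid="ignore"):
        weight = np.where(sel, fc, 0.0).sum(axis=0) / np.where(n_sel > 0, n_sel, 1)
    weight = np.where(n_sel > 0, weight, np.nan)
    cons = n_sel / archive.n_iterations
    return (
        pd.Series(cons, index=archive.genes),
        pd.Series(weight, index=archive.genes),
    )


def conservation_fraction(
    archive: ResamplingArchive,
    gene: str,
    p_thr: float,
    fc_thr: float,
    direction_consistent: bool = True,
) -> float:
    """Fraction of iterations in which ``gene`` qualified at the thresholds."""
    cons, _ = _qualify(archive, p_thr, fc_thr, direction_consistent)
    return float(cons.loc[gene])


def build_candidate(
    archive: ResamplingArchive,
    p_thr: float,
    fc_thr: float,
    cons_thr: float,
    direction_consistent: bool = True,
) -> Signature:
    """Candidate signature at one grid point; may be empty (flagged in provenance)."""
    if not 0 < cons_thr <= 1:
        raise ValueError("conservation threshold must lie in (0, 1]")
    cons, weight = _qualify(archive, p_thr, fc_thr, direction_consistent)
    keep = cons >= cons_thr
    weights = weight[keep].dropna()
    return Signature(
        weights=weights,
        thresholds=(p_thr, fc_thr, cons_thr),
        training_auc=None,
        provenance={
            "drugs": list(archive.drugs),
            "iterations": int(archive.n_iterations),
            "seed": archive.seed,
            "empty": bool(len(weights) == 0),
        },
    )


def optimize(
    archive: ResamplingArchive,
    train_expr: ExpressionMatrix,
    train_calls: SensitivityCalls,
    p_grid=DEFAULT_P_GRID,
    fc_grid=DEFAULT_FC_GRID,
    cons_grid=DEFAULT_CONS_GRID,
    min_genes: int = MIN_GENES,
    min_overlap: int = 3,
    direction_consistent: bool = True,
) -> tuple[Signature, pd.DataFrame]:
    """Sweep the threshold grid and return the best signature plus the grid table.

    ``train_expr`` should already be restricted to the target tissue(s) and
    must exclude any held-out test samples.  For each grid point the
    candidate is built and its training ROC AUC computed over responder vs
    non-responder samples ("neither" excluded); candidates with fewer than
    ``min_genes`` genes are skipped.  Raises :class:`OptimizationError`
    (carrying the diagnostic table) when no usable, better-than-chance
    candidate exists.
    """
    rows = []
    candidates = []
    for p_thr, fc_thr in product(p_grid, fc_grid):
        cons, weight = _qualify(archive, p_thr, fc_thr, direction_consistent)
        for cons_thr in cons_grid:
            keep = cons >= cons_thr
            weights = weight[keep].dropna()
            n = len(weights)
            if n < min_genes:
                rows.append((p_thr, fc_thr, cons_thr, n, np.nan, "too_few_genes"))
                continue
            sig = Signature(
                weights=weights, thresholds=(p_thr, fc_thr, cons_thr)
            )
            try:
                sv = signature_scoring.score(sig, train_expr, min_overlap=min_overlap)
                auc = signature_scoring.auc_from_scores(sv.scores, train_calls)
            except Exception as exc:  # unscorable candidate: record, move on
                rows.append((p_thr, fc_thr, cons_thr, n, np.nan, type(exc).__name__))
                continue
            rows.append((p_thr, fc_thr, cons_thr, n, auc, "ok"))
            candidates.append((auc, n, cons_thr, p_thr, fc_thr, sig))

    grid = pd.DataFrame(
        rows,
        columns=[
            "p_threshold",
            "fc_threshold",
            "conservation_threshold",
            "n_genes",
            "train_auc",
            "status",
        ],
    )
    if not candidates:
        raise OptimizationError(
            "no grid point produced a candidate with at least "
            f"{min_genes} genes", gridpoints=grid
        )
    # max AUC, then most conserved, then most complete, then smallest p
    candidates.sort(key=lambda c: (-c[0], -c[2], -c[1], c[3], c[4]))
    best_auc, n, cons_thr, p_thr, fc_thr, best = candidates[0]
    if best_auc < 0.5:
        raise OptimizationError(
            f"best training AUC {best_auc:.3f} is worse than chance; "
            "refusing to select a signature", gridpoints=grid
        )
    best.training_auc = float(best_auc)
    best.provenance.update(
        {
            "drugs": list(archive.drugs),
            "iterations": int(archive.n_iterations),
            "seed": archive.seed,
            "tissues": sorted(pd.unique(train_expr.tissues)),
            "n_train_samples": int(train_expr.n_samples),
            "grid": {
                "p": list(p_grid),
                "fc": list(fc_grid),
                "conservation": list(cons_grid),
            },
        }
    )
    return best, grid
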