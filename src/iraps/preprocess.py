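"""Expression-matrix normalization: log2, quantile normalization, median polish.

The normalization chain applied to a raw cell-line panel is

1. ``log2_transform`` — elementwise ``log2(x + offset)`` (default offset 1);
2. ``quantile_normalize`` — force every sample (column) onto the common
   distribution of across-sample mean order statistics;
3. ``median_polish`` per tissue — Tukey's two-way decomposition
   ``x = overall + gene + sample + residual`` by alternating median sweeps.

``preprocess_per_tissue`` composes 2 and 3 within each tissue group and
returns the matrix with the gene (row) effects removed, i.e. each gene
centered within its tissue, so cross-tissue baseline differences do not
dominate downstream differential expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SCALE_LOG2, SCALE_RAW, ExpressionMatrix
from .errors import DomainError, LabelingError


@dataclass
class MedianPolishResult:
    """Additive decomposition ``x[i,j] = overall + row[i] + col[j] + residual[i,j]``."""

    overall: float
    row_effects: pd.Series
    col_effects: pd.Series
    residuals: pd.DataFrame
    iterations_used: int
    converged: bool

    def reconstruct(self) -> pd.DataFrame:
        out = self.residuals.add(self.row_effects, axis=0)
        out = out.add(self.col_effects, axis=1)
        return out + self.overall


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise ``log2(value + offset)``; flips the scale flag to log2."""
    if m.scale != SCALE_RAW:
        raise ValueError("matrix is already on the log2 scale")
    if offset < 0:
        raise DomainError("offset must be >= 0")
    shifted = m.values.to_numpy(dtype=float) + offset
    if (shifted <= 0).any():
        rows, cols = np.nonzero(shifted <= 0)
        cells = [
            (m.gene_ids[r], m.sample_ids[c])
            for r, c in list(zip(rows, cols))[:5]
        ]
        raise DomainError(
            f"nonpositive values under offset {offset}: first offenders {cells}"
        )
    out = pd.DataFrame(np.log2(shifted), index=m.gene_ids, columns=m.sample_ids)
    return ExpressionMatrix(out, m.tissues, SCALE_LOG2)


def _quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy(dtype=float)
    n, k = arr.shape
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(k):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        # ties within a column receive the mean of the reference values at
        # their tied ranks (the "average ties" convention)
        out[:, j] = (
            pd.Series(assigned).groupby(col, sort=False).transform("mean").to_numpy()
        )
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples so each column shares one value distribution.

    The reference distribution is the across-column mean of order statistics.
    Within-column rank order is preserved; applying the operation twice is
    the same as applying it once.
    """
    if m.values.isna().to_numpy().any():
        raise ValueError("quantile normalization requires a complete matrix")
    if m.n_samples < 2:
        warnings.warn("single-sample matrix: quantile normalization is a no-op")
        return m.copy()
    return ExpressionMatrix(
        _quantile_normalize_frame(m.values), m.tissues, m.scale
    )


def median_polish(
    m: ExpressionMatrix | pd.DataFrame,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> MedianPolishResult:
    """Tukey median polish by alternating row/column median sweeps.

    Stops when the relative change in the sum of absolute residuals drops
    below ``tol`` or after ``max_iter`` sweeps.  The reconstruction
    invariant ``overall + row + col + residual == input`` holds exactly
    (up to floating point) at any iteration count.
    """
    df = m.values if isinstance(m, ExpressionMatrix) else m
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("median polish needs at least a 2x2 matrix")
    z = df.to_numpy(dtype=float).copy()
    nrow, ncol = z.shape
    overall = 0.0
    row = np.zeros(nrow)
    col = np.zeros(ncol)
    oldsum = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        overall += delta

        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        overall += delta

        newsum = np.abs(z).sum()
        if newsum == 0 or abs(newsum - oldsum) < tol * newsum:
            converged = True
            break
        oldsum = newsum
    # fold any leftover effect medians into the overall term so that both
    # effect vectors are exactly median-centered; residuals are untouched
    for effects in (row, col):
        delta = np.median(effects)
        effects -= delta
        overall += delta
    return MedianPolishResult(
        overall=float(overall),
        row_effects=pd.Series(row, index=df.index),
        col_effects=pd.Series(col, index=df.columns),
        residuals=pd.DataFrame(z, index=df.index, columns=df.columns),
        iterations_used=it,
        converged=converged,
    )


def preprocess_per_tissue(
    m: ExpressionMatrix,
    quantile_within_tissue: bool = True,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> ExpressionMatrix:
    """Quantile-normalize and median-polish each tissue group independently.

    Within each tissue: quantile normalization across that tissue's samples,
    then median polish; the returned matrix keeps the sample (column)
    effects and residuals but drops the overall and gene (row) effects, so
    every gene is centered within its tissue.  Tissue groups of size 1 pass
    through centered at 0.

    Whether quantile normalization happens within tissue (default) or once
    across the whole panel is configurable via ``quantile_within_tissue``.
    """
    if m.tissues.isna().any():
        bad = m.tissues.index[m.tissues.isna()]
        raise LabelingError(f"samples with missing tissue label: {list(bad)[:5]}")
    if m.scale == SCALE_RAW:
        warnings.warn(
            "preprocess_per_tissue called on a raw-scale matrix; "
            "log2_transform first for the standard chain"
        )
    work = m if quantile_within_tissue else quantile_normalize(m)
    pieces = []
    for tissue in pd.unique(work.tissues):
        cols = work.tissues.index[work.tissues == tissue]
        sub = work.values[list(cols)]
        if len(cols) == 1:
            pieces.append(pd.DataFrame(0.0, index=sub.index, columns=sub.columns))
            continue
        if quantile_within_tissue:
            sub = _quantile_normalize_frame(sub)
        mp = median_polish(sub, max_iter=max_iter, tol=tol)
        centered = mp.residuals.add(mp.col_effects, axis=1)
        pieces.append(centered)
    out = pd.concat(pieces, axis=1)[list(m.sample_ids)]
    return ExpressionMatrix(out, m.tissues, m.scale)
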