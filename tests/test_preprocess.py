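"""Normalization chain: log2, quantile normalization, Tukey median polish."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from iraps import (
    ExpressionMatrix,
    log2_transform,
    median_polish,
    preprocess_per_tissue,
    quantile_normalize,
)
from iraps.errors import DomainError
from iraps.preprocess import _quantile_normalize_frame


def _em(values, tissues=None, scale="raw"):
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(np.shape(values)[0])],
        columns=[f"s{i}" for i in range(np.shape(values)[1])],
    )
    if tissues is not None:
        tissues = pd.Series(tissues, index=df.columns)
    return ExpressionMatrix(df, tissues, scale)


# ---------------------------------------------------------------- log2

def test_log2_transform_values():
    out = log2_transform(_em([[8.0, 7.0]]), offset=0.0)
    assert out.values.iloc[0, 0] == 3.0
    out = log2_transform(_em([[0.0, 1.0]]), offset=1.0)
    assert out.values.iloc[0, 0] == 0.0
    assert out.scale == "log2"


def test_log2_transform_rejects_nonpositive_cells():
    with pytest.raises(DomainError, match="g0.*s0"):
        log2_transform(_em([[0.0, 1.0]]), offset=0.0)


def test_log2_transform_rejects_double_application():
    m = log2_transform(_em([[1.0, 2.0]]))
    with pytest.raises(ValueError, match="already"):
        log2_transform(m)


# ---------------------------------------------------------------- quantile

def test_quantile_normalize_hand_example():
    # columns [1,3] and [2,4]: rank means are (1+2)/2 = 1.5 and (3+4)/2 = 3.5
    out = quantile_normalize(_em([[1.0, 2.0], [3.0, 4.0]]))
    expected = np.array([[1.5, 1.5], [3.5, 3.5]])
    np.testing.assert_allclose(out.values.to_numpy(), expected)


def test_quantile_normalize_identical_columns_fixed_point():
    m = _em([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]])
    out = quantile_normalize(m)
    np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())


def test_quantile_normalize_ties_get_mean_reference():
    # reference = mean of sorted columns: [1.5, 2.5, 6.5]; the tied pair in
    # column 0 shares the mean of the reference values at ranks 1-2, i.e. 2.0
    out = quantile_normalize(_em([[1.0, 2.0], [1.0, 4.0], [7.0, 6.0]]))
    np.testing.assert_allclose(out.values.iloc[:, 0].to_numpy(), [2.0, 2.0, 6.5])
    np.testing.assert_allclose(out.values.iloc[:, 1].to_numpy(), [1.5, 2.5, 6.5])


def test_quantile_normalize_single_sample_warns_and_passes_through():
    m = _em([[1.0], [2.0]])
    with pytest.warns(UserWarning, match="single-sample"):
        out = quantile_normalize(m)
    pd.testing.assert_frame_equal(out.values, m.values)


@given(st.integers(0, 10_000))
def test_quantile_normalize_idempotent_and_rank_preserving(seed):
    # idempotence holds exactly on tie-free columns (tie-averaging couples
    # columns, so a second pass could move tied groups slightly)
    rng = np.random.default_rng(seed)
    m = _em(rng.normal(0, 2, size=(15, 4)))
    once = quantile_normalize(m)
    twice = quantile_normalize(once)
    np.testing.assert_allclose(
        once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12
    )
    for j in range(4):
        a = m.values.iloc[:, j].rank(method="average")
        b = once.values.iloc[:, j].rank(method="average")
        pd.testing.assert_series_equal(a, b, check_names=False)


# ---------------------------------------------------------------- median polish

def _brute_force_polish(x, max_iter=10, tol=1e-6):
    """Independent sweep implementation used as an element-wise oracle."""
    z = np.array(x, dtype=float)
    overall, row, col = 0.0, np.zeros(z.shape[0]), np.zeros(z.shape[1])
    oldsum = 0.0
    for _ in range(max_iter):
        for i in range(z.shape[0]):
            d = np.median(z[i])
            z[i] -= d
            row[i] += d
        d = np.median(col)
        col -= d
        overall += d
        for j in range(z.shape[1]):
            d = np.median(z[:, j])
            z[:, j] -= d
            col[j] += d
        d = np.median(row)
        row -= d
        overall += d
        newsum = np.abs(z).sum()
        if newsum == 0 or abs(newsum - oldsum) < tol * newsum:
            break
        oldsum = newsum
    for eff in (row, col):
        d = np.median(eff)
        eff -= d
        overall += d
    return overall, row, col, z


def test_median_polish_additive_matrix_has_zero_residuals():
    r = np.array([1.0, 2.0, 4.0])
    c = np.array([0.5, -0.5, 1.0, 2.0])
    m = _em(r[:, None] + c[None, :])
    res = median_polish(m)
    np.testing.assert_allclose(res.residuals.to_numpy(), 0.0, atol=1e-12)
    np.testing.assert_allclose(
        res.reconstruct().to_numpy(), m.values.to_numpy(), atol=1e-12
    )


def test_median_polish_constant_matrix():
    res = median_polish(_em(np.full((3, 3), 7.0)))
    assert res.overall == 7.0
    np.testing.assert_allclose(res.row_effects, 0.0)
    np.testing.assert_allclose(res.col_effects, 0.0)
    np.testing.assert_allclose(res.residuals.to_numpy(), 0.0)


def test_median_polish_matches_independent_sweep_oracle():
    x = [[1.0, 2.0], [3.0, 5.0]]
    res = median_polish(_em(x))
    overall, row, col, resid = _brute_force_polish(x)
    assert res.overall == pytest.approx(overall)
    np.testing.assert_allclose(res.row_effects.to_numpy(), row)
    np.testing.assert_allclose(res.col_effects.to_numpy(), col)
    np.testing.assert_allclose(res.residuals.to_numpy(), resid)


def test_median_polish_requires_2x2():
    with pytest.raises(ValueError):
        median_polish(_em([[1.0, 2.0]]))


@given(st.integers(0, 10_000))
def test_median_polish_reconstruction_invariant(seed):
    rng = np.random.default_rng(seed)
    m = _em(rng.normal(0, 3, size=(8, 6)))
    res = median_polish(m)
    err = np.abs(res.reconstruct().to_numpy() - m.values.to_numpy()).max()
    assert err < 1e-9
    # effect vectors are exactly median-centered on exit
    assert abs(np.median(res.row_effects)) < 1e-9
    assert abs(np.median(res.col_effects)) < 1e-9


# ---------------------------------------------------------------- per tissue

def test_per_tissue_equal_samples_give_zero():
    m = _em(np.tile([[5.0], [2.0], [9.0]], (1, 4)), tissues=["t"] * 4, scale="log2")
    out = preprocess_per_tissue(m)
    np.testing.assert_allclose(out.values.to_numpy(), 0.0, atol=1e-12)


def test_per_tissue_centers_genes_within_tissue(rng):
    base = rng.normal(6, 1, size=(30, 1))
    shift = np.array([0.0] * 5 + [3.0] * 5)  # tissue 2 has higher baselines
    x = base + shift[None, :] + rng.normal(0, 0.1, size=(30, 10))
    m = _em(x, tissues=["a"] * 5 + ["b"] * 5, scale="log2")
    out = preprocess_per_tissue(m)
    for tissue in ("a", "b"):
        cols = out.tissues.index[out.tissues == tissue]
        med = out.values[list(cols)].median(axis=1)
        np.testing.assert_allclose(med, 0.0, atol=1e-9)
        assert out.values[list(cols)].mean(axis=1).abs().max() < 0.2


def test_per_tissue_equals_composed_stages(small_matrix):
    out = preprocess_per_tissue(small_matrix)
    for tissue in ("breast", "ovary"):
        cols = list(small_matrix.tissues.index[small_matrix.tissues == tissue])
        qn = _quantile_normalize_frame(small_matrix.values[cols])
        mp = median_polish(qn)
        expected = mp.residuals.add(mp.col_effects, axis=1)
        pd.testing.assert_frame_equal(out.values[cols], expected)


def test_per_tissue_invariant_to_sample_order(small_matrix):
    out1 = preprocess_per_tissue(small_matrix)
    perm = list(small_matrix.sample_ids[::-1])
    shuffled = small_matrix.subset_samples(perm)
    out2 = preprocess_per_tissue(shuffled)
    pd.testing.assert_frame_equal(
        out1.values, out2.values[list(out1.sample_ids)]
    )


def test_per_tissue_singleton_group_centered_at_zero(rng):
    x = rng.normal(6, 1, size=(5, 3))
    m = _em(x, tissues=["a", "a", "solo"], scale="log2")
    out = preprocess_per_tissue(m)
    np.testing.assert_allclose(out.values["s2"].to_numpy(), 0.0)
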