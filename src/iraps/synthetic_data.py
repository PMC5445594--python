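"""Synthetic pharmacogenomic fixtures with known ground truth.

The pipeline's core assumption is that a latent per-cell-line sensitivity
factor drives *both* the expression of a subset of genes and the measured
drug response.  The panel generator plants exactly that structure:

* a latent sensitivity ``s_i ~ N(0, 1)`` per cell line;
* two drugs whose response z-scores load on the shared factor,
  ``z_k = sqrt(rho) * s + sqrt(1 - rho) * eps_k``, so the two z-score
  vectors have correlation ``rho`` and each correlates ``sqrt(rho)`` with
  the latent factor; IC50-like values are ``exp(z)`` (log-normal, metric
  "ic50"), so natural-log z-scoring recovers ``z`` up to standardization;
* ``n_planted`` genes with expression
  ``baseline_g + sign_g * effect_size * s_i + N(0, noise_sd)``; all other
  genes are baseline plus noise.

Because responders are the cell lines with *low* response z (low IC50,
i.e. low ``s``), a gene coupled positively to ``s`` is *under*-expressed in
responders: its expected signature-weight sign is the negative of its
coupling sign.  :class:`SyntheticTruth` carries both.

Defaults (2,000 genes x 200 samples, 60 planted genes, effect 1.2 log2
units per SD of the latent factor, drug-pair correlation 0.8) are the study
conditions used throughout the test-suite; they are large enough to
exercise the grid search yet run in well under a minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    METRIC_IC50,
    DrugResponseTable,
    ExpressionMatrix,
    SCALE_LOG2,
    SurvivalTable,
)
from .synergy import DoseResponseSeries

DEFAULT_N_GENES = 2000
DEFAULT_N_SAMPLES = 200
DEFAULT_N_PLANTED = 60
DEFAULT_EFFECT_SIZE = 1.2
DEFAULT_RHO = 0.8
DEFAULT_TISSUES = ("breast", "ovary")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated panel.

    ``planted`` maps gene id -> signed coupling to the latent sensitivity
    factor (log2 units per SD); ``expected_weight_sign`` is the sign a
    recovered responder-vs-non-responder signature weight should carry
    (the negative of the coupling sign).
    """

    planted: pd.Series
    baselines: pd.Series
    latent: pd.Series
    tissue_labels: pd.Series
    rho: float
    effect_size: float
    n_genes: int
    n_samples: int
    drug_ids: tuple[str, str]
    seed: int

    @property
    def planted_genes(self) -> pd.Index:
        return self.planted.index

    @property
    def expected_weight_sign(self) -> pd.Series:
        return -np.sign(self.planted)


def generate_panel(
    n_genes: int = DEFAULT_N_GENES,
    n_samples: int = DEFAULT_N_SAMPLES,
    n_planted: int = DEFAULT_N_PLANTED,
    effect_size: float = DEFAULT_EFFECT_SIZE,
    rho: float = DEFAULT_RHO,
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
    seed: int = 0,
    *,
    truth: SyntheticTruth | None = None,
    baseline_mean: float = 6.0,
    baseline_sd: float = 1.0,
    noise_sd: float = 1.0,
    drug_ids: tuple[str, str] = ("drugA", "drugB"),
    sample_prefix: str = "CL",
) -> tuple[ExpressionMatrix, DrugResponseTable, SyntheticTruth]:
    """Generate an expression panel with correlated drug responses.

    Pass ``truth`` from a previous call to draw *fresh samples from the same
    data-generating process* (same gene universe, planted couplings and
    baselines) — the way to build a held-out cohort for a signature trained
    on the original panel.

    ``rho`` is the correlation between the two drugs' z-scores and must lie
    in [0, 1] under the shared-factor construction; ``rho = 1`` makes the
    two drugs identical.
    """
    if truth is not None:
        n_genes = truth.n_genes
        n_planted = len(truth.planted)
        effect_size = truth.effect_size
        rho = truth.rho
        drug_ids = truth.drug_ids
    if not 0 <= rho <= 1:
        raise ValueError("drug-pair correlation rho must lie in [0, 1]")
    if n_planted >= n_genes:
        raise ValueError("n_planted must be smaller than n_genes")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if n_samples < 4:
        raise ValueError("need at least 4 samples")

    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")
    samples = pd.Index(
        [f"{sample_prefix}{i:04d}" for i in range(n_samples)], name="sample_id"
    )

    if truth is None:
        planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_planted)
        planted = pd.Series(
            signs * effect_size, index=genes[planted_idx]
        ).sort_index()
        baselines = pd.Series(
            rng.normal(baseline_mean, baseline_sd, size=n_genes), index=genes
        )
    else:
        planted = truth.planted.copy()
        baselines = truth.baselines.copy()

    latent = rng.standard_normal(n_samples)
    eps = rng.standard_normal((2, n_samples))
    z = np.sqrt(rho) * latent[None, :] + np.sqrt(1.0 - rho) * eps
    ic50 = np.exp(z)

    coupling = pd.Series(0.0, index=genes)
    coupling.loc[planted.index] = planted
    values = (
        baselines.to_numpy()[:, None]
        + coupling.to_numpy()[:, None] * latent[None, :]
        + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    )
    tissue_labels = pd.Series(
        [tissues[i % len(tissues)] for i in range(n_samples)], index=samples
    )
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        tissue_labels,
        SCALE_LOG2,
    )
    records = pd.DataFrame(
        {
            "sample_id": np.tile(samples.to_numpy(), 2),
            "drug_id": np.repeat(list(drug_ids), n_samples),
            "value": ic50.ravel(),
            "metric": METRIC_IC50,
        }
    )
    response = DrugResponseTable(records)
    out_truth = SyntheticTruth(
        planted=planted,
        baselines=baselines,
        latent=pd.Series(latent, index=samples),
        tissue_labels=tissue_labels,
        rho=rho,
        effect_size=effect_size,
        n_genes=n_genes,
        n_samples=n_samples,
        drug_ids=tuple(drug_ids),
        seed=seed,
    )
    return expr, response, out_truth


def generate_survival(
    n_patients: int,
    true_hr_per_score_unit: float = 1.0,
    censor_rate: float = 0.3,
    seed: int = 0,
    *,
    base_rate: float = 0.05,
    step_cutoff: float | None = None,
    with_covariates: bool = True,
) -> SurvivalTable:
    """Survival cohort whose hazard depends on a normally distributed score.

    Event times are exponential with rate ``base_rate * hr**score`` where
    ``hr = true_hr_per_score_unit`` (hr < 1: higher scores live longer).
    With ``step_cutoff`` set, the hazard instead switches once at the
    cutoff — rate ``base_rate`` below it and ``base_rate * hr`` above —
    planting a sharp change for cutpoint-recovery experiments.  Censored
    records (probability ``censor_rate``) are cut at a uniform fraction of
    their event time.  Optional independent ordinal covariates ``stage``
    (1-4) and ``grade`` (1-3) are attached for adjustment exercises.
    """
    if true_hr_per_score_unit <= 0:
        raise ValueError("hazard ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    score = rng.standard_normal(n_patients)
    if step_cutoff is None:
        rate = base_rate * true_hr_per_score_unit**score
    else:
        rate = np.where(
            score > step_cutoff, base_rate * true_hr_per_score_unit, base_rate
        )
    time = rng.exponential(1.0 / rate)
    event = np.ones(n_patients, dtype=int)
    censored = rng.random(n_patients) < censor_rate
    event[censored] = 0
    time[censored] *= rng.uniform(0.05, 1.0, size=censored.sum())
    data = pd.DataFrame(
        {"time": time, "event": event, "score": score},
        index=pd.Index([f"P{i:04d}" for i in range(n_patients)], name="id"),
    )
    if with_covariates:
        data["stage"] = rng.integers(1, 5, size=n_patients)
        data["grade"] = rng.integers(1, 4, size=n_patients)
    return SurvivalTable(data)


def serial_dilution(top_dose: float, fold: float = 3.0, n: int = 7) -> np.ndarray:
    """Descending n-point serial dilution starting at ``top_dose``."""
    if top_dose <= 0 or fold <= 1 or n < 1:
        raise ValueError("need top_dose > 0, fold > 1, n >= 1")
    return top_dose / fold ** np.arange(n)


def generate_dose_response(
    dm: float,
    m: float,
    doses: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    drug: str = "drug",
) -> DoseResponseSeries:
    """Fractions affected from the median-effect equation plus Gaussian noise.

    ``fa(D) = (D/Dm)^m / (1 + (D/Dm)^m)``; noisy values are clamped to stay
    strictly inside (0, 1).
    """
    if dm <= 0:
        raise ValueError("Dm must be positive")
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be strictly positive")
    ratio = (doses / dm) ** m
    fa = ratio / (1.0 + ratio)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fa = fa + rng.normal(0.0, noise_sd, size=fa.shape)
    fa = np.clip(fa, 1e-4, 1 - 1e-4)
    return DoseResponseSeries(doses=doses, fraction_affected=fa, drug=drug)
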