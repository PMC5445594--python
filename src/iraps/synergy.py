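"""Median-effect dose-response modeling and Chou-Talalay combination indices.

The median-effect equation relates dose ``D`` to the fraction of cells
affected ``fa`` (``fu = 1 - fa``):

    fa / fu = (D / Dm) ** m

``Dm`` is the median-effect dose (the dose giving fa = 0.5) and ``m`` the
sigmoidicity of the curve.  Taking logs linearizes the model, so ``Dm`` and
``m`` come from an ordinary least-squares line of ``log(fa/fu)`` on
``log(D)``.

For a two-drug combination tested at a fixed molar ratio, the combination
index at effect level ``fa`` is

    CI = d_A / D_A(fa) + d_B / D_B(fa)

where ``d_A, d_B`` are the component doses of the combination reaching
``fa`` and ``D_X(fa) = Dm_X * (fa/(1-fa))**(1/m_X)`` is the dose of drug X
alone reaching the same effect.  CI < 1 indicates synergy, CI = 1 Loewe
additivity, CI > 1 antagonism.  This two-term, mutually exclusive form is
the default; the mutually nonexclusive variant adds the product term
``(d_A * d_B) / (D_A * D_B)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, FittingError

FA_CLAMP_EPS = 0.005


@dataclass
class DoseResponseSeries:
    """Doses (molar units) and fractions affected for one drug or combination."""

    doses: np.ndarray
    fraction_affected: np.ndarray
    drug: str = "drug"
    ratio: tuple[float, float] | None = None  # fixed molar ratio for combos

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.fraction_affected = np.asarray(self.fraction_affected, dtype=float)
        if self.doses.shape != self.fraction_affected.shape:
            raise ValueError("doses and fraction_affected lengths differ")
        if (self.doses <= 0).any():
            raise DomainError("doses must be strictly positive")


@dataclass
class MedianEffectFit:
    """Fitted (Dm, m) of the median-effect equation with the linearized r2."""

    dm: float
    m: float
    r2: float
    n_points: int
    drug: str = "drug"

    def dose_for(self, fa: float) -> float:
        """Dose producing fraction affected ``fa`` under the fitted model."""
        if not 0 < fa < 1:
            raise DomainError("effect level must lie strictly inside (0, 1)")
        return self.dm * (fa / (1 - fa)) ** (1.0 / self.m)

    def fa_at(self, dose: float) -> float:
        """Model-predicted fraction affected at ``dose``."""
        ratio = (dose / self.dm) ** self.m
        return ratio / (1.0 + ratio)


def fit_median_effect(
    s: DoseResponseSeries, clamp_eps: float = FA_CLAMP_EPS
) -> MedianEffectFit:
    """Least-squares fit of the linearized median-effect equation.

    ``log(fa/fu)`` is regressed on ``log(D)``; the slope is ``m`` and the
    intercept ``-m * log(Dm)``.  Fractions affected at the assay floor or
    ceiling are clamped into ``(clamp_eps, 1 - clamp_eps)`` with a warning.
    At least 3 usable dose points are required.
    """
    fa = s.fraction_affected
    if len(fa) < 3:
        raise FittingError("median-effect fit needs at least 3 dose points")
    clamped = (fa <= clamp_eps) | (fa >= 1 - clamp_eps)
    if clamped.any():
        warnings.warn(
            f"{int(clamped.sum())} fraction-affected values clamped to "
            f"({clamp_eps}, {1 - clamp_eps})"
        )
        fa = np.clip(fa, clamp_eps, 1 - clamp_eps)
    x = np.log(s.doses)
    y = np.log(fa / (1 - fa))
    slope, intercept = np.polyfit(x, y, 1)
    if slope == 0:
        raise FittingError("flat dose-response: sigmoidicity m fitted as 0")
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return MedianEffectFit(
        dm=float(np.exp(-intercept / slope)),
        m=float(slope),
        r2=float(r2),
        n_points=len(fa),
        drug=s.drug,
    )


def _component_doses(
    fit_combo: MedianEffectFit, ratio: tuple[float, float], fa_level: float
) -> tuple[float, float]:
    a, b = ratio
    if a <= 0 or b <= 0:
        raise DomainError("ratio parts must be positive")
    d_total = fit_combo.dose_for(fa_level)
    return d_total * a / (a + b), d_total * b / (a + b)


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    ratio: tuple[float, float],
    fa_level: float,
    mutually_exclusive: bool = True,
) -> float:
    """Chou-Talalay combination index at one effect level.

    ``ratio = (parts_A, parts_B)`` is the fixed molar ratio of the
    combination series, whose doses are total (A+B) concentrations.  The
    default is the two-term mutually exclusive form; set
    ``mutually_exclusive=False`` to add the product term.
    """
    d_a, d_b = _component_doses(fit_combo, ratio, fa_level)
    D_a = fit_a.dose_for(fa_level)
    D_b = fit_b.dose_for(fa_level)
    ci = d_a / D_a + d_b / D_b
    if not mutually_exclusive:
        ci += (d_a * d_b) / (D_a * D_b)
    return float(ci)


def isobologram_points(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    ratio: tuple[float, float],
    fa_level: float = 0.5,
) -> dict:
    """Equi-effect isobologram coordinates at one effect level.

    Returns the single-agent axis intercepts ``(D_A(fa), 0)`` and
    ``(0, D_B(fa))`` plus the combination point ``(d_A, d_B)``.  The
    combination point lies under the line connecting the intercepts exactly
    when CI < 1.
    """
    d_a, d_b = _component_doses(fit_combo, ratio, fa_level)
    D_a = fit_a.dose_for(fa_level)
    D_b = fit_b.dose_for(fa_level)
    return {
        "intercept_a": (float(D_a), 0.0),
        "intercept_b": (0.0, float(D_b)),
        "combo_point": (float(d_a), float(d_b)),
        "ci": float(d_a / D_a + d_b / D_b),
        "fa_level": float(fa_level),
    }
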