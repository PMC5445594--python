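"""Responder / non-responder calling from z-scored drug sensitivity values.

Sensitivity values (IC50 or dose-response AUC) are standardized across the
cell-line panel; a line is a *responder* when its z-score is below -1 and a
*non-responder* when it is above 0 (strict inequalities; the band in
between belongs to neither class).  When two inhibitors of the same target
are available their z-scores are averaged, with the extra guard that a
responder must reach at least -0.5 on *each* drug — a one-drug-only outlier
cannot qualify — and a non-responder must be above 0 on both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    LABELS,
    METRIC_IC50,
    NEITHER,
    NON_RESPONDER,
    RESPONDER,
    DrugResponseTable,
)
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

RESPONDER_Z = -1.0
NON_RESPONDER_Z = 0.0
DUAL_GUARD_Z = -0.5


@dataclass
class SensitivityCalls:
    """Per-sample z-scores and responder labels.

    ``z`` is samples x drugs; ``combined_z`` is the mean of the available
    per-drug z-scores; ``labels`` takes values in
    ``{"responder", "non_responder", "neither"}`` — an exhaustive and
    exclusive partition of the samples.
    """

    z: pd.DataFrame
    combined_z: pd.Series
    labels: pd.Series

    def __post_init__(self):
        if not self.labels.isin(LABELS).all():
            raise ValueError("labels outside the allowed partition")

    @property
    def samples(self) -> pd.Index:
        return self.labels.index

    @property
    def responders(self) -> pd.Index:
        return self.labels.index[self.labels == RESPONDER]

    @property
    def non_responders(self) -> pd.Index:
        return self.labels.index[self.labels == NON_RESPONDER]

    @property
    def neither(self) -> pd.Index:
        return self.labels.index[self.labels == NEITHER]

    def counts(self) -> dict:
        vc = self.labels.value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in LABELS}

    def subset(self, samples) -> "SensitivityCalls":
        samples = pd.Index(samples).intersection(self.labels.index)
        return SensitivityCalls(
            self.z.loc[samples], self.combined_z.loc[samples], self.labels.loc[samples]
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.z.add_prefix("z_")
        out["combined_z"] = self.combined_z
        out["label"] = self.labels
        return out


def zscore_values(values: pd.Series) -> pd.Series:
    """Standardize with the sample standard deviation (ddof=1)."""
    x = values.astype(float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateInputError(
            "cannot z-score: zero variance across samples"
        )
    return (x - x.mean()) / sd


def zscore_sensitivity(
    d: DrugResponseTable, drug: str, log_ic50: bool = True
) -> pd.Series:
    """z-scores of one drug's sensitivity values across the panel.

    IC50 values are natural-log transformed before standardization when
    ``log_ic50`` is set (IC50s are log-normally distributed across panels);
    dose-response AUC values are standardized directly.
    """
    values = d.values_for(drug)
    if len(values) < 2:
        raise DegenerateInputError(f"drug {drug!r} has fewer than 2 samples")
    if d.metric_for(drug) == METRIC_IC50 and log_ic50:
        if (values <= 0).any():
            raise DegenerateInputError(
                f"drug {drug!r} has nonpositive IC50 values; cannot log-transform"
            )
        values = np.log(values)
    return zscore_values(values)


def _labels_single(z: pd.Series) -> pd.Series:
    lab = np.select(
        [z < RESPONDER_Z, z > NON_RESPONDER_Z],
        [RESPONDER, NON_RESPONDER],
        default=NEITHER,
    )
    return pd.Series(lab, index=z.index)


def call_single(z: pd.Series, drug: str = "drug") -> SensitivityCalls:
    """Single-agent rule: z < -1 responder, z > 0 non-responder, else neither."""
    z = z.astype(float)
    if not np.isfinite(z).all():
        raise ValueError("z-scores must be finite")
    return SensitivityCalls(
        z=z.to_frame(name=drug),
        combined_z=z.copy(),
        labels=_labels_single(z),
    )


def call_dual(
    z1: pd.Series,
    z2: pd.Series,
    drugs: tuple[str, str] = ("drug1", "drug2"),
    guard: float = DUAL_GUARD_Z,
) -> SensitivityCalls:
    """Dual-inhibitor rule on the average z-score of two drugs.

    responder:     mean(z1, z2) < -1 and z1 <= guard and z2 <= guard
    non-responder: z1 > 0 and z2 > 0
    neither:       otherwise

    Samples missing either drug are dropped (count logged).  The guard
    (default -0.5, boundary counted as satisfying it) excludes samples that
    respond strongly to only one of the two inhibitors.
    """
    common = z1.index.intersection(z2.index)
    dropped = len(z1.index.union(z2.index)) - len(common)
    if dropped:
        logger.info("call_dual: dropped %d samples missing one drug", dropped)
    z1 = z1.loc[common].astype(float)
    z2 = z2.loc[common].astype(float)
    mean_z = (z1 + z2) / 2.0
    is_resp = (mean_z < RESPONDER_Z) & (z1 <= guard) & (z2 <= guard)
    is_nonresp = (z1 > NON_RESPONDER_Z) & (z2 > NON_RESPONDER_Z)
    lab = np.select([is_resp, is_nonresp], [RESPONDER, NON_RESPONDER], default=NEITHER)
    return SensitivityCalls(
        z=pd.DataFrame({drugs[0]: z1, drugs[1]: z2}),
        combined_z=mean_z,
        labels=pd.Series(lab, index=common),
    )


def call_from_response(
    d: DrugResponseTable,
    drugs: tuple[str, ...],
    log_ic50: bool = True,
    samples=None,
) -> SensitivityCalls:
    """z-score the given drug(s) over the panel (or ``samples``) and call labels."""
    if len(drugs) not in (1, 2):
        raise ValueError("provide one or two drug ids")
    zs = []
    for drug in drugs:
        z = zscore_sensitivity(d, drug, log_ic50=log_ic50)
        if samples is not None:
            # restrict to the requested samples but keep panel-level z-scores
            z = z.loc[z.index.intersection(pd.Index(samples))]
        zs.append(z)
    if len(drugs) == 1:
        return call_single(zs[0], drug=drugs[0])
    return call_dual(zs[0], zs[1], drugs=(drugs[0], drugs[1]))
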