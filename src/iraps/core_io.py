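"""Domain types shared by every pipeline stage, plus tabular readers/writers.

The pipeline moves four kinds of objects around:

* :class:`ExpressionMatrix` — a dense genes x samples matrix of expression
  values (raw intensity or log2) with a tissue label per sample.
* :class:`DrugResponseTable` — long-format drug sensitivity records
  (IC50 in uM or a dose-response AUC) per (cell line, drug).
* :class:`Signature` — a signed gene-weight map together with the thresholds
  that produced it and its training ROC AUC.
* :class:`SurvivalTable` — per-patient follow-up time, event indicator,
  signature score, and optional ordinal covariates (stage, grade).

TSV is the canonical interchange format; GCT 1.2 is supported read-only
because public cell-line expression compendia ship in it.  Matrices are kept
dense: the method's scale (~25k genes x ~1k samples) never needs sparse
storage.  Gene and sample identifiers are treated as opaque strings.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    FormatError,
    LabelingError,
    ParseError,
    SchemaError,
)

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
NEITHER = "neither"
LABELS = (RESPONDER, NON_RESPONDER, NEITHER)

SCALE_RAW = "raw"
SCALE_LOG2 = "log2"


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with per-sample tissue labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    tissues
        Series mapping sample id -> tissue label.  A plain dict is accepted;
        ``None`` assigns the single shared label ``"all"``.
    scale
        ``"raw"`` or ``"log2"``.  After preprocessing the scale is ``log2``
        and every value is finite.
    """

    values: pd.DataFrame
    tissues: pd.Series | Mapping[str, str] | None = None
    scale: str = SCALE_RAW

    def __post_init__(self):
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample ids: {list(dupes)[:5]}")
        if self.tissues is None:
            self.tissues = pd.Series("all", index=self.values.columns)
        elif not isinstance(self.tissues, pd.Series):
            self.tissues = pd.Series(dict(self.tissues))
        missing = self.values.columns.difference(self.tissues.index)
        if len(missing) > 0:
            raise LabelingError(
                f"samples without a tissue label: {list(missing)[:5]}"
            )
        self.tissues = self.tissues.reindex(self.values.columns)
        if self.scale not in (SCALE_RAW, SCALE_LOG2):
            raise ValueError(f"unknown scale flag {self.scale!r}")
        if self.scale == SCALE_LOG2 and not np.isfinite(
            self.values.to_numpy(dtype=float)
        ).all():
            raise ValueError("log2-scale matrix contains non-finite values")

    # -- conveniences -------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        missing = samples.difference(self.sample_ids)
        if len(missing) > 0:
            raise KeyError(f"unknown samples: {list(missing)[:5]}")
        return ExpressionMatrix(
            self.values[list(samples)], self.tissues.loc[samples], self.scale
        )

    def subset_tissues(self, tissues: Sequence[str]) -> "ExpressionMatrix":
        keep = self.tissues.index[self.tissues.isin(list(tissues))]
        return self.subset_samples(keep)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.tissues.copy(), self.scale)


def _coerce_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    """Convert to float, reporting the first offending cell on failure."""
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = rows[0], cols[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at "
            f"gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return coerced.astype(float)


def read_tissue_map(path) -> pd.Series:
    """Read a two-column (sample_id, tissue) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: tissue map needs two columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def read_expression(
    path,
    format: str | None = None,
    tissue_map_path=None,
    allow_missing: bool = False,
    scale: str = SCALE_RAW,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV (genes in rows) or GCT 1.2.

    Duplicate gene ids are collapsed by their mean (deterministic and
    symmetric) with a warning.  NaN cells are rejected unless
    ``allow_missing`` is set.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[1] == 0:
            raise FormatError(f"{path}: no sample columns found")
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(
                    f"{path}: expected GCT version line '#1.2', got {version!r}"
                )
            dims = fh.readline().split()
            if len(dims) < 2:
                raise FormatError(f"{path}: malformed GCT dimension line")
            body = fh.read()
        df = pd.read_csv(io.StringIO(body), sep="\t", index_col=0)
        # GCT carries a Description column between ids and data; drop it.
        first = df.columns[0]
        if first.lower() == "description":
            df = df.drop(columns=[first])
        nrow, ncol = int(dims[0]), int(dims[1])
        if df.shape != (nrow, ncol):
            warnings.warn(
                f"{path}: GCT header declares {nrow}x{ncol}, found {df.shape}"
            )
    else:
        raise ValueError(f"unknown expression format {format!r}")

    df = _coerce_numeric(df, path)
    df.index.name = "gene_id"
    if df.index.has_duplicates:
        n = int(df.index.duplicated().sum())
        warnings.warn(f"{path}: collapsed {n} duplicate gene id rows by mean")
        df = df.groupby(level=0, sort=False).mean()
    if not allow_missing and df.isna().to_numpy().any():
        raise ParseError(
            f"{path}: matrix contains missing values; pass allow_missing=True "
            "to accept them"
        )
    tissues = read_tissue_map(tissue_map_path) if tissue_map_path else None
    return ExpressionMatrix(df, tissues, scale)


def write_expression(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# DrugResponseTable
# ---------------------------------------------------------------------------

METRIC_IC50 = "ic50"
METRIC_AUC = "auc"


@dataclass
class DrugResponseTable:
    """Long-format drug sensitivity records.

    ``records`` has columns ``sample_id``, ``drug_id``, ``value`` and
    ``metric`` (``"ic50"`` or ``"auc"``, per drug).  Missing (sample, drug)
    pairs are simply absent rows.  Every present value must be finite and
    every drug needs at least two distinct values, since z-scoring requires
    nonzero spread.
    """

    records: pd.DataFrame

    def __post_init__(self):
        required = {"sample_id", "drug_id", "value"}
        missing = required - set(self.records.columns)
        if missing:
            raise SchemaError(f"drug response table missing columns: {missing}")
        if "metric" not in self.records.columns:
            self.records = self.records.assign(metric=METRIC_IC50)
        vals = self.records["value"].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("drug response values must be finite")
        spread = self.records.groupby("drug_id")["value"].nunique()
        degenerate = spread.index[spread < 2]
        if len(degenerate) > 0:
            raise DegenerateInputError(
                f"drugs with fewer than 2 distinct values: {list(degenerate)}"
            )
        dup = self.records.duplicated(["sample_id", "drug_id"])
        if dup.any():
            raise ValueError("duplicate (sample_id, drug_id) records")

    @property
    def drug_ids(self) -> pd.Index:
        return pd.Index(self.records["drug_id"].unique())

    def values_for(self, drug: str) -> pd.Series:
        sub = self.records[self.records["drug_id"] == drug]
        if sub.empty:
            raise KeyError(f"unknown drug {drug!r}")
        return pd.Series(sub["value"].values, index=sub["sample_id"].values)

    def metric_for(self, drug: str) -> str:
        sub = self.records[self.records["drug_id"] == drug]
        if sub.empty:
            raise KeyError(f"unknown drug {drug!r}")
        return sub["metric"].iloc[0]


def read_drug_response(path) -> DrugResponseTable:
    return DrugResponseTable(pd.read_csv(path, sep="\t"))


def write_drug_response(d: DrugResponseTable, path) -> None:
    d.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signature
# ---------------------------------------------------------------------------

@dataclass
class Signature:
    """A drug-sensitivity gene signature: gene -> signed weight.

    Weights are mean log2 fold changes (responders minus non-responders)
    over the resampling iterations in which the gene qualified.  The
    thresholds that produced the signature and its training ROC AUC travel
    with it so a serialized signature is self-describing.
    """

    weights: pd.Series
    thresholds: tuple[float, float, float] | None = None
    training_auc: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.weights, pd.Series):
            self.weights = pd.Series(self.weights, dtype=float)
        self.weights = self.weights.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.weights.index

    def __len__(self) -> int:
        return len(self.weights)

    def validate(self) -> None:
        """Enforce the invariants of a *selected* (final) signature."""
        if len(self.weights) == 0:
            raise ValueError("signature has no genes")
        if self.weights.index.has_duplicates:
            raise ValueError("signature has duplicate genes")
        if (self.weights == 0).any():
            raise ValueError("signature contains zero weights")
        if self.training_auc is not None and not (
            0.5 <= self.training_auc <= 1.0
        ):
            raise ValueError(
                f"training AUC {self.training_auc} outside [0.5, 1]"
            )

    def to_dict(self) -> dict:
        d = {
            "weights": {str(g): float(w) for g, w in self.weights.items()},
            "training_auc": self.training_auc,
            "provenance": dict(self.provenance),
        }
        if self.thresholds is not None:
            p, fc, cons = self.thresholds
            d["thresholds"] = {
                "p_value": float(p),
                "fold_change": float(fc),
                "conservation": float(cons),
            }
        else:
            d["thresholds"] = None
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Signature":
        for key in ("weights",):
            if key not in d:
                raise SchemaError(f"signature JSON missing field {key!r}")
        thr = d.get("thresholds")
        thresholds = None
        if thr is not None:
            for key in ("p_value", "fold_change", "conservation"):
                if key not in thr:
                    raise SchemaError(f"signature thresholds missing {key!r}")
            thresholds = (thr["p_value"], thr["fold_change"], thr["conservation"])
        return cls(
            weights=pd.Series(d["weights"], dtype=float),
            thresholds=thresholds,
            training_auc=d.get("training_auc"),
            provenance=dict(d.get("provenance") or {}),
        )


def write_signature(sig: Signature, path, tsv_sidecar: bool = True) -> None:
    """Write a signature as JSON (canonical), plus a gene/weight TSV export."""
    sig.validate()
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(sig.to_dict(), fh, indent=2)
        fh.write("\n")
    if tsv_sidecar:
        tsv = path.with_suffix(".tsv")
        sig.weights.rename("weight").to_csv(tsv, sep="\t", index_label="gene_id")


def read_signature(path) -> Signature:
    try:
        with open(path) as fh:
            d = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(d, dict):
        raise SchemaError(f"{path}: expected a JSON object")
    return Signature.from_dict(d)


# ---------------------------------------------------------------------------
# SurvivalTable
# ---------------------------------------------------------------------------

@dataclass
class SurvivalTable:
    """Per-patient follow-up records.

    ``data`` columns: ``time`` (>0, unit recorded in ``time_unit``),
    ``event`` (1 = event, 0 = censored), ``score`` (signature score), plus
    optional ordinal covariates such as ``stage`` and ``grade``.  Index is
    the patient id.
    """

    data: pd.DataFrame
    time_unit: str = "days"

    def __post_init__(self):
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise SchemaError(f"survival table missing column {col!r}")
        t = self.data["time"].to_numpy(dtype=float)
        if not (t > 0).all():
            raise ValueError("survival times must be strictly positive")
        ev = self.data["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]


def read_survival(path, time_unit: str = "days") -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    if "id" in df.columns:
        df = df.set_index("id")
    return SurvivalTable(df, time_unit=time_unit)


def write_survival(s: SurvivalTable, path) -> None:
    s.data.to_csv(path, sep="\t", index_label="id")
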