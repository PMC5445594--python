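"""The resampling engine: half-panel draws, responder calls, per-gene DE.

Each iteration draws a fraction (default 50%) of the cell lines that have
both expression and response data, derives responder / non-responder labels
(single- or dual-drug rule), and computes a per-gene two-sided Welch
unequal-variance t-test between the two groups together with the log2 fold
change (mean in responders minus mean in non-responders).  Repeating this
over hundreds of random subsamples yields one differential-expression list
per iteration; the downstream grid search consumes how *conserved* each
gene's alteration is across those lists.

No multiple-testing correction is applied inside iterations: the
conservation-fraction mechanism is the filter, so per-gene FDR is
deliberately absent.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, DrugResponseTable
from .errors import ConfigurationError, GroupTooSmallError
from .response_classification import (
    SensitivityCalls,
    call_dual,
    call_single,
    zscore_sensitivity,
    zscore_values,
)

logger = logging.getLogger(__name__)

MIN_GROUP_SIZE = 5


@dataclass
class ResamplingArchive:
    """Per-iteration, per-gene differential-expression statistics.

    ``pvals`` and ``log2fc`` are (n_iterations x n_genes) arrays over a
    shared gene universe; iterations that failed the minimum-group-size
    precondition are not stored, only counted in ``skipped``.
    """

    genes: pd.Index
    pvals: np.ndarray
    log2fc: np.ndarray
    n_resp: np.ndarray
    n_nonresp: np.ndarray
    skipped: int = 0
    seed: int | None = None
    fraction: float = 0.5
    drugs: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.genes = pd.Index(self.genes)
        self.pvals = np.asarray(self.pvals, dtype=float)
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        if self.pvals.shape != self.log2fc.shape:
            raise ValueError("pvals and log2fc shapes differ")
        if self.pvals.shape[1] != len(self.genes):
            raise ValueError("gene universe does not match statistics width")

    @property
    def n_iterations(self) -> int:
        return self.pvals.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n_iter, n_genes = self.pvals.shape
        return pd.DataFrame(
            {
                "iteration": np.repeat(np.arange(n_iter), n_genes),
                "gene_id": np.tile(self.genes.to_numpy(), n_iter),
                "p_value": self.pvals.ravel(),
                "log2_fc": self.log2fc.ravel(),
            }
        )

    def save(self, path) -> None:
        """Long-format TSV (iteration, gene, p, log2_fc), gzipped for .gz paths."""
        path = Path(path)
        frame = self.to_frame()
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            fh.write(f"# skipped={self.skipped} seed={self.seed} "
                     f"fraction={self.fraction} drugs={','.join(self.drugs)}\n")
            frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "ResamplingArchive":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            header = fh.readline().strip()
            frame = pd.read_csv(fh, sep="\t")
        meta = {}
        if header.startswith("#"):
            for tok in header[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = v
        genes = pd.Index(frame.loc[frame["iteration"] == 0, "gene_id"])
        n_iter = frame["iteration"].nunique()
        pvals = frame["p_value"].to_numpy().reshape(n_iter, len(genes))
        fc = frame["log2_fc"].to_numpy().reshape(n_iter, len(genes))
        return cls(
            genes=genes,
            pvals=pvals,
            log2fc=fc,
            n_resp=np.zeros(n_iter, dtype=int),
            n_nonresp=np.zeros(n_iter, dtype=int),
            skipped=int(meta.get("skipped", 0)),
            seed=int(meta["seed"]) if meta.get("seed", "None") != "None" else None,
            fraction=float(meta.get("fraction", 0.5)),
            drugs=tuple(d for d in meta.get("drugs", "").split(",") if d),
        )


def differential_expression(
    m: ExpressionMatrix,
    calls: SensitivityCalls,
    min_group_size: int = MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """Welch t-test and log2 fold change, responders vs non-responders.

    Returns a DataFrame indexed by gene with columns ``p_value`` and
    ``log2_fc`` (mean log2 expression in responders minus non-responders;
    the fold change as a ratio is ``2**log2_fc``).  "Neither" samples are
    excluded.  Raises :class:`GroupTooSmallError` — the iteration-skip
    signal — if either group is below ``min_group_size``.
    """
    resp = calls.responders.intersection(m.sample_ids)
    nonresp = calls.non_responders.intersection(m.sample_ids)
    if len(resp) < min_group_size or len(nonresp) < min_group_size:
        raise GroupTooSmallError(
            f"{len(resp)} responders / {len(nonresp)} non-responders; "
            f"need {min_group_size} of each"
        )
    a = m.values[list(resp)].to_numpy(dtype=float)
    b = m.values[list(nonresp)].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    fc = a.mean(axis=1) - b.mean(axis=1)
    # zero within-group variance: t is 0/0; identical means -> p = 1,
    # separated constant groups -> p at the floor
    p = np.where(np.isnan(p), np.where(fc == 0, 1.0, np.finfo(float).tiny), p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"p_value": p, "log2_fc": fc}, index=m.gene_ids)


def run_resampling(
    m: ExpressionMatrix,
    d: DrugResponseTable,
    drugs: tuple[str, ...],
    iterations: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
    min_group_size: int = MIN_GROUP_SIZE,
    exclude_samples=None,
    log_ic50: bool = True,
    zscore_per_iteration: bool = False,
) -> ResamplingArchive:
    """Run the full resampling loop and collect per-iteration statistics.

    The candidate pool is every cell line with expression and response data
    for all requested drugs, minus ``exclude_samples`` (held-out test ids
    are removed *before* any sampling).  Samples are canonically sorted
    before the RNG is applied, so results do not depend on input file
    ordering.  Each iteration draws ``floor(fraction * n)`` lines uniformly
    without replacement; iterations whose responder or non-responder group
    falls below ``min_group_size`` are skipped and counted.

    By default drug z-scores are computed once on the full candidate pool
    and labels follow each subsample from there (classification precedes
    iteration); ``zscore_per_iteration`` instead re-standardizes within
    every subsample.
    """
    if len(drugs) not in (1, 2):
        raise ValueError("provide one or two drug ids")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")

    raw_values = {}
    pool = pd.Index(m.sample_ids)
    for drug in drugs:
        vals = d.values_for(drug)
        if d.metric_for(drug) == "ic50" and log_ic50:
            vals = np.log(vals.astype(float))
        raw_values[drug] = vals
        pool = pool.intersection(vals.index)
    if exclude_samples is not None:
        pool = pool.difference(pd.Index(exclude_samples))
    pool = pd.Index(sorted(pool))  # canonical order before seeding
    n_draw = int(np.floor(fraction * len(pool)))
    if n_draw < 2 * min_group_size:
        raise ConfigurationError(
            f"subsample size {n_draw} cannot contain two groups of {min_group_size}"
        )

    panel_z = None
    if not zscore_per_iteration:
        panel_z = {drug: zscore_values(raw_values[drug].loc[pool]) for drug in drugs}

    rng = np.random.default_rng(seed)
    pvals, fcs, n_r, n_n = [], [], [], []
    skipped = 0
    for _ in range(iterations):
        chosen = pool[np.sort(rng.choice(len(pool), size=n_draw, replace=False))]
        if zscore_per_iteration:
            zs = [zscore_values(raw_values[drug].loc[chosen]) for drug in drugs]
        else:
            zs = [panel_z[drug].loc[chosen] for drug in drugs]
        if len(drugs) == 1:
            calls = call_single(zs[0], drug=drugs[0])
        else:
            calls = call_dual(zs[0], zs[1], drugs=(drugs[0], drugs[1]))
        try:
            # calls only cover the drawn samples, so the full matrix can be
            # passed: differential_expression selects columns by label
            de = differential_expression(m, calls, min_group_size=min_group_size)
        except GroupTooSmallError:
            skipped += 1
            continue
        pvals.append(de["p_value"].to_numpy())
        fcs.append(de["log2_fc"].to_numpy())
        n_r.append(len(calls.responders))
        n_n.append(len(calls.non_responders))

    if not pvals:
        raise ConfigurationError(
            "every iteration was skipped: too few responders per subsample; "
            "lower min_group_size, raise fraction, or pick another drug"
        )
    if skipped:
        logger.info("run_resampling: skipped %d/%d iterations", skipped, iterations)
    return ResamplingArchive(
        genes=m.gene_ids,
        pvals=np.vstack(pvals),
        log2fc=np.vstack(fcs),
        n_resp=np.asarray(n_r, dtype=int),
        n_nonresp=np.asarray(n_n, dtype=int),
        skipped=skipped,
        seed=seed,
        fraction=fraction,
        drugs=tuple(drugs),
        metadata={"pool_size": len(pool), "n_draw": n_draw},
    )
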