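"""Array preprocessing: low-signal filtering, quantile normalization,
probe-to-gene aggregation.

The pipeline order is filter -> normalize -> aggregate.  All operations
act on log2 intensities.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import ExpressionMatrix

log = logging.getLogger(__name__)


def filter_low_signal(matrix: ExpressionMatrix,
                      floor: float | None = None,
                      min_fraction: float = 0.75) -> ExpressionMatrix:
    """Drop probes/genes without acceptable signal in most replicates.

    A row is retained if, within at least one condition, its value exceeds
    ``floor`` in at least ``min_fraction`` of that condition's replicates.
    ``floor`` defaults to the 1st percentile of all intensities.  Row order
    is preserved.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    vals = matrix.values
    if floor is None:
        floor = float(np.percentile(vals.to_numpy(), 1))
    above = vals.gt(floor)
    keep = pd.Series(False, index=vals.index)
    for cond in matrix.design["condition"].unique():
        samples = matrix.samples_for(cond)
        keep |= above[samples].mean(axis=1) >= min_fraction
    if not keep.any():
        warnings.warn("low-signal filter removed every row", stacklevel=2)
    log.info("low-signal filter: kept %d / %d rows (floor=%.3g, min_fraction=%.2f)",
             int(keep.sum()), len(keep), floor, min_fraction)
    return ExpressionMatrix(vals.loc[keep], matrix.design, matrix.probe_to_gene)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize intensities across arrays.

    Every column is mapped onto the common reference distribution given by
    the row means of the column-sorted matrix, preserving within-column
    ranks.  Tied values within a column receive the mean of the reference
    values their positions span.
    """
    df = matrix.values
    x = df.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile normalization requires complete data "
                         "(missing values present; imputation out of scope)")
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    ref = np.sort(x, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        rmin = rankdata(x[:, j], method="min").astype(int)
        rmax = rankdata(x[:, j], method="max").astype(int)
        # mean of the reference values spanned by each (possibly tied) rank
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    return ExpressionMatrix(res, matrix.design, matrix.probe_to_gene)


def aggregate_probes(matrix: ExpressionMatrix,
                     probe_to_gene: pd.Series | dict | None = None) -> ExpressionMatrix:
    """Average probes mapping to the same gene (on the log2 scale).

    Unmapped probes are dropped with a logged count.  The result has one
    row per distinct mapped gene, gene symbols sorted.
    """
    if probe_to_gene is None:
        probe_to_gene = matrix.probe_to_gene
    if probe_to_gene is None or len(probe_to_gene) == 0:
        raise ValueError("probe-to-gene mapping is empty")
    mapping = pd.Series(probe_to_gene)
    genes = matrix.values.index.map(mapping)
    unmapped = genes.isna()
    if unmapped.any():
        log.info("aggregate_probes: dropping %d unmapped probes", int(unmapped.sum()))
    vals = matrix.values.loc[~unmapped]
    agg = vals.groupby(genes[~unmapped]).mean()
    agg.index.name = "gene_id"
    return ExpressionMatrix(agg, matrix.design)


def preprocess(matrix: ExpressionMatrix,
               floor: float | None = None,
               min_fraction: float = 0.75,
               normalize: bool = True,
               probe_to_gene=None) -> ExpressionMatrix:
    """Full preprocessing: low-signal filter, quantile normalization, and —
    when a probe map is available — probe-to-gene averaging."""
    m = filter_low_signal(matrix, floor=floor, min_fraction=min_fraction)
    if normalize:
        m = quantile_normalize(m)
    if probe_to_gene is not None or m.probe_to_gene is not None:
        m = aggregate_probes(m, probe_to_gene)
    m.assert_finite()
    return m
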