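"""Rank-product differential expression test with permutation pfp.

For a contrast with t treatment and c control replicates, every gene gets
K = t*c pairwise log2 fold changes.  Within each pairwise comparison genes
are ranked by fold change (rank 1 = most up-regulated for the ``up``
direction, most down-regulated for ``down``; ties get average ranks); the
rank product is the geometric mean of a gene's ranks across the K
comparisons.  Consistently extreme genes obtain small rank products.

Significance is assessed by permutation.  The default null shuffles the
expression values within each *array* (sample column) independently and
recomputes the pairwise ranks and rank products; because pairwise
comparisons share replicate arrays, their ranks are correlated, and the
array-wise shuffle preserves exactly that dependence.  For the observed
gene at sorted position k, the expected number of false positives is the
mean count of permuted rank products at or below the observed one, and

    pfp_k = E[FP at rank k] / k,

the permutation analogue of the FDR (percentage of false positives).
Monotonicity down the sorted list is enforced by a cumulative maximum and
values are capped at 1.

A second, comparison-wise null — shuffling values independently within
each pairwise comparison, i.e. assigning each gene an independent uniform
rank per comparison — ignores the shared-replicate dependence and is
anti-conservative for inference, but it is exactly enumerable: each
gene's null rank is marginally uniform on {1..n} and independent across
comparisons, so E[FP](x) = n * #{rank tuples with product <= x^K} / n^K.
It is provided as the ``exact`` mode for validating tiny instances
against exhaustive enumeration.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import Contrast, ExpressionMatrix

#: Enumerating the exact null is limited to n_genes**K of this size.
_EXACT_ENUM_LIMIT = 5_000_000


def pairwise_lfc(matrix: ExpressionMatrix, contrast: Contrast) -> pd.DataFrame:
    """Per-gene log2 fold change for every (treatment, control) replicate pair.

    Returns a DataFrame (genes x K) with columns ``"{treat}-{ctrl}"``;
    values are treatment minus control log2 intensity.
    """
    missing = [s for s in contrast.treatment_samples + contrast.control_samples
               if s not in matrix.values.columns]
    if missing:
        raise ValueError(f"contrast {contrast.name!r}: samples not in matrix: {missing}")
    cols, names = [], []
    vals = matrix.values
    for t in contrast.treatment_samples:
        for c in contrast.control_samples:
            cols.append(vals[t].to_numpy() - vals[c].to_numpy())
            names.append(f"{t}-{c}")
    return pd.DataFrame(np.column_stack(cols), index=vals.index, columns=names)


def _rank_matrix(lfc: np.ndarray, direction: str) -> np.ndarray:
    """Per-comparison ranks; rank 1 = most extreme in ``direction``."""
    signed = -lfc if direction == "up" else lfc
    ranks = np.empty_like(signed)
    for j in range(signed.shape[1]):
        col = signed[:, j]
        if np.ptp(col) == 0:
            warnings.warn(
                "constant pairwise comparison (all fold changes tied); "
                "average ranks applied", stacklevel=3)
        ranks[:, j] = rankdata(col, method="average")
    return ranks


def rank_product(matrix: ExpressionMatrix, contrast: Contrast,
                 direction: str) -> pd.Series:
    """Geometric-mean fold-change rank per gene for one direction."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    lfc = pairwise_lfc(matrix, contrast).to_numpy()
    ranks = _rank_matrix(lfc, direction)
    rp = np.exp(np.log(ranks).mean(axis=1))
    return pd.Series(rp, index=matrix.values.index, name=f"rp_{direction}")


def _exact_null_products(n_genes: int, k: int) -> np.ndarray:
    """Sorted products over all n^K per-comparison rank tuples."""
    if n_genes ** k > _EXACT_ENUM_LIMIT:
        raise ValueError(
            f"exact null enumeration infeasible: {n_genes}^{k} tuples")
    arr = np.arange(1, n_genes + 1, dtype=float)
    prod = arr.copy()
    for _ in range(k - 1):
        prod = np.multiply.outer(prod, arr).ravel()
    prod.sort()
    return prod


def _pfp_from_counts(obs_products: np.ndarray, gene_order_key: np.ndarray,
                     count_le) -> tuple[np.ndarray, np.ndarray]:
    """pfp per gene given a function counting expected null products <= x.

    ``count_le(sorted_obs) -> E[FP]`` per sorted observed product.  Genes
    are sorted by product ascending with a deterministic secondary key.
    Returns (pfp, efp) in original gene order.
    """
    order = np.lexsort((gene_order_key, obs_products))
    efp_sorted = count_le(obs_products[order])
    k = np.arange(1, len(obs_products) + 1)
    pfp_sorted = np.minimum(np.maximum.accumulate(efp_sorted / k), 1.0)
    pfp = np.empty_like(pfp_sorted)
    efp = np.empty_like(pfp_sorted)
    pfp[order] = pfp_sorted
    efp[order] = efp_sorted
    return pfp, efp


def _array_permutation_null(matrix: ExpressionMatrix, contrast: Contrast,
                            n_permutations: int, seed: int) -> dict:
    """Monte-Carlo null rank products from array-wise value shuffling.

    Each round permutes every array of the contrast independently, then
    recomputes all pairwise ranks; comparisons sharing a replicate array
    stay correlated, as in the observed statistics.  Null ranks are
    ordinal (ties in permuted values broken by sort order), and the down
    ranks are the exact complements of the up ranks, which makes the
    up/down symmetry under matrix negation exact.  Returns per-direction
    counting functions E[FP](sorted observed products).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tvals = matrix.values[list(contrast.treatment_samples)].to_numpy()
    cvals = matrix.values[list(contrast.control_samples)].to_numpy()
    n = tvals.shape[0]
    null = {"up": np.empty(n_permutations * n),
            "down": np.empty(n_permutations * n)}
    positions = np.arange(1, n + 1, dtype=float)
    for b in range(n_permutations):
        pt = [rng.permutation(n) for _ in range(tvals.shape[1])]
        pc = [rng.permutation(n) for _ in range(cvals.shape[1])]
        prod_up = np.ones(n)
        prod_down = np.ones(n)
        rank_up = np.empty(n)
        for i in range(tvals.shape[1]):
            t_col = tvals[pt[i], i]
            for j in range(cvals.shape[1]):
                pl = t_col - cvals[pc[j], j]
                rank_up[np.argsort(-pl)] = positions
                prod_up *= rank_up
                prod_down *= (n + 1) - rank_up
        null["up"][b * n:(b + 1) * n] = prod_up
        null["down"][b * n:(b + 1) * n] = prod_down

    counters = {}
    for direction in ("up", "down"):
        null[direction].sort()

        def count_le(sorted_obs, _null=null[direction], _b=n_permutations):
            return np.searchsorted(_null, sorted_obs, side="right") / _b

        counters[direction] = count_le
    return counters


def estimate_pfp(matrix: ExpressionMatrix, contrast: Contrast,
                 n_permutations: int = 100, seed: int = 0,
                 exact: bool = False) -> pd.DataFrame:
    """Rank-product test for both directions with permutation pfp.

    Parameters
    ----------
    n_permutations:
        Number of full permutation rounds (each shuffles the values of
        every array in the contrast independently).  Ignored when
        ``exact`` is True.
    exact:
        Enumerate the comparison-wise permutation null exhaustively
        (tiny validation instances only; see module docstring).
    seed:
        Seed of the permutation stream; results are deterministic given it.

    Returns
    -------
    DataFrame indexed by gene id with columns rp_up, rp_down, pfp_up,
    pfp_down, avg_lfc, n_comparisons, n_permutations, seed.
    """
    if not exact and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not exact and n_permutations < 20:
        warnings.warn(
            f"n_permutations={n_permutations} gives a coarse pfp resolution "
            f"of {1.0 / n_permutations:.3g} in expected false positives at the "
            "top rank; consider >= 100", stacklevel=2)

    lfc_df = pairwise_lfc(matrix, contrast)
    lfc = lfc_df.to_numpy()
    n, k = lfc.shape
    gene_ids = lfc_df.index.to_numpy()
    # secondary deterministic ordering on gene id for tied rank products
    gene_key = rankdata(gene_ids, method="ordinal")

    products = {}
    for direction in ("up", "down"):
        ranks = _rank_matrix(lfc, direction)
        products[direction] = ranks.prod(axis=1)

    if exact:
        null_sorted = _exact_null_products(n, k)
        total = float(len(null_sorted))

        def count_le(sorted_obs, _null=null_sorted, _total=total):
            return n * np.searchsorted(_null, sorted_obs, side="right") / _total

        counters = {"up": count_le, "down": count_le}
    else:
        counters = _array_permutation_null(matrix, contrast, n_permutations, seed)

    out = pd.DataFrame(index=lfc_df.index)
    for direction in ("up", "down"):
        pfp, _ = _pfp_from_counts(products[direction], gene_key, counters[direction])
        out[f"rp_{direction}"] = products[direction] ** (1.0 / k)
        out[f"pfp_{direction}"] = pfp
    out["avg_lfc"] = lfc.mean(axis=1)
    out["n_comparisons"] = k
    out["n_permutations"] = 0 if exact else n_permutations
    out["seed"] = seed
    return out
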