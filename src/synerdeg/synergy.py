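"""DEG thresholds, the synergy-effect statistic, and signature extraction.

A DEG passes both a significance threshold (pfp < 0.05) and an effect-size
threshold (|avg log2 FC| > 2) for a contrast.  Synergistic DEGs are
double-vs-mock DEGs that additionally pass pfp < 0.005 in the
double-vs-all contrast; the stricter variant further requires the synergy
effect

    SE = lfc_AB - (lfc_A + lfc_B)

to exceed 0 for up-regulated genes (fall below 0 for down-regulated ones).
Both filter variants are reported side by side.  The signature list keeps
up-regulated synergistic genes whose single-treatment responses are
minimal: each single's linear fold change must be below 25% of the double
treatment's.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def call_degs(result: pd.DataFrame, pfp_threshold: float = 0.05,
              lfc_threshold: float = 2.0, contrast: str = "") -> pd.DataFrame:
    """Select DEGs from a rank-product result table.

    A gene is an up-DEG if ``pfp_up < pfp_threshold`` and
    ``avg_lfc > lfc_threshold`` (strict), a down-DEG symmetrically.
    Rows are ordered by pfp ascending, then |avg_lfc| descending, then
    gene id; a gene appears at most once per direction.
    """
    if not 0 < pfp_threshold <= 1:
        raise ValueError("pfp_threshold must be in (0, 1]")
    if lfc_threshold < 0:
        raise ValueError("lfc_threshold must be >= 0")
    for col in ("pfp_up", "pfp_down", "avg_lfc"):
        if col not in result.columns:
            raise ValueError(f"result table missing column {col!r}")
    up = result.index[(result["pfp_up"] < pfp_threshold)
                      & (result["avg_lfc"] > lfc_threshold)]
    down = result.index[(result["pfp_down"] < pfp_threshold)
                        & (result["avg_lfc"] < -lfc_threshold)]
    rows = []
    for gene in up:
        rows.append((gene, contrast, "up",
                     result.at[gene, "avg_lfc"], result.at[gene, "pfp_up"]))
    for gene in down:
        rows.append((gene, contrast, "down",
                     result.at[gene, "avg_lfc"], result.at[gene, "pfp_down"]))
    deg = pd.DataFrame(rows, columns=["gene_id", "contrast", "direction",
                                      "avg_lfc", "pfp"])
    deg = deg.sort_values(["pfp", "avg_lfc", "gene_id"],
                          key=lambda s: -s.abs() if s.name == "avg_lfc" else s,
                          kind="mergesort").reset_index(drop=True)
    return deg


def synergy_effect(lfc_ab, lfc_a, lfc_b):
    """SE = log2 FC(double) - (log2 FC(A) + log2 FC(B)); vectorized."""
    return np.asarray(lfc_ab) - (np.asarray(lfc_a) + np.asarray(lfc_b))


def ratio_filter(lfc_a: float, lfc_b: float, lfc_ab: float,
                 threshold: float = 0.25, scale: str = "linear") -> bool:
    """Single/double fold-change ratio filter for up-regulated genes.

    On the default linear scale the fold changes are 2**lfc with
    single-treatment fold changes below 1 floored to 1 (a repressed single
    response contributes no up-regulation); the gene passes when both
    FC(A)/FC(AB) and FC(B)/FC(AB) are strictly below ``threshold``.
    ``scale="log2"`` compares max(lfc, 0)/lfc_ab instead.
    """
    if lfc_ab <= 0:
        raise ValueError("ratio filter is defined only for up-regulated genes "
                         f"(lfc_ab > 0 required, got {lfc_ab})")
    if scale == "linear":
        fc_ab = 2.0 ** lfc_ab
        ra = 2.0 ** max(lfc_a, 0.0) / fc_ab
        rb = 2.0 ** max(lfc_b, 0.0) / fc_ab
    elif scale == "log2":
        ra = max(lfc_a, 0.0) / lfc_ab
        rb = max(lfc_b, 0.0) / lfc_ab
    else:
        raise ValueError("scale must be 'linear' or 'log2'")
    return bool(ra < threshold and rb < threshold)


def _check_same_universe(tables: dict[str, pd.DataFrame]) -> None:
    names = list(tables)
    ref = set(tables[names[0]].index)
    for name in names[1:]:
        other = set(tables[name].index)
        if other != ref:
            only_ref = sorted(ref - other)[:10]
            only_other = sorted(other - ref)[:10]
            raise ValueError(
                f"gene universes differ between {names[0]!r} and {name!r}: "
                f"only in {names[0]!r}: {only_ref}; only in {name!r}: {only_other}")


def call_synergistic(deg_ab_vs_mock: pd.DataFrame,
                     rp_a: pd.DataFrame,
                     rp_b: pd.DataFrame,
                     rp_ab: pd.DataFrame,
                     rp_ab_vs_all: pd.DataFrame,
                     pfp_all_threshold: float = 0.005,
                     ratio_threshold: float = 0.25,
                     ratio_scale: str = "linear") -> pd.DataFrame:
    """Annotate double-vs-mock DEGs with synergy statistics and flags.

    Returns one row per DEG with per-contrast log2 fold changes, SE, the
    direction-matched double-vs-all pfp, the single/double fold-change
    ratios (up genes only) and three flags:

    ``synergistic_pfp_only``
        double-vs-all pfp < ``pfp_all_threshold``.
    ``synergistic``
        pfp filter plus the SE rule (SE>0 up / SE<0 down) — the stricter
        of the two reported filter variants.
    ``signature``
        synergistic, up-regulated, and passing the ratio filter.
    """
    if not 0 < pfp_all_threshold <= 1:
        raise ValueError("pfp_all_threshold must be in (0, 1]")
    _check_same_universe({"A_vs_mock": rp_a, "B_vs_mock": rp_b,
                          "AB_vs_mock": rp_ab, "AB_vs_all": rp_ab_vs_all})
    rows = []
    for _, deg in deg_ab_vs_mock.iterrows():
        g, direction = deg["gene_id"], deg["direction"]
        lfc_a = rp_a.at[g, "avg_lfc"]
        lfc_b = rp_b.at[g, "avg_lfc"]
        lfc_ab = rp_ab.at[g, "avg_lfc"]
        se = float(synergy_effect(lfc_ab, lfc_a, lfc_b))
        pfp_all = rp_ab_vs_all.at[g, f"pfp_{direction}"]
        syn_pfp = bool(pfp_all < pfp_all_threshold)
        se_ok = se > 0 if direction == "up" else se < 0
        syn = syn_pfp and se_ok
        if direction == "up" and lfc_ab > 0:
            fc_ab = 2.0 ** lfc_ab
            ratio_a = 2.0 ** max(lfc_a, 0.0) / fc_ab
            ratio_b = 2.0 ** max(lfc_b, 0.0) / fc_ab
            sig = syn and ratio_filter(lfc_a, lfc_b, lfc_ab,
                                       threshold=ratio_threshold,
                                       scale=ratio_scale)
        else:
            ratio_a = ratio_b = np.nan
            sig = False
        rows.append((g, direction, lfc_a, lfc_b, lfc_ab, se,
                     deg["pfp"], pfp_all, ratio_a, ratio_b,
                     syn_pfp, syn, sig))
    return pd.DataFrame(rows, columns=[
        "gene_id", "direction", "lfc_a", "lfc_b", "lfc_ab", "se",
        "pfp_ab_vs_mock", "pfp_ab_vs_all", "ratio_a", "ratio_b",
        "synergistic_pfp_only", "synergistic", "signature"])


def extract_signature(synergy_table: pd.DataFrame) -> pd.DataFrame:
    """Up-regulated synergistic genes passing the ratio filter, ranked by
    double-treatment log2 fold change descending."""
    if len(synergy_table) == 0:
        warnings.warn("empty synergy table; signature is empty", stacklevel=2)
        return synergy_table.copy()
    sig = synergy_table[synergy_table["signature"]]
    return (sig.sort_values(["lfc_ab", "gene_id"], ascending=[False, True],
                            kind="mergesort")
            .reset_index(drop=True))
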