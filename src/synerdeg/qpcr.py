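"""qPCR ΔΔCt quantification and ChIP-qPCR percent-of-input enrichment.

Fold changes are computed by the comparative Ct method: the target Ct is
normalized to the arithmetic mean of the reference-gene Cts of the same
sample (equivalent to geometric-mean normalization on the linear scale,
amplification efficiency assumed 2.0), then to the mock condition:

    ΔCt  = Ct_target - mean(Ct_references)
    ΔΔCt = ΔCt_condition - ΔCt_mock
    FC   = 2**(-ΔΔCt)

ChIP enrichment is expressed as percent of input chromatin:

    % input = 100 * input_fraction * 2**(ct_input - ct_ip)

where ``input_fraction`` is the fraction of chromatin kept as input and
``ct_input`` is measured on that (diluted) input aliquot — the factor
``input_fraction`` is exactly the -log2(input_fraction) dilution
adjustment of the input Ct.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class MissingReferenceError(ValueError):
    """Raised when a sample lacks reference-gene measurements."""


def _delta_ct(table: pd.DataFrame, target: str,
              reference_genes: list[str] | None) -> pd.DataFrame:
    """Per-sample ΔCt (target Ct minus mean reference Ct)."""
    if reference_genes is None:
        reference_genes = sorted(table.loc[table["role"] == "reference",
                                           "gene_id"].unique())
    if not reference_genes:
        raise MissingReferenceError("no reference genes in table")
    rows = []
    for sample, sub in table.groupby("sample_id", sort=True):
        refs = sub[sub["gene_id"].isin(reference_genes)]
        if set(reference_genes) - set(refs["gene_id"]):
            missing = sorted(set(reference_genes) - set(refs["gene_id"]))
            raise MissingReferenceError(
                f"sample {sample!r} is missing reference gene(s) {missing}")
        tgt = sub[sub["gene_id"] == target]
        if len(tgt) == 0:
            continue
        rows.append((sample, sub["condition"].iloc[0],
                     float(tgt["ct"].mean() - refs["ct"].mean())))
    if not rows:
        raise ValueError(f"target {target!r} not measured in any sample")
    return pd.DataFrame(rows, columns=["sample_id", "condition", "delta_ct"])


def ddct_fold_change(table: pd.DataFrame, target: str, condition: str,
                     mock_label: str = "mock",
                     reference_genes: list[str] | None = None) -> dict:
    """ΔΔCt fold change of ``target`` in ``condition`` relative to mock.

    The mock baseline is the mean ΔCt over mock replicates; each condition
    replicate yields its own fold change, and the dispersion reported is
    the standard deviation of those per-replicate fold changes.

    Returns a dict with ``fold_change`` (mean), ``sd``, ``n`` and the
    per-replicate ``fold_changes``.
    """
    dct = _delta_ct(table, target, reference_genes)
    mock = dct.loc[dct["condition"] == mock_label, "delta_ct"]
    cond = dct.loc[dct["condition"] == condition, "delta_ct"]
    if len(mock) == 0:
        raise ValueError(f"no mock ({mock_label!r}) samples for target {target!r}")
    if len(cond) == 0:
        raise ValueError(f"no {condition!r} samples for target {target!r}")
    ddct = cond.to_numpy() - mock.mean()
    fcs = 2.0 ** (-ddct)
    return {
        "target": target,
        "condition": condition,
        "fold_change": float(fcs.mean()),
        "sd": float(fcs.std(ddof=1)) if len(fcs) > 1 else 0.0,
        "n": int(len(fcs)),
        "fold_changes": fcs,
    }


def ddct_table(table: pd.DataFrame, mock_label: str = "mock",
               reference_genes: list[str] | None = None) -> pd.DataFrame:
    """ΔΔCt fold changes for every (target, non-mock condition) pair."""
    targets = sorted(table.loc[table["role"] == "target", "gene_id"].unique())
    conditions = [c for c in table["condition"].unique() if c != mock_label]
    rows = []
    for t in targets:
        for c in conditions:
            r = ddct_fold_change(table, t, c, mock_label=mock_label,
                                 reference_genes=reference_genes)
            rows.append((t, c, r["fold_change"], r["sd"], r["n"]))
    return pd.DataFrame(rows, columns=["gene_id", "condition",
                                       "fold_change", "sd", "n"])


def percent_input(ct_ip: float, ct_input: float, input_fraction: float,
                  input_is_diluted: bool = True) -> float:
    """ChIP enrichment as percent of input.

    ``input_fraction`` is the fraction of chromatin used as input (no
    default: assay-specific).  With ``input_is_diluted`` (default) the
    input Ct is taken to be measured on that diluted aliquot and the
    dilution correction is applied; otherwise ``ct_input`` is assumed
    already adjusted to the full-chromatin equivalent.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    if input_is_diluted:
        return 100.0 * input_fraction * 2.0 ** (ct_input - ct_ip)
    return 100.0 * 2.0 ** (ct_input - ct_ip)


def percent_input_table(table: pd.DataFrame,
                        input_is_diluted: bool = True) -> pd.DataFrame:
    """Percent input per (region, antibody, condition): mean, sd, n over
    replicates.  Expects columns region_id, antibody, condition, ct_ip,
    ct_input, input_fraction, replicate."""
    pct = np.array([
        percent_input(r.ct_ip, r.ct_input, r.input_fraction, input_is_diluted)
        for r in table.itertuples()
    ])
    work = table.assign(percent_input=pct)
    out = (work.groupby(["region_id", "antibody", "condition"], sort=True)
           ["percent_input"]
           .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
                n="size")
           .reset_index())
    return out
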