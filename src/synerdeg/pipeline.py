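"""End-to-end orchestration: simulate (or load) -> preprocess -> rank-product
tests -> DEG/synergy calling -> signature, with deterministic outputs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .core import ExpressionMatrix, standard_contrasts
from .preprocess import preprocess
from .rankprod import estimate_pfp
from .simulate import SimConfig, generate_factorial
from .synergy import call_degs, call_synergistic, extract_signature

log = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``sim`` (a :class:`~synerdeg.simulate.SimConfig`) or
    ``matrix_path``/``design_path`` must be provided.  Thresholds default
    to the study values: DEG pfp < 0.05, |log2 FC| > 2, double-vs-all
    pfp < 0.005, single/double fold-change ratio < 0.25.
    """

    sim: SimConfig | None = None
    matrix_path: str | None = None
    design_path: str | None = None
    probe_map_path: str | None = None
    pfp_deg: float = 0.05
    lfc_threshold: float = 2.0
    pfp_synergy: float = 0.005
    ratio_threshold: float = 0.25
    ratio_scale: str = "linear"
    n_permutations: int = 100
    seed: int = 0
    normalize: bool = True
    low_signal_floor: float | None = None
    low_signal_min_fraction: float = 0.75
    outdir: str | None = None

    def validate(self) -> None:
        has_sim = self.sim is not None
        has_paths = self.matrix_path is not None
        if has_sim == has_paths:
            raise ValueError("provide either a simulation block or input paths, not both")
        if has_paths and self.design_path is None:
            raise ValueError("matrix_path requires design_path")
        for name in ("pfp_deg", "lfc_threshold", "pfp_synergy", "ratio_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    rankprod: dict[str, pd.DataFrame]
    degs: dict[str, pd.DataFrame]
    synergy: pd.DataFrame
    signature: pd.DataFrame
    truth: pd.DataFrame | None
    metadata: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; writes TSV/JSON outputs when ``outdir`` is set.

    Identical config + seed give byte-identical outputs.
    """
    config.validate()
    meta: dict = {"version": __version__, "seed": config.seed,
                  "thresholds": {"pfp_deg": config.pfp_deg,
                                 "lfc": config.lfc_threshold,
                                 "pfp_synergy": config.pfp_synergy,
                                 "ratio": config.ratio_threshold},
                  "n_permutations": config.n_permutations,
                  "stage_counts": {}}

    truth = None
    if config.sim is not None:
        matrix, truth, sim_meta = generate_factorial(config.sim)
        meta["simulation"] = sim_meta
    else:
        matrix = io.read_expression_tsv(config.matrix_path, config.design_path)
        if config.probe_map_path:
            matrix.probe_to_gene = io.read_probe_map_tsv(config.probe_map_path)
    meta["stage_counts"]["input_genes"] = matrix.n_genes
    log.info("input: %d genes, %d samples", matrix.n_genes, len(matrix.sample_ids))

    matrix = preprocess(matrix, floor=config.low_signal_floor,
                        min_fraction=config.low_signal_min_fraction,
                        normalize=config.normalize)
    meta["stage_counts"]["after_preprocessing"] = matrix.n_genes
    log.info("after preprocessing: %d genes", matrix.n_genes)

    contrasts = standard_contrasts(matrix)
    # derive a deterministic per-contrast permutation seed from the master seed
    seed_rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    rp = {}
    for name in ("A_vs_mock", "B_vs_mock", "AB_vs_mock", "AB_vs_all"):
        sub_seed = int(seed_rng.integers(0, 2**31 - 1))
        rp[name] = estimate_pfp(matrix, contrasts[name],
                                n_permutations=config.n_permutations,
                                seed=sub_seed)

    degs = {}
    for name in ("A_vs_mock", "B_vs_mock", "AB_vs_mock"):
        degs[name] = call_degs(rp[name], pfp_threshold=config.pfp_deg,
                               lfc_threshold=config.lfc_threshold, contrast=name)
        meta["stage_counts"][f"degs_{name}_up"] = int((degs[name]["direction"] == "up").sum())
        meta["stage_counts"][f"degs_{name}_down"] = int((degs[name]["direction"] == "down").sum())
        log.info("%s: %d DEGs", name, len(degs[name]))

    synergy = call_synergistic(degs["AB_vs_mock"], rp["A_vs_mock"], rp["B_vs_mock"],
                               rp["AB_vs_mock"], rp["AB_vs_all"],
                               pfp_all_threshold=config.pfp_synergy,
                               ratio_threshold=config.ratio_threshold,
                               ratio_scale=config.ratio_scale)
    for direction in ("up", "down"):
        d = synergy["direction"] == direction
        meta["stage_counts"][f"synergistic_pfp_only_{direction}"] = int(
            (synergy["synergistic_pfp_only"] & d).sum())
        meta["stage_counts"][f"synergistic_se_{direction}"] = int(
            (synergy["synergistic"] & d).sum())
    signature = extract_signature(synergy) if len(synergy) else synergy.iloc[0:0]
    meta["stage_counts"]["signature"] = len(signature)
    log.info("synergistic (SE rule): %d up / %d down; signature: %d genes",
             meta["stage_counts"]["synergistic_se_up"],
             meta["stage_counts"]["synergistic_se_down"], len(signature))

    result = PipelineResult(matrix=matrix, rankprod=rp, degs=degs,
                            synergy=synergy, signature=signature,
                            truth=truth, metadata=meta)
    if config.outdir:
        _write_bundle(result, config)
    return result


def _write_bundle(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = {"version": __version__, "seed": config.seed,
              "n_permutations": config.n_permutations,
              "pfp_deg": config.pfp_deg, "lfc_threshold": config.lfc_threshold,
              "pfp_synergy": config.pfp_synergy,
              "ratio_threshold": config.ratio_threshold}
    io.write_expression_tsv(result.matrix, out / "expression_preprocessed.tsv",
                            out / "design.tsv")
    for name, df in result.rankprod.items():
        io.write_table_tsv(df.reset_index(), out / f"rankprod_{name}.tsv", header)
    for name, df in result.degs.items():
        io.write_table_tsv(df, out / f"degs_{name}.tsv", header)
    io.write_table_tsv(result.synergy, out / "synergy_table.tsv", header)
    io.write_table_tsv(result.signature, out / "signature_table.tsv", header)
    io.write_signature_txt(result.signature["gene_id"], out / "signature.txt")
    if result.truth is not None:
        io.write_table_tsv(result.truth, out / "ground_truth.tsv", header)
    io.write_metadata_json(result.metadata, out / "run_metadata.json")
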