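"""Tab-separated I/O for expression matrices, designs, probe maps, Ct tables
and result tables.  All files are TSV, UTF-8, LF line endings; result tables
carry a ``#`` header comment block recording thresholds and seeds."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import CONDITIONS, DesignError, ExpressionMatrix


def write_expression_tsv(matrix: ExpressionMatrix, matrix_path, design_path) -> None:
    """Write matrix (first column gene_id) and design (sample_id, condition,
    replicate) as TSV."""
    df = matrix.values.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(matrix_path, sep="\t", lineterminator="\n")
    matrix.design.reset_index().to_csv(design_path, sep="\t", index=False,
                                       lineterminator="\n")


def read_design_tsv(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "condition", "replicate"}
    if not required <= set(design.columns):
        raise DesignError(f"design file {path} must have columns {sorted(required)}")
    bad = set(design["condition"]) - set(CONDITIONS)
    if bad:
        raise DesignError(f"design file {path}: unknown conditions {sorted(bad)}")
    return design.set_index("sample_id")


def read_expression_tsv(path, design_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus its design; validates that sample ids
    match and gene ids are unique."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    design = read_design_tsv(design_path)
    missing = [s for s in df.columns if s not in design.index]
    extra = [s for s in design.index if s not in df.columns]
    if missing or extra:
        raise DesignError(
            f"sample mismatch between {path} and {design_path}: "
            f"matrix-only samples {missing}; design-only samples {extra}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DesignError(f"duplicate gene ids in {path}: {dups[:10]}")
    return ExpressionMatrix(df, design)


def read_probe_map_tsv(path) -> pd.Series:
    """Two-column TSV probe_id, gene_symbol -> Series probe_id -> gene."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"probe map {path} needs two columns (probe_id, gene)")
    return df.set_index(df.columns[0])[df.columns[1]]


def read_ct_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table_tsv(df: pd.DataFrame, path, metadata: dict | None = None,
                    index: bool = False) -> None:
    """Write a result table with a ``# key: value`` comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def write_signature_txt(gene_ids, path) -> None:
    """Plain one-gene-per-line signature list."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in gene_ids:
            fh.write(f"{g}\n")


def write_metadata_json(metadata: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
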