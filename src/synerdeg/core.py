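"""Core containers: expression matrices with factorial design metadata, and contrasts.

The experimental design modelled throughout the package is a two-factor
factorial: untreated cells (``mock``), each single treatment (``A``, ``B``)
and the double treatment (``AB``), with biological replicates per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four conditions of the factorial design.
CONDITIONS = ("mock", "A", "B", "AB")


class DesignError(ValueError):
    """Raised when an expression matrix and its design metadata disagree."""


@dataclass
class ExpressionMatrix:
    """A genes(or probes) x samples table of log2 intensities plus design metadata.

    Parameters
    ----------
    values:
        DataFrame indexed by gene/probe id, one column per sample, log2 scale.
    design:
        DataFrame indexed by sample id with columns ``condition`` (one of
        :data:`CONDITIONS`) and ``replicate`` (integer replicate index).
    probe_to_gene:
        Optional Series mapping probe id -> gene symbol, for probe-level input.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    probe_to_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DesignError(f"duplicate gene/probe ids: {dups[:10]}")
        if self.values.columns.has_duplicates:
            raise DesignError("duplicate sample ids in matrix columns")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise DesignError(f"samples missing from design: {missing}")
        extra = [s for s in self.design.index if s not in self.values.columns]
        if extra:
            raise DesignError(f"design samples missing from matrix: {extra}")
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise DesignError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in design order."""
        sel = self.design.index[self.design["condition"] == condition]
        return [s for s in sel]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[gene_ids], self.design,
                                self.probe_to_gene)

    def assert_finite(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")


@dataclass
class Contrast:
    """A treatment-vs-control comparison defined by two disjoint sample sets."""

    name: str
    treatment_samples: list[str]
    control_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.treatment_samples or not self.control_samples:
            raise ValueError(f"contrast {self.name!r}: both sample sets must be non-empty")
        overlap = set(self.treatment_samples) & set(self.control_samples)
        if overlap:
            raise ValueError(
                f"contrast {self.name!r}: treatment/control overlap {sorted(overlap)}")

    @property
    def n_comparisons(self) -> int:
        return len(self.treatment_samples) * len(self.control_samples)


def standard_contrasts(matrix: ExpressionMatrix) -> dict[str, Contrast]:
    """The four contrasts of the factorial analysis.

    Each treatment is compared to mock, and the double treatment is
    additionally compared against the pool of all remaining samples
    (single treatments plus mock) — the "double vs all" contrast used as
    the extra synergy filter.
    """
    mock = matrix.samples_for("mock")
    a = matrix.samples_for("A")
    b = matrix.samples_for("B")
    ab = matrix.samples_for("AB")
    return {
        "A_vs_mock": Contrast("A_vs_mock", a, mock),
        "B_vs_mock": Contrast("B_vs_mock", b, mock),
        "AB_vs_mock": Contrast("AB_vs_mock", ab, mock),
        "AB_vs_all": Contrast("AB_vs_all", ab, a + b + mock),
    }
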