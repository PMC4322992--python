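"""Synthetic factorial expression data with known ground truth.

The generator emulates a single-colour microarray experiment with four
conditions (mock, single treatment A, single treatment B, double treatment
AB) and replicated arrays, producing a log2-intensity matrix together with
a ground-truth table of planted per-gene effects.  Planted gene classes
mirror the response patterns a two-factor synergy analysis must
distinguish:

``null``
    no response in any condition.
``a_only`` / ``b_only``
    respond to one single treatment; the double treatment reproduces that
    single response (no interaction, true synergy effect exactly 0).
``additive``
    respond to both singles; the double response is exactly the sum of the
    two single responses (true synergy effect exactly 0).
``synergistic_up`` / ``synergistic_down``
    double response exceeds (falls short of) the sum of singles, with at
    least one single treatment itself strongly responsive — so these genes
    are synergistic but *not* "minimally single-responsive".
``signature_like``
    strongly double-responsive but minimally responsive to either single:
    by construction both linear-scale single/double fold-change ratios are
    below 0.25, the signature filter.
``low_signal``
    flat genes near the detection floor, for exercising the low-signal
    preprocessing filter (default fraction 0).

Also provides generators for qPCR and ChIP-qPCR Ct tables with known
fold changes / percent-input enrichments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import ExpressionMatrix

GENE_CLASSES = (
    "null",
    "a_only",
    "b_only",
    "additive",
    "synergistic_up",
    "synergistic_down",
    "signature_like",
    "low_signal",
)

DEFAULT_CLASS_FRACTIONS = {
    "null": 0.90,
    "a_only": 0.0025,
    "b_only": 0.0025,
    "additive": 0.005,
    "synergistic_up": 0.025,
    "synergistic_down": 0.045,
    "signature_like": 0.02,
    "low_signal": 0.0,
}

# log2 effect-size ranges by role within each planted class construction.
DEFAULT_EFFECT_RANGES = {
    # a_only / b_only: the single-treatment response magnitude (sign random)
    "single": (3.0, 5.0),
    # additive: each single's response magnitude (shared sign; double = sum)
    "additive_single": (1.5, 1.8),
    # synergistic: one strong single, one weak single, plus an interaction excess
    "synergy_strong_single": (2.2, 2.7),
    "synergy_weak_single": (0.5, 0.85),
    "synergy_excess": (0.5, 0.85),
    # signature_like: near-silent singles, strong double response
    "signature_single": (0.0, 0.5),
    "signature_double": (3.0, 5.0),
}


class ConfigurationError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass
class SimConfig:
    """Configuration of the factorial simulator.

    Parameters
    ----------
    n_genes:
        Number of genes in the matrix.
    class_fractions:
        Map gene class -> proportion; non-negative, summing to 1 (1e-9 tol).
        Counts are obtained by the largest-remainder rounding rule, ties
        broken in :data:`GENE_CLASSES` order.
    n_replicates:
        Biological replicates per condition (the study design uses 4);
        at least 2 so every contrast has >=1 pairwise comparison per side.
    baseline_mean, baseline_sd:
        Per-gene baseline log2 intensity distribution (Gaussian).
    noise_sd:
        Within-condition residual standard deviation, log2 units.
    effect_ranges:
        Map effect role -> (min, max) log2 magnitude; see
        :data:`DEFAULT_EFFECT_RANGES`.
    heavy_tailed:
        If True, residuals are Student-t (df=3) scaled to ``noise_sd``
        instead of Gaussian.
    low_signal_baseline, low_signal_sd:
        Location/spread of the detection-floor class.
    seed:
        Master seed; per-stage sub-streams are derived from it and recorded
        in the output metadata.
    """

    n_genes: int = 2000
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    n_replicates: int = 4
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    effect_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_RANGES))
    heavy_tailed: bool = False
    low_signal_baseline: float = 1.0
    low_signal_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ConfigurationError(
                "n_replicates must be >= 2 (pairwise fold-change ranks need "
                "at least one comparison per contrast side)")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown gene classes: {sorted(unknown)}")
        fracs = np.array(list(self.class_fractions.values()), dtype=float)
        if (fracs < 0).any():
            raise ConfigurationError("class fractions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class fractions must sum to 1 (got {fracs.sum()!r})")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def largest_remainder_counts(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Integer class counts by the largest-remainder rule.

    Each class first gets floor(fraction*total); the remaining units go to
    the classes with the largest fractional remainders, ties broken by
    :data:`GENE_CLASSES` order.  Counts always sum to ``total``.
    """
    classes = [c for c in GENE_CLASSES if c in fractions]
    exact = {c: fractions[c] * total for c in classes}
    counts = {c: int(math.floor(exact[c])) for c in classes}
    short = total - sum(counts.values())
    by_remainder = sorted(classes,
                          key=lambda c: (-(exact[c] - counts[c]), GENE_CLASSES.index(c)))
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def _uniform(rng: np.random.Generator, rng_range: tuple[float, float], size: int) -> np.ndarray:
    lo, hi = rng_range
    return rng.uniform(lo, hi, size)


def _draw_class_effects(gene_class: str, n: int, er: dict, rng: np.random.Generator):
    """Per-gene (lfc_a, lfc_b, lfc_ab) for one planted class."""
    z = np.zeros(n)
    if gene_class in ("null", "low_signal"):
        return z, z.copy(), z.copy()
    if gene_class in ("a_only", "b_only"):
        mag = _uniform(rng, er["single"], n)
        sign = rng.choice([-1.0, 1.0], n)
        eff = sign * mag
        if gene_class == "a_only":
            return eff, z, eff.copy()
        return z, eff, eff.copy()
    if gene_class == "additive":
        a = _uniform(rng, er["additive_single"], n)
        b = _uniform(rng, er["additive_single"], n)
        sign = rng.choice([-1.0, 1.0], n)
        return sign * a, sign * b, sign * (a + b)
    if gene_class in ("synergistic_up", "synergistic_down"):
        strong = _uniform(rng, er["synergy_strong_single"], n)
        weak = _uniform(rng, er["synergy_weak_single"], n)
        excess = _uniform(rng, er["synergy_excess"], n)
        swap = rng.random(n) < 0.5  # which single is the strong one
        a = np.where(swap, weak, strong)
        b = np.where(swap, strong, weak)
        ab = a + b + excess
        if gene_class == "synergistic_down":
            return -a, -b, -ab
        return a, b, ab
    if gene_class == "signature_like":
        a = _uniform(rng, er["signature_single"], n)
        b = _uniform(rng, er["signature_single"], n)
        ab = _uniform(rng, er["signature_double"], n)
        return a, b, ab
    raise ConfigurationError(f"unknown gene class {gene_class!r}")


def generate_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Ground-truth table: gene_id, gene_class, true per-condition log2 effects."""
    counts = largest_remainder_counts(config.class_fractions, config.n_genes)
    width = len(str(config.n_genes))
    rows = []
    i = 0
    for cls in GENE_CLASSES:
        n = counts.get(cls, 0)
        if n == 0:
            continue
        a, b, ab = _draw_class_effects(cls, n, config.effect_ranges, rng)
        for j in range(n):
            rows.append((f"g{i + j + 1:0{width}d}", cls, a[j], b[j], ab[j]))
        i += n
    return pd.DataFrame(rows, columns=["gene_id", "gene_class",
                                       "true_lfc_a", "true_lfc_b", "true_lfc_ab"])


def _residuals(rng: np.random.Generator, sd: float, shape, heavy: bool) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    if heavy:
        df = 3.0
        return rng.standard_t(df, shape) * sd / math.sqrt(df / (df - 2.0))
    return rng.normal(0.0, sd, shape)


def generate_factorial(config: SimConfig):
    """Simulate a factorial experiment.

    Returns
    -------
    (matrix, truth, metadata):
        ``matrix`` is an :class:`~synerdeg.core.ExpressionMatrix` with
        4*n_replicates samples named ``{condition}_{replicate}``;
        ``truth`` the ground-truth DataFrame; ``metadata`` a dict recording
        the config and the per-stage sub-stream indices of the master seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    effects_ss, baseline_ss, noise_ss = ss.spawn(3)
    truth = generate_truth(config, np.random.default_rng(effects_ss))

    n = len(truth)
    baseline_rng = np.random.default_rng(baseline_ss)
    baseline = baseline_rng.normal(config.baseline_mean, config.baseline_sd, n)
    low = truth["gene_class"].to_numpy() == "low_signal"
    if low.any():
        baseline[low] = baseline_rng.normal(
            config.low_signal_baseline, config.low_signal_sd, int(low.sum()))

    cond_lfc = {
        "mock": np.zeros(n),
        "A": truth["true_lfc_a"].to_numpy(),
        "B": truth["true_lfc_b"].to_numpy(),
        "AB": truth["true_lfc_ab"].to_numpy(),
    }
    noise_rng = np.random.default_rng(noise_ss)
    cols, names, design_rows = [], [], []
    for cond in ("mock", "A", "B", "AB"):
        for rep in range(1, config.n_replicates + 1):
            resid = _residuals(noise_rng, config.noise_sd, n, config.heavy_tailed)
            cols.append(baseline + cond_lfc[cond] + resid)
            name = f"{cond}_{rep}"
            names.append(name)
            design_rows.append((name, cond, rep))
    values = pd.DataFrame(np.column_stack(cols),
                          index=pd.Index(truth["gene_id"], name="gene_id"),
                          columns=names)
    design = pd.DataFrame(design_rows, columns=["sample_id", "condition", "replicate"]
                          ).set_index("sample_id")
    matrix = ExpressionMatrix(values, design)
    metadata = {
        "seed": config.seed,
        "substreams": {"effects": 0, "baselines": 1, "noise": 2},
        "config": {k: (dict(v) if isinstance(v, dict) else v)
                   for k, v in asdict(config).items()},
        "class_counts": largest_remainder_counts(config.class_fractions, config.n_genes),
    }
    return matrix, truth, metadata


# ---------------------------------------------------------------------------
# qPCR / ChIP-qPCR table generators


def generate_qpcr_table(n_targets: int,
                        n_references: int = 3,
                        true_fold_changes=None,
                        ct_noise_sd: float = 0.1,
                        seed: int = 0,
                        n_replicates: int = 3,
                        mock_label: str = "mock") -> pd.DataFrame:
    """Simulate a long-format qPCR Ct table.

    ``true_fold_changes`` maps condition -> (target -> linear fold change vs
    mock); a flat mapping target -> fold change is treated as a single
    ``"treated"`` condition.  Target Ct values drop by log2(FC) in treated
    samples; reference-gene Ct values are unchanged in expectation.
    """
    if n_references < 1:
        raise ConfigurationError("need at least one reference gene")
    targets = [f"T{i+1}" for i in range(n_targets)]
    references = [f"REF{i+1}" for i in range(n_references)]
    if true_fold_changes is None:
        true_fold_changes = {"treated": {t: 1.0 for t in targets}}
    elif true_fold_changes and not isinstance(next(iter(true_fold_changes.values())), dict):
        true_fold_changes = {"treated": dict(true_fold_changes)}
    for cond, fcs in true_fold_changes.items():
        for t, fc in fcs.items():
            if fc <= 0:
                raise ConfigurationError(
                    f"fold change for {t!r} in {cond!r} must be positive (got {fc})")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base_ct = {t: rng.uniform(22.0, 28.0) for t in targets}
    base_ct.update({r: rng.uniform(16.0, 22.0) for r in references})

    rows = []
    conditions = [mock_label] + list(true_fold_changes)
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_{rep}"
            for gene in targets + references:
                ct = base_ct[gene]
                if cond != mock_label and gene in targets:
                    ct -= math.log2(true_fold_changes[cond].get(gene, 1.0))
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                role = "target" if gene in targets else "reference"
                rows.append((sample, cond, gene, role, ct, rep))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene_id",
                                       "role", "ct", "replicate"])


def generate_chip_table(true_percent_input: dict,
                        input_fraction: float,
                        ct_noise_sd: float = 0.0,
                        seed: int = 0,
                        n_replicates: int = 3,
                        antibody: str = "ab") -> pd.DataFrame:
    """Simulate a ChIP-qPCR table with known percent-input enrichment.

    ``true_percent_input`` maps (region_id, condition) -> percent of input;
    ``ct_input`` is the Ct of the diluted input (fraction ``input_fraction``
    of the chromatin), so that
    ``percent = 100 * input_fraction * 2**(ct_input - ct_ip)``.
    """
    if not 0 < input_fraction <= 1:
        raise ConfigurationError("input_fraction must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for (region, cond), pct in true_percent_input.items():
        if pct <= 0:
            raise ConfigurationError(f"percent input must be positive for {region!r}")
        for rep in range(1, n_replicates + 1):
            ct_input = rng.uniform(24.0, 27.0)
            ct_ip = ct_input - math.log2(pct / (100.0 * input_fraction))
            if ct_noise_sd > 0:
                ct_input += rng.normal(0.0, ct_noise_sd)
                ct_ip += rng.normal(0.0, ct_noise_sd)
            rows.append((region, antibody, cond, ct_ip, ct_input,
                         input_fraction, rep))
    return pd.DataFrame(rows, columns=["region_id", "antibody", "condition",
                                       "ct_ip", "ct_input", "input_fraction",
                                       "replicate"])
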