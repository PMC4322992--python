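# Methods

`synerdeg` analyses two-factor factorial expression experiments — untreated
cells (mock), two single treatments (A, B), and the double treatment (AB),
each with biological replicates — to identify genes regulated
*synergistically* by the combination, i.e. more strongly than the sum of
the single-treatment responses. The motivating setting is a genotoxic drug
combined with an inflammatory cytokine (e.g. doxorubicin × TNFα), where the
p53 and NF-κB pathways are activated jointly, but the statistics are
agnostic to the identity of the factors.

## Rank-product test and permutation pfp

For a contrast with *t* treatment and *c* control replicates, every gene
receives K = t·c pairwise log2 fold changes (treatment replicate minus
control replicate). Within each pairwise comparison, genes are ranked by
fold change — rank 1 being the most up-regulated for the `up` direction,
the most down-regulated for `down`, ties receiving average ranks — and the
rank product is the geometric mean of a gene's K ranks. Genes that are
consistently extreme across comparisons obtain small rank products; the up
and down directions are tested separately, matching the separate up/down
DEG counts of the factorial analysis.

Significance is expressed as the **percentage of false positives (pfp)**,
the permutation analogue of the FDR. Each of B permutation rounds (default
B = 100) shuffles the expression values within each *array* of the contrast
independently and recomputes all pairwise ranks and rank products. For the
observed gene at position k of the sorted rank-product list,

    E[FP](k) = (count of permuted rank products ≤ observed) / B
    pfp(k)   = E[FP](k) / k,

with monotonicity down the sorted list enforced by a cumulative maximum and
values capped at 1. Tied rank products are ordered deterministically by
gene id so output is reproducible.

**Why array-wise permutation.** Pairwise comparisons share replicate
arrays: comparisons (AB₁−mock₁) and (AB₁−mock₂) both contain the AB₁
measurement, so a gene's ranks are positively dependent across comparisons
even under the null. Shuffling each array's values preserves exactly this
dependence. The alternative null — shuffling values independently within
each pairwise comparison, equivalent to giving each gene an independent
uniform rank per comparison — ignores it and is measurably
anti-conservative (on pure-null simulations with 4-vs-4 replicates it calls
~7% of genes at pfp < 0.05). That comparison-wise null is nevertheless
retained as the `exact=True` mode, because it is exactly enumerable: by
linearity of expectation each gene's null rank is marginally uniform on
{1..n} and independent across comparisons, so E[FP](x) = n·#{rank tuples
with product ≤ xᴷ}/nᴷ. The exact mode exists to validate tiny instances
against exhaustive enumeration, not for inference.

Null ranks inside the Monte-Carlo permutation are ordinal (ties broken by
sort order), and down-direction null ranks are the exact complements of the
up ranks; together with a shared permutation stream this makes the up/down
symmetry under matrix negation exact. With B permutations the granularity
of E[FP] at the top rank is 1/B; a warning is emitted below B = 20.

## DEG and synergy calling

A gene is a DEG for a contrast when `pfp < 0.05` and `|avg log2 FC| > 2`
(both strict; the fold-change estimate is the arithmetic mean of the K
pairwise log2 fold changes, which equals the difference of group means).
Four contrasts are tested: A vs mock, B vs mock, AB vs mock, and AB vs all
(the double treatment against the pooled single treatments and mock).

Synergistic DEGs are AB-vs-mock DEGs that additionally pass
`pfp < 0.005` in the AB-vs-all contrast (direction-matched). Two filter
variants are reported side by side:

* `synergistic_pfp_only` — the pfp filter alone;
* `synergistic` — additionally the **synergy effect**
  `SE = lfc_AB − (lfc_A + lfc_B)` must be > 0 for up-regulated genes and
  < 0 for down-regulated ones.

The **signature** keeps up-regulated synergistic genes whose
single-treatment contributions are minimal: each single treatment's linear
fold change must be below 25% of the double treatment's
(`2^max(lfc,0) / 2^lfc_AB < 0.25`, both singles, strict). Fold changes
below 1 are floored to 1 before the ratio — a repressed single-treatment
response contributes no up-regulation; a log2-scale variant of the ratio is
available behind the `ratio_scale` flag for sensitivity analysis. The
signature is ranked by double-treatment fold change, descending. By
construction: signature ⊆ synergistic-up ⊆ AB-vs-mock up-DEGs ⊆ tested
genes.

A known property of the strict SE rule: genes whose true interaction is
exactly zero (pure single-treatment responders, perfectly additive genes)
pass both pfp filters whenever their responses are strong, and their
*estimated* SE is then a coin flip around zero — about half of them enter
the synergistic set regardless of noise level. They are an irreducible
false-positive floor of the rule; the simulator keeps such classes at a
realistic minority so the floor stays below the 10% FDP envelope.

## Preprocessing

Order: low-signal filter → quantile normalization → probe-to-gene
averaging, all on log2 intensities.

* **Low-signal filter**: a row is kept if its value exceeds a floor in at
  least 75% of the replicates of at least one condition ("acceptable
  signal in most replicates"); the floor defaults to the 1st percentile of
  all intensities. Both knobs are configurable, as no canonical threshold
  exists for this rule.
* **Quantile normalization**: every column is mapped onto the row means of
  the column-sorted matrix, preserving within-column ranks; tied values
  receive the mean of the reference values their positions span. Sorted
  columns are identical to machine precision afterwards. Re-normalizing a
  normalized matrix is a no-op for matrices with distinct values; when
  ties are present, a tied span's mean feeds back into the reference
  distribution of the other columns, so exact idempotence is guaranteed
  only in the generic (tie-free, continuous) case. Caveat measured on the
  synthetic study: when a sizeable fraction of genes carries 3–5 log2
  planted effects, quantile normalization compresses the regulated tail
  (mean log2 FC of strong responders shrinks from ≈3.9 to ≈3.1) — the
  standard assumption that most genes are unchanged is violated. The
  simulated arrays share a common scale by construction, so the
  recovery-benchmark runs disable normalization (`normalize=False`);
  real array data, which carries technical array effects, should keep it.
* **Probe aggregation**: probes mapping to the same gene are averaged on
  the log2 scale (linear-scale averaging is deliberately not the default
  because the matrix is log2 throughout); unmapped probes are dropped with
  a logged count.

## Synthetic data generator

The generator emulates a single-colour microarray factorial: per-gene
baseline log2 intensity ~ N(8, 1.5²), additive condition effects, and
i.i.d. Gaussian residuals (default sd 0.25 in log2 units; a Student-t
(df = 3) option models heavier-tailed noise). The within-condition
variance of the original arrays is not documented anywhere, so the default
noise is a package choice, not a reconstruction. Default design: 2000
genes, 4 replicates per condition.

Planted classes and their default constructions (log2 units):

| class             | fraction | lfc_A            | lfc_B           | lfc_AB            |
|-------------------|---------:|------------------|-----------------|-------------------|
| null              | 0.90     | 0                | 0               | 0                 |
| a_only            | 0.0025   | ±U(3, 5)         | 0               | = lfc_A           |
| b_only            | 0.0025   | 0                | ±U(3, 5)        | = lfc_B           |
| additive          | 0.005    | ±U(1.5, 1.8)     | same sign       | = lfc_A + lfc_B   |
| synergistic_up    | 0.025    | U(2.2, 2.7) / U(0.5, 0.85)* | (swapped)* | A + B + U(0.5, 0.85) |
| synergistic_down  | 0.045    | mirrored negation of synergistic_up              |||
| signature_like    | 0.02     | U(0, 0.5)        | U(0, 0.5)       | U(3, 5)           |
| low_signal        | 0        | 0 (baseline at the detection floor)              |||

\* one single treatment is strong and one weak, the strong side chosen at
random — synergistic but *not* minimally single-responsive, so these genes
fail the 0.25 ratio filter by a ≥0.3 log2 margin while signature_like
genes pass it by ≥0.5; this separation is what makes exact signature
recovery meaningful. Class counts use largest-remainder rounding (ties
broken in the canonical class order above), the 0.90 null fraction follows
the stated recovery conditions, up- and down-regulated planted mass is
balanced so the intensity distributions stay comparable across conditions,
and one master seed spawns per-stage sub-streams (effects, baselines,
noise) recorded in the output metadata.

What the generator does *not* model: probe-level feature-extraction
output, dye or spatial artifacts, array-level technical effects
(normalization therefore has nothing to correct), gene–gene correlation,
and intensity-dependent variance. Passing the recovery benchmarks
demonstrates correctness of the statistical machinery under the stated
conditions, not performance on real arrays.

## qPCR and ChIP quantification

ΔΔCt with multiple reference genes: per sample,
`ΔCt = Ct_target − mean(Ct_references)` (arithmetic mean of Cts =
geometric-mean normalization on the linear scale; amplification
efficiencies are assumed 2.0 as no standard curves are modelled). The mock
baseline is the mean ΔCt over mock replicates; each treated replicate
yields `FC = 2^−(ΔCt − baseline)`, and the reported dispersion is the sd
of those per-replicate fold changes. Fold changes are invariant to adding
a constant to every Ct of a sample (plate-shift invariance).

ChIP enrichment: `% input = 100 · f · 2^(Ct_input − Ct_IP)`, where `f` is
the fraction of chromatin kept as input and `Ct_input` is measured on that
diluted aliquot (the factor `f` is exactly the −log2 f dilution
correction). `f` is a required argument with no default — it is
assay-specific and not recoverable from the analysis itself. If the input
Ct has already been adjusted to the full-chromatin equivalent, set
`input_is_diluted=False`.

## Numerical and design choices

* Rank products are accumulated as products of ranks (floats); for n·K up
  to ~20000¹⁶ this stays within double range, and in the exact mode the
  integer products are exact, so enumeration comparisons are equality
  comparisons.
* All thresholds are strict inequalities, as stated.
* Rows failing a direction's test are simply absent from that direction's
  DEG set; a gene can appear in at most one direction per contrast because
  the fold-change conditions are mutually exclusive.
* Deterministic ordering everywhere (pfp ascending, |lfc| descending, gene
  id) so that equal-seed runs are byte-identical.
* The benchmark problem sizes (2000 genes, 3 seeds per recovery metric, 50
  null-calibration seeds, 100 permutations) are the package's default
  study scale; they reproduce the documented behaviour in seconds.

## Known limitations

* pfp resolution is bounded by the permutation count; pfp < 0.005
  decisions near the boundary are Monte-Carlo noisy at B = 100, which can
  occasionally drop a true signature gene at a boundary rank.
* With very strong, abundant planted effects the permutation null is
  contaminated by the planted values themselves (scattered by the
  shuffle), making the test conservative for weaker effects — visible as
  reduced sensitivity when the planted fraction is pushed well above the
  default 10%.
* The comparison-wise exact mode is for validation only; its null is
  anti-conservative for inference (see above).
* The ratio filter is defined only for up-regulated genes; calling it on a
  gene with lfc_AB ≤ 0 is an error by design.
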