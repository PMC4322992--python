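#!/usr/bin/env python
"""Rank-product differential expression tests for all four contrasts.

Each treatment is compared against mock, plus the double-vs-all contrast
(AB against the pooled single treatments and mock) that feeds the synergy
filter.  Permutation pfp uses 100 array-wise permutation rounds.  Writes
one table per contrast under results/rankprod/.
"""

from pathlib import Path

import numpy as np

from synerdeg import standard_contrasts
from synerdeg.io import read_expression_tsv, write_table_tsv
from synerdeg.rankprod import estimate_pfp

BASE = Path(__file__).resolve().parent.parent / "results"
PRE = BASE / "preprocessed"
OUT = BASE / "rankprod"
SEED = 0
N_PERM = 100

matrix = read_expression_tsv(PRE / "expression_filtered.tsv", PRE / "design.tsv")
contrasts = standard_contrasts(matrix)
seed_rng = np.random.default_rng(np.random.SeedSequence(SEED))

OUT.mkdir(parents=True, exist_ok=True)
for name in ("A_vs_mock", "B_vs_mock", "AB_vs_mock", "AB_vs_all"):
    sub_seed = int(seed_rng.integers(0, 2**31 - 1))
    res = estimate_pfp(matrix, contrasts[name], n_permutations=N_PERM,
                       seed=sub_seed)
    write_table_tsv(res.reset_index(), OUT / f"rankprod_{name}.tsv",
                    {"contrast": name, "seed": sub_seed,
                     "n_permutations": N_PERM})
    n_sig = int(((res.pfp_up < 0.05) | (res.pfp_down < 0.05)).sum())
    top = res.sort_values("rp_up").index[0]
    print(f"{name}: {res.n_comparisons.iloc[0]} pairwise comparisons, "
          f"{n_sig} genes at pfp<0.05 (either direction); top up-gene {top}")
print(f"tables -> {OUT}")
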