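import numpy as np
import pandas as pd
import pytest

from synerdeg import ExpressionMatrix, PipelineConfig, SimConfig, run_pipeline


def make_matrix(values, n_replicates=None, conditions=None, gene_ids=None):
    """Build an ExpressionMatrix from a 2D array.

    Columns are assigned to conditions mock/A/B/AB in blocks; either
    ``n_replicates`` (equal blocks over the four conditions) or an explicit
    per-column ``conditions`` list may be given.
    """
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    if conditions is None:
        if n_replicates is None:
            n_replicates = n_samples // 4
        conditions = [c for c in ("mock", "A", "B", "AB")
                      for _ in range(n_replicates)][:n_samples]
    reps: dict[str, int] = {}
    names, design_rows = [], []
    for cond in conditions:
        reps[cond] = reps.get(cond, 0) + 1
        name = f"{cond}_{reps[cond]}"
        names.append(name)
        design_rows.append((name, cond, reps[cond]))
    if gene_ids is None:
        gene_ids = [f"g{i+1}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=names)
    design = pd.DataFrame(design_rows,
                          columns=["sample_id", "condition", "replicate"]
                          ).set_index("sample_id")
    return ExpressionMatrix(df, design)


@pytest.fixture(scope="session")
def recovery_run():
    """Default-condition simulation piped through testing + calling stages.

    Normalization is off: the simulator emits gene-level data with no
    array-level technical effects (see docs/methods.md).
    """
    cfg = PipelineConfig(sim=SimConfig(seed=11), seed=11, normalize=False)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def low_noise_run():
    """Strong effects, low noise: the regime where signature recovery is exact."""
    cfg = PipelineConfig(sim=SimConfig(seed=13, noise_sd=0.05), seed=13,
                         normalize=False)
    return run_pipeline(cfg)
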