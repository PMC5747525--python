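import numpy as np
import pandas as pd
import pytest

from peptinet import ExpressionMatrix, Scale, SimConfig, generate_dataset, normalize_rpkm_to_logcpm


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 cells x 4 genes log-scale matrix with mixed symmetry codes."""
    values = pd.DataFrame(
        [[1.0, 0.0, 2.0, 0.5], [0.0, 1.5, 0.0, 0.0], [2.0, 2.0, 1.0, 0.0]],
        index=pd.Index(["c1", "c2", "c3"], name="cell_id"),
        columns=["PNP1", "PNP2", "GPCR1", "TRM1"],
    )
    meta = pd.DataFrame({"symmetry": ["Y2", "N", "Y1"]}, index=values.index)
    return ExpressionMatrix(values=values, scale=Scale.log_cpm, cell_meta=meta)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset, normalized, with its ground truth."""
    matrix, roles, pairs, coords, truth = generate_dataset(SimConfig(seed=42))
    return normalize_rpkm_to_logcpm(matrix), roles, pairs, coords, truth


def random_log_matrix(seed: int, n_cells: int = 15, n_genes: int = 30) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    on = rng.random((n_cells, n_genes)) < 0.4
    vals = np.where(on, np.abs(rng.normal(1.5, 0.6, (n_cells, n_genes))), 0.0)
    return ExpressionMatrix(
        values=pd.DataFrame(
            vals,
            index=[f"c{i}" for i in range(n_cells)],
            columns=[f"g{j}" for j in range(n_genes)],
        ),
        scale=Scale.log_cpm,
    )
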