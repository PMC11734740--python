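import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from stagescreen import SimulationConfig, simulate_screen


def make_wells(rows, n_rows=8, n_cols=12):
    """Tidy well frame from (plate, batch, rep, row, col, role, gene, sirna, channel, value)."""
    df = pd.DataFrame(rows, columns=[
        "plate_id", "batch_id", "replicate", "row", "col", "role", "gene",
        "sirna_id", "channel", "value"])
    df["gene"] = df["gene"].astype("string")
    df["sirna_id"] = df["sirna_id"].astype("string")
    return df


def additive_plate_frame(n_rows=8, n_cols=12, base=10.0, row_step=1.0,
                         col_step=2.0, channel="IL6", plate="P1", rep=1):
    """Fully additive single plate: value = base + row_step*i + col_step*j."""
    rows = []
    for i in range(n_rows):
        for j in range(n_cols):
            rows.append((plate, "B1", rep, i, j, "sample", f"G{i * n_cols + j:03d}",
                         f"s{i * n_cols + j:03d}", channel,
                         base + row_step * i + col_step * j))
    return make_wells(rows, n_rows, n_cols)


def random_plate_matrix(rng, n_rows=8, n_cols=12, missing_fraction=0.0):
    mat = rng.normal(10.0, 3.0, size=(n_rows, n_cols))
    mat += rng.normal(0, 2, size=(n_rows, 1))       # row artifact
    mat += rng.normal(0, 2, size=(1, n_cols))       # column artifact
    if missing_fraction:
        mask = rng.random((n_rows, n_cols)) < missing_fraction
        # keep at least one value per row and column
        for i in range(n_rows):
            mask[i, rng.integers(n_cols)] = False
        for j in range(n_cols):
            mask[rng.integers(n_rows), j] = False
        mat[mask] = np.nan
    return mat


def scores_frame(tensor, gene="GENE1", channel="KILLING"):
    """Tidy score frame from one (siRNA x replicate) array; NaN rows dropped."""
    rows = []
    for i in range(tensor.shape[0]):
        for j in range(tensor.shape[1]):
            v = tensor[i, j]
            if not np.isnan(v):
                rows.append(dict(gene=gene, sirna_id=f"s{i + 1}", replicate=j + 1,
                                 channel=channel, score=float(v)))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_primary_screen():
    cfg = SimulationConfig.primary(n_genes=84, hit_fraction=0.1, seed=11)
    return cfg, *simulate_screen(cfg)


@pytest.fixture(scope="session")
def small_secondary_screen():
    cfg = SimulationConfig.secondary(n_genes=30, seed=12)
    return cfg, *simulate_screen(cfg)


@pytest.fixture(scope="session")
def small_killing_screen():
    cfg = SimulationConfig.killing(n_genes=30, seed=13)
    return cfg, *simulate_screen(cfg)
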