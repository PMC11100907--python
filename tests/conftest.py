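from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dcistme.io_model import CellTable


def make_cells(
    xy: np.ndarray,
    phenotypes: dict[str, np.ndarray] | None = None,
    sample: str = "S0",
    **meta,
) -> CellTable:
    """Build a cell table from coordinates and phenotype masks."""
    xy = np.asarray(xy, dtype=float)
    df = pd.DataFrame({"sample": sample, "x": xy[:, 0], "y": xy[:, 1]})
    for name, mask in (phenotypes or {}).items():
        df[name] = np.asarray(mask, dtype=bool)
    for key, val in meta.items():
        df[key] = val
    return CellTable(df, validate=False)


def random_pattern(rng: np.random.Generator, n: int, extent: float = 500.0) -> np.ndarray:
    return rng.uniform(0.0, extent, size=(n, 2))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def two_type_table(rng) -> CellTable:
    """A random 150-cell pattern with overlapping A/B phenotypes."""
    xy = random_pattern(rng, 150)
    a = rng.uniform(size=150) < 0.5
    b = rng.uniform(size=150) < 0.4
    a[~(a | b)] = True  # no dead cells
    return make_cells(xy, {"A": a, "B": b})
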