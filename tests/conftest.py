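import numpy as np
import pytest

from esdm.env_layers import EnvStack, GridSpec, Layer


@pytest.fixture
def grid10() -> GridSpec:
    return GridSpec(n_rows=10, n_cols=10, cell_size=30.0, origin_x=0.0, origin_y=300.0)


def make_layer(grid: GridSpec, name: str, values, kind: str = "continuous") -> Layer:
    return Layer(name, kind, np.asarray(values, dtype=float), grid)


def grid_for(values, cell_size: float = 30.0) -> GridSpec:
    values = np.asarray(values)
    return GridSpec(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        cell_size=cell_size,
        origin_x=0.0,
        origin_y=values.shape[0] * cell_size,
    )


def stack_from_columns(columns: dict[str, np.ndarray], n_rows: int, n_cols: int) -> EnvStack:
    """Build an aligned stack whose per-layer raveled values are the given columns."""
    grid = GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size=1.0, origin_x=0.0, origin_y=float(n_rows))
    layers = [
        Layer(name, "continuous", np.asarray(col, dtype=float).reshape(n_rows, n_cols), grid)
        for name, col in columns.items()
    ]
    return EnvStack(layers)
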