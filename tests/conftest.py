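import numpy as np
import pandas as pd
import pytest

from nichesignal.io_formats import (
    ENV_VARS,
    EnvironmentGrid,
    StemMap,
    parse_newick,
)

BALANCED4 = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def balanced4():
    return parse_newick(BALANCED4)


def make_balanced_newick(depth: int, prefix: str = "t") -> str:
    """Perfect binary tree with unit branch lengths and 2**depth tips."""
    counter = [0]

    def build(d):
        if d == 0:
            counter[0] += 1
            return f"{prefix}{counter[0]:03d}:1"
        return f"({build(d - 1)},{build(d - 1)}):1"

    left = build(depth - 1)
    right = build(depth - 1)
    return f"({left},{right});"


@pytest.fixture
def balanced16():
    return parse_newick(make_balanced_newick(4))


def make_grid(n_rows, n_cols, quadrat_size=1.0, seed=0, **overrides):
    """Small environment grid with iid standard-normal variables.

    ``overrides`` replace whole fields with given flat arrays/constants.
    """
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    df = pd.DataFrame({"row": rr.ravel(), "col": cc.ravel()})
    for name in ENV_VARS:
        if name == "aspect":
            df[name] = rng.uniform(0, 360, n_rows * n_cols)
        else:
            df[name] = rng.standard_normal(n_rows * n_cols)
    for name, value in overrides.items():
        df[name] = np.broadcast_to(
            np.asarray(value, dtype=float).ravel(), (n_rows * n_cols,)
        )
    return EnvironmentGrid(n_rows, n_cols, quadrat_size, df)


def make_stems(coords, species="sp", stage="adult", extent=(5.0, 5.0)):
    """StemMap from a list of (x, y) or (x, y, species) tuples."""
    rows = []
    for i, item in enumerate(coords):
        if len(item) == 2:
            x, y = item
            sp = species
        else:
            x, y, sp = item
        rows.append((f"tag{i:04d}", sp, x, y, stage))
    df = pd.DataFrame(rows, columns=["tag", "species", "x", "y", "stage"])
    return StemMap(df, extent_x=extent[0], extent_y=extent[1])


def random_tree(rng, n_min=5, n_max=15):
    """Random tree with random (non-ultrametric) branch lengths."""
    from nichesignal.synthetic_data import simulate_tree

    n = int(rng.integers(n_min, n_max + 1))
    tree = simulate_tree(n, int(rng.integers(0, 2**31)))
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(0.1, 2.0))
    return tree
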