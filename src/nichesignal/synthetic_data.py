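"""Ground-truthed synthetic forest plots.

Generates pure-birth phylogenies, spatially autocorrelated environment
fields, niche optima evolved under (lambda-scaled) Brownian motion, and
stem maps placed by a Gaussian niche response — so every downstream
statistic can be calibrated against known conservatism or lability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    ENV_VARS,
    SOIL_VARS,
    TOPO_VARS,
    EnvironmentGrid,
    PhylogeneticTree,
    StemMap,
    parse_newick,
)

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "evolve_niche_optima",
    "generate_environment",
    "place_individuals",
    "simulate_dataset",
    "SyntheticDataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic generator.

    ``conservatism_lambda`` interpolates between full Brownian motion
    (1) and a star phylogeny / labile traits (0) by scaling internal
    branch lengths and stretching tip branches to preserve root-to-tip
    depths.
    """

    n_species: int = 64
    grid_width: int = 50          # quadrat columns
    grid_height: int = 20         # quadrat rows
    quadrat_size: float = 20.0    # metres
    autocorr_range: float = 100.0  # metres
    bm_sigma2: float = 1.0
    conservatism_lambda: float = 1.0
    root_value: float = 0.0
    niche_breadth: float = 0.5
    mean_abundance: float = 150.0          # adult stems per species
    seedling_abundance: float | None = None  # defaults to mean_abundance
    niche_axis: str = "elevation"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValidationError("n_species must be >= 2")
        if self.grid_width < 1 or self.grid_height < 1:
            raise ValidationError("grid dimensions must be >= 1")
        if self.quadrat_size <= 0:
            raise ValidationError("quadrat_size must be positive")
        if self.autocorr_range <= 0:
            raise ValidationError("autocorr_range must be positive")
        if not 0.0 <= self.conservatism_lambda <= 1.0:
            raise ValidationError("conservatism_lambda must lie in [0, 1]")
        if self.niche_breadth <= 0:
            raise ValidationError("niche_breadth must be positive")
        if self.bm_sigma2 < 0:
            raise ValidationError("bm_sigma2 must be non-negative")
        if self.mean_abundance < 0:
            raise ValidationError("mean_abundance must be non-negative")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def simulate_tree(n_species: int, seed: int) -> PhylogeneticTree:
    """Pure-birth (Yule) tree with unit rate, rescaled to depth 1.

    Tips are labelled ``sp0001`` ... in a seed-determined random order,
    so label and topology are independent.
    """
    if n_species < 2:
        raise ValidationError("n_species must be >= 2")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    # root splits at t=0 into two lineages
    births = {root: 0.0}
    leaves = []
    for _ in range(2):
        child = root.new_child()
        births[child] = 0.0
        leaves.append(child)
    t = 0.0
    while len(leaves) < n_species:
        t += rng.exponential(1.0 / len(leaves))
        i = int(rng.integers(len(leaves)))
        parent = leaves.pop(i)
        births[parent] = t  # now an internal node that splits at time t
        for _ in range(2):
            child = parent.new_child()
            leaves.append(child)
    depth = t + rng.exponential(1.0 / len(leaves))

    # Internal node "birth" recorded above is its split time; edge length
    # runs from the parent's split to this node's split (or to `depth`).
    split_time = dict(births)
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = None
            continue
        start = split_time[node.parent_node]
        end = split_time[node] if node.child_nodes() else depth
        node.edge.length = (end - start) / depth

    labels = [f"sp{i + 1:04d}" for i in range(n_species)]
    order = rng.permutation(n_species)
    for leaf, j in zip(leaves, order):
        leaf.taxon = taxa.new_taxon(labels[j])
    # re-parse to normalize internal bookkeeping
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    return parse_newick(newick, strict=False)


def _lambda_branch_lengths(
    tree: PhylogeneticTree, lam: float
) -> dict:
    """Edge lengths of the lambda-transformed tree, keyed by node.

    Internal edges are multiplied by ``lam``; each tip edge is stretched
    so the tip's root-to-tip depth is preserved.
    """
    depths = tree.node_depths()
    out = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.is_leaf():
            parent_depth = depths[node.parent_node]
            out[node] = depths[node] - lam * parent_depth
        else:
            out[node] = lam * node.edge.length
    return out


def evolve_niche_optima(
    tree: PhylogeneticTree,
    bm_sigma2: float,
    conservatism_lambda: float,
    root_value: float = 0.0,
    seed: int = 0,
    n_traits: int | None = None,
):
    """Brownian-motion traits on a lambda-transformed tree.

    Returns a Series (tip -> value) for the default single trait, or a
    DataFrame of ``n_traits`` independent replicate columns. Increments
    are Gaussian with variance ``bm_sigma2 * branch length``.
    """
    if not 0.0 <= conservatism_lambda <= 1.0:
        raise ValidationError("conservatism_lambda must lie in [0, 1]")
    if bm_sigma2 < 0:
        raise ValidationError("bm_sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    m = 1 if n_traits is None else int(n_traits)
    if m < 1:
        raise ValidationError("n_traits must be >= 1")

    lengths = _lambda_branch_lengths(tree, conservatism_lambda)
    values: dict = {}
    tips: dict[str, np.ndarray] = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = np.full(m, float(root_value))
        else:
            bl = max(lengths[node], 0.0)
            step = rng.normal(0.0, np.sqrt(bm_sigma2 * bl), size=m)
            values[node] = values[node.parent_node] + step
        if node.is_leaf():
            tips[node.taxon.label] = values[node]

    labels = tree.tip_labels
    mat = np.vstack([tips[lab] for lab in labels])
    if n_traits is None:
        return pd.Series(mat[:, 0], index=labels, name="optimum")
    cols = [f"trait_{j + 1:04d}" for j in range(m)]
    return pd.DataFrame(mat, index=labels, columns=cols)


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------

def _gaussian_random_fields(
    n_rows: int,
    n_cols: int,
    quadrat_size: float,
    autocorr_range: float,
    n_fields: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary fields with exponential covariance, via Cholesky.

    Returns (n_quadrats, n_fields), each column standardized to zero
    mean and unit variance over the grid.
    """
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    y = (rr.ravel() + 0.5) * quadrat_size
    x = (cc.ravel() + 0.5) * quadrat_size
    d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    cov = np.exp(-d / autocorr_range)
    cov[np.diag_indices_from(cov)] += 1e-9  # numerical jitter
    chol = np.linalg.cholesky(cov)
    z = chol @ rng.standard_normal((len(x), n_fields))
    z -= z.mean(axis=0)
    sd = z.std(axis=0)
    sd[sd == 0] = 1.0
    return z / sd


def generate_environment(
    grid_width: int,
    grid_height: int,
    quadrat_size: float,
    autocorr_range: float,
    seed: int,
) -> EnvironmentGrid:
    """Grid of 4 topographic + 9 soil fields, each a Gaussian random
    field with exponential spatial correlation of the given range.

    All variables are standardized except aspect, which is wrapped to
    degrees in [0, 360).
    """
    if grid_width < 1 or grid_height < 1:
        raise ValidationError("grid dimensions must be >= 1")
    if autocorr_range <= 0:
        raise ValidationError("autocorr_range must be positive")
    if quadrat_size <= 0:
        raise ValidationError("quadrat_size must be positive")
    rng = np.random.default_rng(seed)
    fields = _gaussian_random_fields(
        grid_height, grid_width, quadrat_size, autocorr_range, len(ENV_VARS), rng
    )
    rr, cc = np.meshgrid(
        np.arange(grid_height), np.arange(grid_width), indexing="ij"
    )
    df = pd.DataFrame({"row": rr.ravel(), "col": cc.ravel()})
    for j, name in enumerate(ENV_VARS):
        if name == "aspect":
            df[name] = np.mod(180.0 + 120.0 * fields[:, j], 360.0)
        else:
            df[name] = fields[:, j]
    return EnvironmentGrid(grid_height, grid_width, quadrat_size, df)


# ---------------------------------------------------------------------------
# Stems
# ---------------------------------------------------------------------------

def place_individuals(
    optima: pd.Series,
    grid: EnvironmentGrid,
    axis: str,
    niche_breadth: float,
    mean_abundance: float,
    seed: int,
    stage: str = "adult",
) -> StemMap:
    """Place stems by an inhomogeneous Poisson process on quadrats.

    Per-quadrat intensity is proportional to
    ``exp(-(x_q - optimum)^2 / (2 * niche_breadth^2))`` and scaled so the
    expected total per species equals ``mean_abundance``; positions are
    uniform within each quadrat.
    """
    if niche_breadth <= 0:
        raise ValidationError("niche_breadth must be positive")
    if mean_abundance < 0:
        raise ValidationError("mean_abundance must be non-negative")
    rng = np.random.default_rng(seed)
    x_q = grid.axis_values(axis)
    n_q = grid.n_quadrats
    rows = np.repeat(np.arange(grid.n_rows), grid.n_cols)
    cols = np.tile(np.arange(grid.n_cols), grid.n_rows)
    qs = grid.quadrat_size

    records = []
    prefix = stage[0]
    for species in optima.index:
        opt = float(optima[species])
        d2 = (x_q - opt) ** 2
        w = np.exp(-(d2 - d2.min()) / (2.0 * niche_breadth**2))
        lam = mean_abundance * w / w.sum()
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        q_idx = np.repeat(np.arange(n_q), counts)
        u = rng.random((total, 2))
        xs = (cols[q_idx] + u[:, 0]) * qs
        ys = (rows[q_idx] + u[:, 1]) * qs
        for i in range(total):
            records.append(
                (f"{species}-{prefix}{i + 1:05d}", species, xs[i], ys[i], stage)
            )
    df = pd.DataFrame(records, columns=["tag", "species", "x", "y", "stage"])
    return StemMap(df, extent_x=grid.extent_x, extent_y=grid.extent_y)


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Bundle of generated objects plus the ground truth table."""

    config: SimulationConfig
    tree: PhylogeneticTree
    grid: EnvironmentGrid
    stems: StemMap
    optima: pd.Series
    truth: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the whole generator under one config (deterministic in seed).

    Seedlings and adults are placed as independent point processes with
    their own abundance parameters around the same niche optima.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(5)]
    tree = simulate_tree(config.n_species, seeds[0])
    optima = evolve_niche_optima(
        tree,
        config.bm_sigma2,
        config.conservatism_lambda,
        config.root_value,
        seeds[1],
    )
    grid = generate_environment(
        config.grid_width,
        config.grid_height,
        config.quadrat_size,
        config.autocorr_range,
        seeds[2],
    )
    adult = place_individuals(
        optima, grid, config.niche_axis, config.niche_breadth,
        config.mean_abundance, seeds[3], stage="adult",
    )
    seedling_ab = (
        config.mean_abundance
        if config.seedling_abundance is None
        else config.seedling_abundance
    )
    seedling = place_individuals(
        optima, grid, config.niche_axis, config.niche_breadth,
        seedling_ab, seeds[4], stage="seedling",
    )
    stems = StemMap(
        pd.concat([seedling.data, adult.data], ignore_index=True),
        extent_x=grid.extent_x,
        extent_y=grid.extent_y,
    )
    counts = stems.data.groupby(["species", "stage"]).size().unstack(fill_value=0)
    truth = pd.DataFrame(
        {
            "species": optima.index,
            "optimum": optima.to_numpy(),
            "n_seedling": counts.reindex(optima.index)
            .get("seedling", pd.Series(0, index=optima.index))
            .fillna(0)
            .astype(int)
            .to_numpy(),
            "n_adult": counts.reindex(optima.index)
            .get("adult", pd.Series(0, index=optima.index))
            .fillna(0)
            .astype(int)
            .to_numpy(),
        }
    )
    return SyntheticDataset(config, tree, grid, stems, optima, truth)
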