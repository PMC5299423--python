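"""Readers/writers and core data model: trees, stem maps, environment grids.

Conventions fixed here and used everywhere downstream:

* coordinates are 0-based metres; quadrat intervals are half-open
  ``[low, high)``, so a stem at ``x == extent_x`` is out of bounds;
* quadrat ``(row, col)`` is derived from ``(y, x)`` by integer division
  with the quadrat size;
* the circular ``aspect`` variable (degrees) is consumed downstream as
  ``northness = cos(aspect * pi / 180)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import NewickParseError, ValidationError

TOPO_VARS: tuple[str, ...] = ("aspect", "convexity", "elevation", "slope")
SOIL_VARS: tuple[str, ...] = tuple(f"soil_{i:02d}" for i in range(1, 10))
ENV_VARS: tuple[str, ...] = TOPO_VARS + SOIL_VARS
STAGES: tuple[str, ...] = ("seedling", "adult")


# ---------------------------------------------------------------------------
# Phylogenetic trees
# ---------------------------------------------------------------------------

class PhylogeneticTree:
    """A rooted, branch-lengthed tree over uniquely labelled tips.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the
    invariants the statistics need (unique labels, lengths on every
    non-root edge) and provides deterministic serialization.
    """

    def __init__(self, dtree: dendropy.Tree, strict: bool = True):
        self._dtree = dtree
        self._validate(strict=strict)

    # -- validation --------------------------------------------------------
    def _validate(self, strict: bool) -> None:
        labels = []
        for leaf in self._dtree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValidationError("tree has an unlabelled tip")
            labels.append(leaf.taxon.label)
        if len(labels) < 1:
            raise ValidationError("tree has no tips")
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise ValidationError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        root = self._dtree.seed_node
        for node in self._dtree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                label = node.taxon.label if node.taxon else "<internal>"
                if strict:
                    raise NewickParseError(
                        f"missing branch length on edge above {label}"
                    )
                warnings.warn(
                    f"imputing missing branch length above {label} as 0",
                    stacklevel=3,
                )
                node.edge.length = 0.0
            elif node.edge.length < 0:
                raise ValidationError("negative branch length")
        self._tip_labels = tuple(sorted(seen))

    # -- basic accessors ---------------------------------------------------
    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in sorted order (the canonical species order)."""
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    def node_depths(self) -> dict:
        """Root-to-node path length for every node (root depth 0)."""
        depths: dict = {}
        for node in self._dtree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        depths = self.node_depths()
        return max(depths[leaf] for leaf in self._dtree.leaf_node_iter())

    def subtree(self, labels) -> "PhylogeneticTree":
        """Restriction to ``labels``, suppressing unifurcations."""
        labels = sorted(set(labels))
        missing = [lab for lab in labels if lab not in self._tip_labels]
        if missing:
            raise ValidationError(f"labels not on tree: {missing}")
        if len(labels) < 2:
            raise ValidationError("subtree needs at least 2 tips")
        sub = self._dtree.extract_tree_with_taxa_labels(labels)
        return PhylogeneticTree(sub, strict=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhylogeneticTree):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    def __repr__(self) -> str:
        return f"PhylogeneticTree(n_tips={self.n_tips})"


def parse_newick(text: str, strict: bool = True) -> PhylogeneticTree:
    """Parse a Newick string into a validated :class:`PhylogeneticTree`.

    In strict mode (default) every non-root edge must carry a branch
    length; lenient mode imputes missing lengths as 0 with a warning.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    stripped = text.strip()
    if stripped.count("(") != stripped.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {stripped.count('(')} open "
            f"vs {stripped.count(')')} close"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon label" in str(exc):
            raise ValidationError(f"duplicate tip label: {exc}") from exc
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    return PhylogeneticTree(dtree, strict=strict)


def _min_tip_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return min(_min_tip_label(c) for c in node.child_nodes())


def _newick_node(node) -> str:
    if node.is_leaf():
        name = node.taxon.label
    else:
        children = sorted(node.child_nodes(), key=_min_tip_label)
        name = "(" + ",".join(_newick_node(c) for c in children) + ")"
    if node.parent_node is None:
        return name
    return f"{name}:{float(node.edge.length)!r}"


def write_newick(tree: PhylogeneticTree) -> str:
    """Serialize with children ordered by smallest descendant label.

    Deterministic: isomorphic trees with equal lengths produce identical
    strings.
    """
    return _newick_node(tree.dendropy_tree.seed_node) + ";"


def read_newick_file(path, strict: bool = True) -> PhylogeneticTree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read(), strict=strict)


def write_newick_file(tree: PhylogeneticTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Stem maps
# ---------------------------------------------------------------------------

@dataclass
class StemMap:
    """Mapped stems: tag, species, x, y (metres), life stage.

    ``data`` columns: tag, species, x, y, stage. Coordinates live in
    ``[0, extent_x) x [0, extent_y)``.
    """

    data: pd.DataFrame
    extent_x: float
    extent_y: float

    def __post_init__(self) -> None:
        required = ["tag", "species", "x", "y", "stage"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"stem table missing columns: {missing}")
        self.data = self.data[required].reset_index(drop=True)
        if len(self.data):
            if self.data["tag"].duplicated().any():
                dupes = self.data.loc[self.data["tag"].duplicated(), "tag"]
                raise ValidationError(
                    f"duplicate stem tags: {sorted(set(dupes))[:5]}"
                )
            bad_stage = ~self.data["stage"].isin(STAGES)
            if bad_stage.any():
                raise ValidationError(
                    f"unknown stages in rows {list(self.data.index[bad_stage][:5])}"
                )
            x = self.data["x"].to_numpy(float)
            y = self.data["y"].to_numpy(float)
            out = (x < 0) | (x >= self.extent_x) | (y < 0) | (y >= self.extent_y)
            if out.any():
                raise ValidationError(
                    "stems outside plot extent at rows "
                    f"{list(self.data.index[out][:10])}"
                )

    def __len__(self) -> int:
        return len(self.data)

    def filter_stage(self, stage: str) -> "StemMap":
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}")
        return StemMap(
            self.data[self.data["stage"] == stage].reset_index(drop=True),
            self.extent_x,
            self.extent_y,
        )

    def abundance(self, stage: str | None = None) -> pd.Series:
        """Stem counts per species, optionally restricted to a stage."""
        df = self.data if stage is None else self.data[self.data["stage"] == stage]
        return df.groupby("species").size().sort_index()

    def quadrat_indices(self, quadrat_size: float) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) per stem: floor division, half-open intervals."""
        row = np.floor(self.data["y"].to_numpy(float) / quadrat_size).astype(int)
        col = np.floor(self.data["x"].to_numpy(float) / quadrat_size).astype(int)
        return row, col

    def counts_grid(
        self,
        species: str,
        n_rows: int,
        n_cols: int,
        quadrat_size: float,
        stage: str | None = None,
    ) -> np.ndarray:
        """Per-quadrat stem counts of one species as an (n_rows, n_cols) array."""
        mask = self.data["species"] == species
        if stage is not None:
            mask &= self.data["stage"] == stage
        row, col = self.quadrat_indices(quadrat_size)
        counts = np.zeros((n_rows, n_cols), dtype=np.int64)
        np.add.at(counts, (row[mask.to_numpy()], col[mask.to_numpy()]), 1)
        return counts


# ---------------------------------------------------------------------------
# Environment grids
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentGrid:
    """Rectangular lattice of quadrats with topographic + soil variables.

    ``data`` holds one row per quadrat in row-major order with columns
    row, col, the 13 environment variables, and any appended soil-PCA
    score columns.
    """

    n_rows: int
    n_cols: int
    quadrat_size: float
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.quadrat_size <= 0:
            raise ValidationError("quadrat_size must be positive")
        missing = [c for c in ("row", "col", *ENV_VARS) if c not in self.data.columns]
        if missing:
            raise ValidationError(f"environment table missing columns: {missing}")
        expected = self.n_rows * self.n_cols
        if len(self.data) != expected:
            raise ValidationError(
                f"non-rectangular grid: {len(self.data)} quadrats, "
                f"expected {expected}"
            )
        pairs = set(zip(self.data["row"], self.data["col"]))
        if len(pairs) != expected:
            raise ValidationError("duplicate or missing quadrats in grid")
        self.data = (
            self.data.sort_values(["row", "col"]).reset_index(drop=True)
        )

    @property
    def n_quadrats(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent_x(self) -> float:
        return self.n_cols * self.quadrat_size

    @property
    def extent_y(self) -> float:
        return self.n_rows * self.quadrat_size

    def field(self, name: str) -> np.ndarray:
        """Variable as an (n_rows, n_cols) array; 'northness' is derived."""
        if name == "northness":
            aspect = self.field("aspect")
            return np.cos(np.radians(aspect))
        if name not in self.data.columns:
            raise ValidationError(f"unknown environment variable {name!r}")
        return (
            self.data[name].to_numpy(float).reshape(self.n_rows, self.n_cols)
        )

    def axis_values(self, axis: str) -> np.ndarray:
        """Flattened (row-major) per-quadrat values of an analysis axis.

        ``aspect`` is mapped to northness before any linear treatment.
        """
        if axis == "aspect":
            axis = "northness"
        return self.field(axis).ravel()


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def _sniff_delimiter(path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_stem_table(path, extent_x: float, extent_y: float) -> StemMap:
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    return StemMap(df, extent_x=extent_x, extent_y=extent_y)


def read_environment_table(path, quadrat_size: float) -> EnvironmentGrid:
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    if "row" not in df.columns or "col" not in df.columns:
        raise ValidationError("environment table needs 'row' and 'col' columns")
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    return EnvironmentGrid(n_rows, n_cols, quadrat_size, df)


def read_plot_tables(
    stem_path, env_path, quadrat_size: float = 20.0
) -> tuple[StemMap, EnvironmentGrid]:
    """Read and cross-validate the stem and environment tables.

    Plot extent is inferred from the environment grid; stems must fall
    inside it (half-open intervals).
    """
    grid = read_environment_table(env_path, quadrat_size)
    stems = read_stem_table(stem_path, grid.extent_x, grid.extent_y)
    return stems, grid


def write_stem_table(stem_map: StemMap, path, sep: str = "\t") -> None:
    stem_map.data.to_csv(path, sep=sep, index=False, float_format="%.10g")


def write_environment_table(grid: EnvironmentGrid, path, sep: str = "\t") -> None:
    grid.data.to_csv(path, sep=sep, index=False, float_format="%.10g")
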