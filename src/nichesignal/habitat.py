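"""Habitat classification and torus-translation association tests.

Quadrats are clustered on standardized topography into habitat classes
(named valley/slope/ridge for k=3), and species-habitat association is
tested against a null built from toroidal translations of the habitat
map (optionally including its rotated and mirrored variants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import DegenerateInputError, ValidationError
from .io_formats import EnvironmentGrid, StemMap

CLASSIFICATION_VARS = ("northness", "convexity", "elevation", "slope")


@dataclass
class HabitatMap:
    """Per-quadrat habitat labels on the analysis lattice.

    ``labels`` holds integer classes in ``[0, k)``; ``names[i]`` is the
    display name of class ``i``.
    """

    labels: np.ndarray  # (n_rows, n_cols) ints
    names: tuple[str, ...]
    quadrat_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValidationError("habitat labels must be a 2-D grid")
        if self.quadrat_size <= 0:
            raise ValidationError("quadrat_size must be positive")
        present = np.unique(self.labels)
        k = len(self.names)
        if present.min() < 0 or present.max() >= k:
            raise ValidationError("habitat labels outside [0, k)")
        if len(present) != k:
            missing = sorted(set(range(k)) - set(present.tolist()))
            raise ValidationError(
                f"habitats never used: {[self.names[i] for i in missing]}"
            )

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def n_rows(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.labels.shape[1]

    def quadrat_counts(self) -> pd.Series:
        counts = np.bincount(self.labels.ravel(), minlength=self.k)
        return pd.Series(counts, index=list(self.names), name="n_quadrats")

    def index_of(self, habitat: str | int) -> int:
        if isinstance(habitat, str):
            if habitat not in self.names:
                raise ValidationError(f"unknown habitat {habitat!r}")
            return self.names.index(habitat)
        if not 0 <= int(habitat) < self.k:
            raise ValidationError(f"habitat index {habitat} out of range")
        return int(habitat)


def write_habitat_map(hmap: HabitatMap, path) -> None:
    """Grid CSV of habitat names, one row of the lattice per line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# quadrat_size=%g names=%s\n" % (
            hmap.quadrat_size, ",".join(hmap.names)))
        for r in range(hmap.n_rows):
            fh.write(",".join(hmap.names[i] for i in hmap.labels[r]) + "\n")


def read_habitat_map(path) -> HabitatMap:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        rows = [line.strip().split(",") for line in fh if line.strip()]
    if not header.startswith("#"):
        raise ValidationError("habitat map file missing header line")
    meta = dict(item.split("=", 1) for item in header[1:].split())
    names = tuple(meta["names"].split(","))
    index = {n: i for i, n in enumerate(names)}
    labels = np.array([[index[cell] for cell in row] for row in rows])
    return HabitatMap(labels, names, float(meta["quadrat_size"]))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean()
    sd = x.std()
    return np.zeros_like(x) if sd == 0 else (x - mu) / sd


def classify_habitats(
    grid: EnvironmentGrid, k: int = 3, seed: int = 0
) -> HabitatMap:
    """K-means on standardized {northness, convexity, elevation, slope}.

    For k=3 classes are named by topographic position: lowest mean
    elevation -> valley; of the rest, higher mean convexity -> ridge,
    the other -> slope. Other k get generic names ordered by elevation.
    Deterministic for fixed inputs and seed.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > grid.n_quadrats:
        raise ValidationError("k exceeds number of quadrats")
    feats = np.column_stack(
        [_standardize(grid.axis_values(v)) for v in CLASSIFICATION_VARS]
    )
    if k == 1:
        raw = np.zeros(grid.n_quadrats, dtype=int)
    else:
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        raw = km.fit_predict(feats)

    elev = grid.axis_values("elevation")
    conv = grid.axis_values("convexity")
    mean_elev = np.array([elev[raw == c].mean() for c in range(k)])
    if k == 3:
        valley = int(np.argmin(mean_elev))
        rest = [c for c in range(k) if c != valley]
        mean_conv = {c: conv[raw == c].mean() for c in rest}
        ridge = max(rest, key=lambda c: mean_conv[c])
        slope = next(c for c in rest if c != ridge)
        order = [valley, slope, ridge]
        names: tuple[str, ...] = ("valley", "slope", "ridge")
    else:
        order = list(np.argsort(mean_elev, kind="stable"))
        names = tuple(f"habitat_{i + 1}" for i in range(k))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    labels = remap[raw].reshape(grid.n_rows, grid.n_cols)
    return HabitatMap(labels, names, grid.quadrat_size)


# ---------------------------------------------------------------------------
# Association statistics
# ---------------------------------------------------------------------------

def _species_counts(stem_map: StemMap, hmap: HabitatMap, species: str,
                    stage: str | None = None) -> np.ndarray:
    counts = stem_map.counts_grid(
        species, hmap.n_rows, hmap.n_cols, hmap.quadrat_size, stage=stage
    )
    if counts.sum() == 0:
        raise DegenerateInputError(
            f"species {species!r} has no stems"
            + (f" at stage {stage!r}" if stage else "")
        )
    return counts


def habitat_relative_density(
    stem_map: StemMap,
    hmap: HabitatMap,
    species: str,
    habitat: str | int,
    stage: str | None = None,
) -> float:
    """Stems of ``species`` per quadrat of ``habitat``."""
    h = hmap.index_of(habitat)
    counts = _species_counts(stem_map, hmap, species, stage)
    n_quadrats = int((hmap.labels == h).sum())
    return float(counts[hmap.labels == h].sum()) / n_quadrats


class TorusNull:
    """Precomputed torus-translation null for one habitat map.

    The null set contains every toroidal translation (by whole quadrats)
    of the habitat map — identity included — and, when reflections are
    on, the translations of the 180-degree rotation and the two mirror
    images as well. Precomputing the per-habitat masks lets many species
    be tested against the same map cheaply.
    """

    def __init__(self, hmap: HabitatMap, include_reflections: bool = True):
        self.hmap = hmap
        self.include_reflections = include_reflections
        lab = hmap.labels
        variants = [lab]
        if include_reflections:
            variants += [lab[::-1, ::-1], lab[:, ::-1], lab[::-1, :]]
        nr, nc = lab.shape
        shifts = []
        for variant in variants:
            for dr in range(nr):
                for dc in range(nc):
                    shifts.append(np.roll(variant, (dr, dc), axis=(0, 1)))
        stack = np.stack(shifts)  # (n_maps, nr, nc)
        self.n_translations = stack.shape[0]
        # one-hot per habitat: (k, n_maps, nr*nc) as float for matmul
        flat = stack.reshape(self.n_translations, nr * nc)
        self._masks = np.stack(
            [(flat == h).astype(float) for h in range(hmap.k)]
        )
        self._hab_quadrats = np.array(
            [(lab == h).sum() for h in range(hmap.k)], dtype=float
        )
        if (self._hab_quadrats == 0).any():
            raise ValidationError("habitat with zero quadrats")

    def null_densities(self, counts: np.ndarray) -> np.ndarray:
        """(k, n_maps) relative densities; column 0 is the observed map."""
        c = counts.ravel().astype(float)
        return (self._masks @ c) / self._hab_quadrats[:, None]


def _tie_mean_quantile(null: np.ndarray, observed: float) -> float:
    """Mean rank of the observed among the null values, as a fraction."""
    less = int((null < observed).sum())
    equal = int((null == observed).sum())
    rank = less + (equal + 1) / 2.0
    return rank / len(null)


def torus_translation_test(
    stem_map: StemMap,
    hmap: HabitatMap,
    species: str,
    alpha: float = 0.025,
    include_reflections: bool = True,
    stage: str | None = None,
    null: TorusNull | None = None,
) -> pd.DataFrame:
    """Association of one species with every habitat.

    Returns one row per habitat with the observed relative density, the
    null quantile (mean rank for ties), and a verdict: positive if
    quantile > 1 - alpha, negative if quantile < alpha, else neutral.
    """
    if not 0.0 < alpha < 0.5:
        raise ValidationError("alpha must lie in (0, 0.5)")
    if null is None:
        null = TorusNull(hmap, include_reflections=include_reflections)
    elif null.include_reflections != include_reflections:
        raise ValidationError("precomputed null disagrees on reflections")
    counts = _species_counts(stem_map, hmap, species, stage)
    dens = null.null_densities(counts)
    rows = []
    for h, name in enumerate(hmap.names):
        observed = float(
            counts[hmap.labels == h].sum() / (hmap.labels == h).sum()
        )
        q = _tie_mean_quantile(dens[h], observed)
        if q > 1.0 - alpha:
            verdict = "positive"
        elif q < alpha:
            verdict = "negative"
        else:
            verdict = "neutral"
        rows.append(
            {
                "species": species,
                "habitat": name,
                "relative_density": observed,
                "quantile": q,
                "verdict": verdict,
                "alpha": alpha,
                "n_translations": null.n_translations,
            }
        )
    return pd.DataFrame(rows)


def torus_translation_tests(
    stem_map: StemMap,
    hmap: HabitatMap,
    species_list,
    alpha: float = 0.025,
    include_reflections: bool = True,
    stage: str | None = None,
) -> pd.DataFrame:
    """Batch torus tests sharing one precomputed null."""
    null = TorusNull(hmap, include_reflections=include_reflections)
    frames = [
        torus_translation_test(
            stem_map, hmap, sp, alpha=alpha,
            include_reflections=include_reflections, stage=stage, null=null,
        )
        for sp in species_list
    ]
    return pd.concat(frames, ignore_index=True)
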