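"""Soil PCA and conditional-probability niche estimation.

The niche of a species on an environmental axis is the axis value at
which the conditional occurrence probability p(E|x) — the probability
that the species occupies a quadrat given the quadrat's value is x —
reaches its maximum. The estimator is a binned (histogram) Bayes
estimate over quadrats: occupied quadrats / total quadrats per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, ValidationError
from .io_formats import SOIL_VARS, EnvironmentGrid, StemMap

#: axes over which niches are estimated (aspect enters as northness)
TOPO_AXES = ("aspect", "convexity", "elevation", "slope")
SOIL_PCA_AXES = ("soil_pca_1", "soil_pca_2", "soil_pca_3")
DEFAULT_AXES = TOPO_AXES + SOIL_PCA_AXES


@dataclass
class SoilPcaResult:
    """PCA of the standardized soil variables.

    ``explained`` covers every possible axis (sums to 1); ``scores`` and
    ``loadings`` are restricted to the requested leading axes.
    """

    n_axes: int
    scores: pd.DataFrame           # n_quadrats x n_axes
    loadings: pd.DataFrame         # soil variables x n_axes
    explained: np.ndarray          # all component variance fractions

    @property
    def explained_selected(self) -> np.ndarray:
        return self.explained[: self.n_axes]


def soil_pca(grid: EnvironmentGrid, n_axes: int = 3) -> SoilPcaResult:
    """PCA on standardized soil nutrients; scores appended to the grid.

    Sign convention: each loading vector is oriented so its
    largest-magnitude element is positive.
    """
    if not 1 <= n_axes <= len(SOIL_VARS):
        raise ValidationError(f"n_axes must lie in [1, {len(SOIL_VARS)}]")
    X = grid.data[list(SOIL_VARS)].to_numpy(float)
    sd = X.std(axis=0)
    constant = [v for v, s in zip(SOIL_VARS, sd) if s == 0]
    if constant:
        raise DegenerateInputError(f"constant soil columns: {constant}")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=None)
    scores = pca.fit_transform(Z)
    comps = pca.components_  # (n_comp, n_vars)
    for j in range(comps.shape[0]):
        i = int(np.argmax(np.abs(comps[j])))
        if comps[j, i] < 0:
            comps[j] *= -1
            scores[:, j] *= -1
    cols = [f"soil_pca_{j + 1}" for j in range(n_axes)]
    score_df = pd.DataFrame(scores[:, :n_axes], columns=cols)
    grid.data[cols] = score_df.to_numpy()
    loadings = pd.DataFrame(
        comps[:n_axes].T, index=list(SOIL_VARS), columns=cols
    )
    return SoilPcaResult(
        n_axes=n_axes,
        scores=score_df,
        loadings=loadings,
        explained=pca.explained_variance_ratio_.copy(),
    )


@dataclass
class NicheEstimate:
    """p(E|x) curve on one axis and its argmax (the niche value)."""

    species: str
    axis: str
    bin_edges: np.ndarray
    bin_mids: np.ndarray
    curve: np.ndarray          # p(E|x) per bin; NaN where bin is empty
    bin_quadrats: np.ndarray   # quadrats per bin
    niche_value: float
    niche_bin: int
    support: int               # occupied-quadrat count


def occupancy_grid(
    stem_map: StemMap,
    grid: EnvironmentGrid,
    species: str,
    stage: str | None = None,
) -> np.ndarray:
    """Boolean presence of a species per quadrat."""
    counts = stem_map.counts_grid(
        species, grid.n_rows, grid.n_cols, grid.quadrat_size, stage=stage
    )
    return counts > 0


def conditional_probability_niche(
    occurrence,
    grid: EnvironmentGrid,
    species: str,
    axis: str,
    n_bins: int = 20,
    min_bin_quadrats: int = 5,
    stage: str | None = None,
    smooth_bandwidth: float | None = None,
) -> NicheEstimate:
    """Binned estimate of p(E|x) and its maximizing axis value.

    ``occurrence`` is either a :class:`StemMap` or a boolean per-quadrat
    occupancy array. Bins with fewer than ``min_bin_quadrats`` quadrats
    are excluded from the argmax. Ties are broken toward the bin with
    more occupied quadrats, then toward smaller x. An optional Gaussian
    smoothing of the curve (bandwidth in bins) is off by default.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if isinstance(occurrence, StemMap):
        occ = occupancy_grid(occurrence, grid, species, stage=stage)
    else:
        occ = np.asarray(occurrence, dtype=bool)
        if occ.shape != (grid.n_rows, grid.n_cols):
            raise ValidationError("occupancy shape does not match grid")
    support = int(occ.sum())
    if support == 0:
        raise DegenerateInputError(
            f"species {species!r} occupies no quadrat"
            + (f" at stage {stage!r}" if stage else "")
        )

    x = grid.axis_values(axis)
    occ_flat = occ.ravel()
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise DegenerateInputError(f"axis {axis!r} is constant over the grid")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    totals = np.bincount(idx, minlength=n_bins)
    occupied = np.bincount(idx, weights=occ_flat.astype(float),
                           minlength=n_bins)
    with np.errstate(invalid="ignore"):
        curve = np.where(totals > 0, occupied / np.maximum(totals, 1), np.nan)
    if smooth_bandwidth is not None and smooth_bandwidth > 0:
        filled = np.where(np.isnan(curve), 0.0, curve)
        weight = (totals > 0).astype(float)
        num = gaussian_filter1d(filled * weight, smooth_bandwidth,
                                mode="nearest")
        den = gaussian_filter1d(weight, smooth_bandwidth, mode="nearest")
        curve = np.where(den > 0, num / den, np.nan)

    eligible = totals >= min_bin_quadrats
    if not eligible.any():
        raise DegenerateInputError(
            f"all bins below min_bin_quadrats={min_bin_quadrats} "
            f"for axis {axis!r}"
        )
    # argmax among eligible bins; ties -> more occupied quadrats -> smaller x
    cand = np.flatnonzero(eligible)
    vals = curve[cand]
    best = vals == np.nanmax(vals)
    cand = cand[best]
    if len(cand) > 1:
        occ_counts = occupied[cand]
        cand = cand[occ_counts == occ_counts.max()]
    niche_bin = int(cand[0])
    mids = 0.5 * (edges[:-1] + edges[1:])
    return NicheEstimate(
        species=species,
        axis=axis,
        bin_edges=edges,
        bin_mids=mids,
        curve=curve,
        bin_quadrats=totals,
        niche_value=float(mids[niche_bin]),
        niche_bin=niche_bin,
        support=support,
    )


def niche_table(
    stem_map: StemMap,
    grid: EnvironmentGrid,
    species_list,
    axes=DEFAULT_AXES,
    n_bins: int = 20,
    min_bin_quadrats: int = 5,
    stage: str | None = None,
) -> pd.DataFrame:
    """Long-format table of niche values: species x axis rows."""
    rows = []
    for sp in species_list:
        occ = occupancy_grid(stem_map, grid, sp, stage=stage)
        for axis in axes:
            est = conditional_probability_niche(
                occ, grid, sp, axis, n_bins=n_bins,
                min_bin_quadrats=min_bin_quadrats,
            )
            rows.append(
                {
                    "species": sp,
                    "stage": stage if stage is not None else "all",
                    "axis": axis,
                    "niche_value": est.niche_value,
                    "support": est.support,
                }
            )
    return pd.DataFrame(rows)
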