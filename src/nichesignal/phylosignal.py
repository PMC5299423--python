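"""Phylogenetic signal statistics and their permutation nulls.

Three families:

* Blomberg's K for continuous traits, with a tip-shuffle permutation
  test (one-tailed on large K);
* Sankoff parsimony scores for categorical states, with a tip-shuffle
  permutation test (one-tailed on small scores);
* NRI/NTI: standardized effect sizes of MPD/MNTD for a species group
  against random draws from a species pool, signed so that positive
  values mean phylogenetic clustering.

All permutation machinery is vectorized so calibration experiments with
hundreds of thousands of permutations stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .io_formats import PhylogeneticTree

__all__ = [
    "phylo_covariance",
    "patristic_distance_matrix",
    "KCalculator",
    "blomberg_k",
    "k_permutation_test",
    "sankoff_score",
    "sankoff_permutation_test",
    "pairwise_dispersion",
    "ses_dispersion",
    "SignalResult",
    "DispersionResult",
]


# ---------------------------------------------------------------------------
# Tree matrices
# ---------------------------------------------------------------------------

def phylo_covariance(tree: PhylogeneticTree) -> tuple[np.ndarray, tuple[str, ...]]:
    """Shared-path covariance matrix V and its (sorted) species order.

    ``V[i, j]`` is the root-to-MRCA path length of tips i and j; the
    diagonal holds root-to-tip depths.
    """
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    depths = tree.node_depths()
    tipsets: dict = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            V[i, i] = depths[node]
            tipsets[node] = [i]
        else:
            children = [tipsets.pop(c) for c in node.child_nodes()]
            d = depths[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    ia = np.array(children[a])
                    ib = np.array(children[b])
                    V[np.ix_(ia, ib)] = d
                    V[np.ix_(ib, ia)] = d
            tipsets[node] = [i for sub in children for i in sub]
    return V, labels


def patristic_distance_matrix(
    tree: PhylogeneticTree,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Sum of branch lengths between every pair of tips."""
    V, labels = phylo_covariance(tree)
    d = np.diag(V)
    return d[:, None] + d[None, :] - 2.0 * V, labels


def _align_trait(trait, labels: tuple[str, ...]) -> np.ndarray:
    """Trait mapping -> vector in tree order, with strict label checks."""
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    if not isinstance(trait, dict):
        raise ValidationError("trait must be a mapping or Series")
    missing = [lab for lab in labels if lab not in trait]
    extra = [lab for lab in trait if lab not in labels]
    if missing or extra:
        raise ValidationError(
            f"tip/trait mismatch: missing {missing[:5]}, extra {extra[:5]}"
        )
    return np.array([float(trait[lab]) for lab in labels])


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

class KCalculator:
    """Precomputed pieces of the K statistic for one tree.

    K = (MSE0 / MSE) / ((tr V - n / (1' V^-1 1)) / (n - 1)) with the GLS
    phylogenetic mean a = (1' V^-1 X) / (1' V^-1 1), MSE0 the ordinary
    mean squared deviation from a, and MSE the V-weighted one. Reused
    across many trait vectors (e.g. permutations) via :meth:`k_many`.
    """

    def __init__(self, tree: PhylogeneticTree):
        V, labels = phylo_covariance(tree)
        n = len(labels)
        if n < 3:
            raise ValidationError("Blomberg's K needs at least 3 tips")
        self.labels = labels
        self.n = n
        self.V = V
        self.Vinv = np.linalg.inv(V)
        ones = np.ones(n)
        self.w = self.Vinv @ ones
        self.sum_vinv = float(ones @ self.w)
        self.expected_ratio = (
            (np.trace(V) - n / self.sum_vinv) / (n - 1)
        )

    def k_many(self, X: np.ndarray) -> np.ndarray:
        """K per column of an (n, m) trait matrix."""
        X = np.atleast_2d(X.T).T  # ensure 2-D with columns = traits
        if (X.max(axis=0) == X.min(axis=0)).any():
            raise DegenerateInputError("constant trait has undefined K")
        a = (self.w @ X) / self.sum_vinv
        R = X - a[None, :]
        mse0 = np.einsum("ij,ij->j", R, R) / (self.n - 1)
        mse = np.einsum("ij,ij->j", R, self.Vinv @ R) / (self.n - 1)
        return (mse0 / mse) / self.expected_ratio

    def k(self, x: np.ndarray) -> float:
        return float(self.k_many(x[:, None])[0])


def blomberg_k(tree: PhylogeneticTree, trait) -> float:
    """Blomberg's K of a continuous trait on a tree.

    Invariant to affine transforms of the trait and to rescaling all
    branch lengths by a common factor. Raises for constant traits.
    """
    calc = KCalculator(tree)
    x = _align_trait(trait, calc.labels)
    return calc.k(x)


@dataclass
class SignalResult:
    """Observed statistic plus its permutation null summary."""

    statistic: str
    observed: float
    n_perm: int
    p_value: float
    seed: int
    null: np.ndarray = field(repr=False, default=None)


def _permutation_matrix(
    x: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, n_perm) matrix whose columns are shuffles of x."""
    n = len(x)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    return x[order].T


def k_permutation_test(
    tree: PhylogeneticTree,
    trait,
    n_perm: int = 999,
    seed: int = 0,
    calculator: KCalculator | None = None,
) -> SignalResult:
    """Tip-shuffle null for K; p = (1 + #{K_perm >= K_obs}) / (1 + n_perm)."""
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    calc = calculator if calculator is not None else KCalculator(tree)
    x = _align_trait(trait, calc.labels)
    rng = np.random.default_rng(seed)
    observed = calc.k(x)
    null = calc.k_many(_permutation_matrix(x, n_perm, rng))
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return SignalResult("K", observed, n_perm, p, seed, null)


# ---------------------------------------------------------------------------
# Sankoff parsimony
# ---------------------------------------------------------------------------

def _resolve_states(tip_states: dict, states) -> tuple[tuple, np.ndarray]:
    observed = set(tip_states.values())
    if states is None:
        states = tuple(sorted(observed))
    else:
        states = tuple(states)
        bad = observed - set(states)
        if bad:
            raise ValidationError(f"tip states not in alphabet: {sorted(bad)}")
    return states, np.array(states, dtype=object)


def _validate_cost(cost_matrix, k: int) -> np.ndarray:
    if cost_matrix is None:
        return 1.0 - np.eye(k)
    C = np.asarray(cost_matrix, dtype=float)
    if C.shape != (k, k):
        raise ValidationError(
            f"cost matrix shape {C.shape} does not match {k} states"
        )
    if (np.diag(C) != 0).any():
        raise ValidationError("cost matrix diagonal must be zero")
    if (C < 0).any():
        raise ValidationError("cost matrix must be non-negative")
    return C


def _sankoff_many(
    tree: PhylogeneticTree,
    tip_idx: np.ndarray,  # (n_tips, m) state indices in tree.tip_labels order
    C: np.ndarray,
) -> np.ndarray:
    """Minimum total cost per column, by leaf-to-root dynamic programming."""
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    k = C.shape[0]
    m = tip_idx.shape[1]
    inf = np.inf
    costs: dict = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.full((m, k), inf)
            vec[np.arange(m), tip_idx[index[node.taxon.label]]] = 0.0
            costs[node] = vec
        else:
            total = np.zeros((m, k))
            for child in node.child_nodes():
                child_cost = costs.pop(child)  # (m, k)
                # min over child state j of child_cost[:, j] + C[s, j]
                total += np.min(
                    child_cost[:, None, :] + C[None, :, :], axis=2
                )
            costs[node] = total
    root_cost = costs[tree.dendropy_tree.seed_node]
    return root_cost.min(axis=1)


def sankoff_score(
    tree: PhylogeneticTree,
    tip_states,
    cost_matrix=None,
    states=None,
) -> float:
    """Minimum total transition cost of a categorical character.

    With the default unit off-diagonal cost matrix this is the minimum
    number of state changes on the tree.
    """
    if isinstance(tip_states, pd.Series):
        tip_states = tip_states.to_dict()
    labels = tree.tip_labels
    missing = [lab for lab in labels if lab not in tip_states]
    if missing:
        raise ValidationError(f"tips without a state: {missing[:5]}")
    states, _ = _resolve_states(tip_states, states)
    C = _validate_cost(cost_matrix, len(states))
    sidx = {s: i for i, s in enumerate(states)}
    tip_idx = np.array([[sidx[tip_states[lab]]] for lab in labels])
    return float(_sankoff_many(tree, tip_idx, C)[0])


def sankoff_permutation_test(
    tree: PhylogeneticTree,
    tip_states,
    cost_matrix=None,
    states=None,
    n_perm: int = 999,
    seed: int = 0,
) -> SignalResult:
    """Tip-shuffle null for the parsimony score.

    Low scores mean conserved states, so
    p = (1 + #{S_perm <= S_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if isinstance(tip_states, pd.Series):
        tip_states = tip_states.to_dict()
    labels = tree.tip_labels
    missing = [lab for lab in labels if lab not in tip_states]
    if missing:
        raise ValidationError(f"tips without a state: {missing[:5]}")
    states, _ = _resolve_states(tip_states, states)
    C = _validate_cost(cost_matrix, len(states))
    sidx = {s: i for i, s in enumerate(states)}
    x = np.array([sidx[tip_states[lab]] for lab in labels])
    rng = np.random.default_rng(seed)
    perm = _permutation_matrix(x, n_perm, rng)
    all_cols = np.column_stack([x, perm])
    scores = _sankoff_many(tree, all_cols, C)
    observed, null = float(scores[0]), scores[1:]
    p = (1 + int((null <= observed).sum())) / (1 + n_perm)
    return SignalResult("sankoff", observed, n_perm, p, seed, null)


# ---------------------------------------------------------------------------
# NRI / NTI
# ---------------------------------------------------------------------------

def _group_indices(group, labels: tuple[str, ...]) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    missing = [g for g in group if g not in index]
    if missing:
        raise ValidationError(f"group members not on tree: {missing[:5]}")
    idx = sorted(index[g] for g in set(group))
    return np.array(idx, dtype=int)


def _mpd_mntd(D: np.ndarray) -> tuple[float, float]:
    g = D.shape[0]
    iu = np.triu_indices(g, k=1)
    mpd = float(D[iu].mean())
    D_off = D + np.diag(np.full(g, np.inf))
    mntd = float(D_off.min(axis=1).mean())
    return mpd, mntd


def pairwise_dispersion(tree: PhylogeneticTree, group) -> tuple[float, float]:
    """(MPD, MNTD): mean pairwise / mean nearest-neighbour patristic
    distance among the group's species."""
    D, labels = patristic_distance_matrix(tree)
    idx = _group_indices(group, labels)
    if len(idx) < 2:
        raise DegenerateInputError("dispersion needs at least 2 species")
    return _mpd_mntd(D[np.ix_(idx, idx)])


@dataclass
class DispersionResult:
    group: str
    n_species: int
    mpd_obs: float
    mntd_obs: float
    mpd_null_mean: float
    mpd_null_sd: float
    mntd_null_mean: float
    mntd_null_sd: float
    nri: float
    nti: float
    p_mpd: float
    p_mntd: float
    n_null: int
    seed: int


def ses_dispersion(
    tree: PhylogeneticTree,
    group,
    species_pool,
    n_null: int = 999,
    seed: int = 0,
    group_label: str = "",
) -> DispersionResult:
    """NRI/NTI of a group against random draws from the pool.

    Null: ``n_null`` draws of ``len(group)`` species from the pool
    without replacement. NRI = -(MPD_obs - mean) / sd and NTI likewise
    with MNTD, so positive values indicate phylogenetic clustering.
    p per metric is the clustering tail: (1 + #{null <= obs}) / (1 + n_null).
    """
    D, labels = patristic_distance_matrix(tree)
    pool = sorted(set(species_pool))
    gset = set(group)
    if not gset <= set(pool):
        raise ValidationError("group must be a subset of the species pool")
    if gset == set(pool):
        raise DegenerateInputError("group equals pool: null is degenerate")
    gidx = _group_indices(group, labels)
    pidx = _group_indices(pool, labels)
    g, p_n = len(gidx), len(pidx)
    if g < 2:
        raise DegenerateInputError("dispersion needs at least 2 species")

    mpd_obs, mntd_obs = _mpd_mntd(D[np.ix_(gidx, gidx)])

    rng = np.random.default_rng(seed)
    Dp = D[np.ix_(pidx, pidx)]
    draws = np.argsort(rng.random((n_null, p_n)), axis=1)[:, :g]
    sub = Dp[draws[:, :, None], draws[:, None, :]]  # (n_null, g, g)
    iu = np.triu_indices(g, k=1)
    mpd_null = sub[:, iu[0], iu[1]].mean(axis=1)
    sub_inf = sub + np.diag(np.full(g, np.inf))[None, :, :]
    mntd_null = sub_inf.min(axis=2).mean(axis=1)

    if mpd_null.std() == 0 or mntd_null.std() == 0:
        raise DegenerateInputError("null distribution has zero variance")
    nri = -(mpd_obs - mpd_null.mean()) / mpd_null.std()
    nti = -(mntd_obs - mntd_null.mean()) / mntd_null.std()
    p_mpd = (1 + int((mpd_null <= mpd_obs).sum())) / (1 + n_null)
    p_mntd = (1 + int((mntd_null <= mntd_obs).sum())) / (1 + n_null)
    return DispersionResult(
        group=group_label,
        n_species=g,
        mpd_obs=mpd_obs,
        mntd_obs=mntd_obs,
        mpd_null_mean=float(mpd_null.mean()),
        mpd_null_sd=float(mpd_null.std()),
        mntd_null_mean=float(mntd_null.mean()),
        mntd_null_sd=float(mntd_null.std()),
        nri=float(nri),
        nti=float(nti),
        p_mpd=float(p_mpd),
        p_mntd=float(p_mntd),
        n_null=n_null,
        seed=seed,
    )
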