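import itertools

import numpy as np
import pytest
from scipy.linalg import cho_factor, cho_solve

from nichesignal.errors import DegenerateInputError, ValidationError
from nichesignal.io_formats import parse_newick
from nichesignal.phylosignal import (
    KCalculator,
    blomberg_k,
    k_permutation_test,
    pairwise_dispersion,
    patristic_distance_matrix,
    phylo_covariance,
    sankoff_permutation_test,
    sankoff_score,
    ses_dispersion,
)
from nichesignal.synthetic_data import evolve_niche_optima, simulate_tree

from .conftest import make_balanced_newick, random_tree

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def covariance_oracle(tree):
    """V by explicit root-to-tip path intersection, no recursion tricks."""
    labels = tree.tip_labels
    paths = {}
    for leaf in tree.dendropy_tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    n = len(labels)
    V = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = set(id(e) for e in paths[a]) & set(
                id(e) for e in paths[b]
            )
            V[i, j] = sum(
                e.edge.length for e in paths[a] if id(e) in shared
            )
    return V, labels


def blomberg_k_oracle(tree, trait):
    """K via the GLS definition with a Cholesky solve (different numeric
    path from the implementation's explicit inverse)."""
    V, labels = covariance_oracle(tree)
    x = np.array([trait[lab] for lab in labels])
    n = len(x)
    c = cho_factor(V)
    ones = np.ones(n)
    vinv_ones = cho_solve(c, ones)
    vinv_x = cho_solve(c, x)
    a = (ones @ vinv_x) / (ones @ vinv_ones)
    r = x - a
    mse0 = (r @ r) / (n - 1)
    mse = (r @ cho_solve(c, r)) / (n - 1)
    expected = (np.trace(V) - n / (ones @ vinv_ones)) / (n - 1)
    return (mse0 / mse) / expected


def sankoff_oracle(tree, tip_states, cost, states):
    """Exhaustive minimum over every internal-state assignment."""
    nodes = list(tree.dendropy_tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    sidx = {s: i for i, s in enumerate(states)}
    best = np.inf
    for assign in itertools.product(range(len(cost)), repeat=len(internal)):
        state_of = {id(nd): s for nd, s in zip(internal, assign)}
        total = 0.0
        for nd in nodes:
            if nd.parent_node is None:
                continue
            ps = state_of[id(nd.parent_node)]
            cs = (
                sidx[tip_states[nd.taxon.label]]
                if nd.is_leaf()
                else state_of[id(nd)]
            )
            total += cost[ps][cs]
        best = min(best, total)
    return best


# ---------------------------------------------------------------------------
# Covariance / distances
# ---------------------------------------------------------------------------


class TestPhyloCovariance:
    def test_cherry(self):
        V, labels = phylo_covariance(parse_newick("(A:1,B:1);"))
        assert labels == ("A", "B")
        np.testing.assert_allclose(V, np.eye(2))

    def test_balanced4(self, balanced4):
        V, labels = phylo_covariance(balanced4)
        idx = {lab: i for i, lab in enumerate(labels)}
        np.testing.assert_allclose(np.diag(V), 2.0)
        assert V[idx["A"], idx["B"]] == 1.0
        assert V[idx["A"], idx["C"]] == 0.0

    def test_matches_path_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            tree = random_tree(rng)
            V, labels = phylo_covariance(tree)
            Vo, labels_o = covariance_oracle(tree)
            assert labels == labels_o
            np.testing.assert_allclose(V, Vo, atol=1e-12)

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            tree = random_tree(rng)
            V, _ = phylo_covariance(tree)
            eig = np.linalg.eigvalsh(V)
            assert eig.min() > -1e-8

    def test_patristic_balanced4(self, balanced4):
        D, labels = patristic_distance_matrix(balanced4)
        idx = {lab: i for i, lab in enumerate(labels)}
        assert D[idx["A"], idx["B"]] == 2.0
        assert D[idx["A"], idx["C"]] == 4.0
        np.testing.assert_allclose(np.diag(D), 0.0)


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------


class TestBlombergK:
    def test_clade_concordant_exceeds_one(self, balanced4):
        trait = {"A": 0.0, "B": 0.0, "C": 10.0, "D": 10.0}
        k = blomberg_k(balanced4, trait)
        assert k > 1
        assert k == pytest.approx(blomberg_k_oracle(balanced4, trait))

    def test_clade_discordant_below_one(self, balanced4):
        trait = {"A": 0.0, "B": 10.0, "C": 0.0, "D": 10.0}
        k = blomberg_k(balanced4, trait)
        assert k < 1
        assert k == pytest.approx(blomberg_k_oracle(balanced4, trait))

    def test_matches_oracle_on_random_trees(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            tree = random_tree(rng)
            trait = {
                lab: float(rng.standard_normal()) for lab in tree.tip_labels
            }
            k = blomberg_k(tree, trait)
            ko = blomberg_k_oracle(tree, trait)
            assert abs(k - ko) <= 1e-10 * max(1.0, abs(ko))

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        tree = random_tree(rng)
        trait = {lab: float(rng.standard_normal()) for lab in tree.tip_labels}
        k0 = blomberg_k(tree, trait)
        shifted = {lab: 3.5 * v - 7.0 for lab, v in trait.items()}
        assert blomberg_k(tree, shifted) == pytest.approx(k0, rel=1e-9)

    def test_branch_rescale_invariance(self):
        rng = np.random.default_rng(4)
        tree = random_tree(rng)
        trait = {lab: float(rng.standard_normal()) for lab in tree.tip_labels}
        k0 = blomberg_k(tree, trait)
        for node in tree.dendropy_tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length *= 5.0
        assert blomberg_k(tree, trait) == pytest.approx(k0, rel=1e-9)

    def test_tip_order_relabeling_invariance(self):
        a = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        b = parse_newick("((D:1,C:1):1,(B:1,A:1):1);")
        trait = {"A": 1.0, "B": 2.0, "C": 5.0, "D": 9.0}
        assert blomberg_k(a, trait) == pytest.approx(
            blomberg_k(b, trait), rel=1e-12
        )

    def test_constant_trait_error(self, balanced4):
        with pytest.raises(DegenerateInputError):
            blomberg_k(balanced4, {t: 1.0 for t in "ABCD"})

    def test_label_mismatch_error(self, balanced4):
        with pytest.raises(ValidationError, match="mismatch"):
            blomberg_k(balanced4, {"A": 1.0, "B": 2.0, "C": 3.0, "X": 4.0})

    def test_mean_k_under_bm_near_one(self):
        tree = simulate_tree(64, seed=7)
        traits = evolve_niche_optima(tree, 1.0, 1.0, 0.0, seed=1,
                                     n_traits=500)
        ks = KCalculator(tree).k_many(traits.to_numpy())
        assert 0.9 <= ks.mean() <= 1.1


class TestKPermutation:
    def test_clade_signal_significant(self):
        tree = parse_newick(make_balanced_newick(5))
        # trait = deterministic function of the deepest split
        half = tree.n_tips // 2
        trait = {
            lab: (0.0 if i < half else 5.0) + 0.01 * i
            for i, lab in enumerate(tree.tip_labels)
        }
        res = k_permutation_test(tree, trait, n_perm=999, seed=0)
        assert res.p_value <= 0.01

    def test_add_one_lower_bound(self):
        tree = parse_newick(make_balanced_newick(5))
        trait = {
            lab: float(i < 16) for i, lab in enumerate(tree.tip_labels)
        }
        res = k_permutation_test(tree, trait, n_perm=999, seed=1)
        assert res.p_value >= 1.0 / 1000

    def test_type_one_error_calibrated(self):
        tree = simulate_tree(64, seed=11)
        calc = KCalculator(tree)
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            trait = dict(zip(calc.labels, rng.standard_normal(64)))
            res = k_permutation_test(
                tree, trait, n_perm=199,
                seed=int(rng.integers(2**31)), calculator=calc,
            )
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_seeded_reproducibility(self):
        tree = simulate_tree(10, 1)
        trait = dict(
            zip(tree.tip_labels, np.random.default_rng(0).standard_normal(10))
        )
        a = k_permutation_test(tree, trait, n_perm=99, seed=5)
        b = k_permutation_test(tree, trait, n_perm=99, seed=5)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null, b.null)


# ---------------------------------------------------------------------------
# Sankoff parsimony
# ---------------------------------------------------------------------------


class TestSankoff:
    def test_single_state_zero(self, balanced4):
        assert sankoff_score(balanced4, {t: "v" for t in "ABCD"}) == 0.0

    def test_clade_partition_one_change(self, balanced4):
        states = {"A": "v", "B": "v", "C": "r", "D": "r"}
        assert sankoff_score(balanced4, states) == 1.0

    def test_discordant_two_changes(self, balanced4):
        states = {"A": "v", "B": "r", "C": "v", "D": "r"}
        assert sankoff_score(balanced4, states) == 2.0

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        n_cases = 0
        while n_cases < 200:
            tree = random_tree(rng, n_min=4, n_max=8)
            k = int(rng.integers(2, 4))
            states = tuple("abc"[:k])
            tip_states = {
                lab: states[rng.integers(k)] for lab in tree.tip_labels
            }
            if rng.random() < 0.5:
                cost = 1.0 - np.eye(k)
            else:
                cost = rng.integers(1, 4, size=(k, k)).astype(float)
                np.fill_diagonal(cost, 0.0)
            s = sankoff_score(tree, tip_states, cost, states)
            so = sankoff_oracle(tree, tip_states, cost, states)
            assert s == pytest.approx(so)
            n_cases += 1

    def test_missing_tip_state_error(self, balanced4):
        with pytest.raises(ValidationError, match="without a state"):
            sankoff_score(balanced4, {"A": "v", "B": "v", "C": "r"})

    def test_alphabet_mismatch_error(self, balanced4):
        with pytest.raises(ValidationError, match="alphabet"):
            sankoff_score(
                balanced4,
                {"A": "v", "B": "v", "C": "r", "D": "x"},
                states=("v", "r"),
            )

    def test_bad_cost_matrix(self, balanced4):
        states = {"A": "v", "B": "v", "C": "r", "D": "r"}
        with pytest.raises(ValidationError, match="diagonal"):
            sankoff_score(balanced4, states, np.ones((2, 2)))
        with pytest.raises(ValidationError, match="shape"):
            sankoff_score(balanced4, states, np.zeros((3, 3)))


class TestSankoffPermutation:
    def test_clade_partition_significant(self):
        tree = parse_newick(make_balanced_newick(5))
        half = tree.n_tips // 2
        states = {
            lab: ("v" if i < half else "r")
            for i, lab in enumerate(tree.tip_labels)
        }
        res = sankoff_permutation_test(tree, states, n_perm=999, seed=0)
        assert res.p_value <= 0.01

    def test_degenerate_single_state(self, balanced4):
        res = sankoff_permutation_test(
            balanced4, {t: "v" for t in "ABCD"}, n_perm=99, seed=0
        )
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_seeded_reproducibility(self, balanced4):
        states = {"A": "v", "B": "r", "C": "v", "D": "r"}
        a = sankoff_permutation_test(balanced4, states, n_perm=99, seed=3)
        b = sankoff_permutation_test(balanced4, states, n_perm=99, seed=3)
        assert a.p_value == b.p_value


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------


class TestDispersion:
    def test_pair_on_balanced4(self, balanced4):
        mpd, mntd = pairwise_dispersion(balanced4, ["A", "B"])
        assert mpd == 2.0 and mntd == 2.0

    def test_all_four(self, balanced4):
        mpd, mntd = pairwise_dispersion(balanced4, ["A", "B", "C", "D"])
        assert mpd == pytest.approx(20.0 / 6.0)
        assert mntd == 2.0

    def test_mntd_le_mpd_property(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            tree = random_tree(rng, n_min=6, n_max=14)
            g = int(rng.integers(2, tree.n_tips))
            group = list(
                rng.choice(tree.tip_labels, size=g, replace=False)
            )
            mpd, mntd = pairwise_dispersion(tree, group)
            assert mntd <= mpd + 1e-12

    def test_small_group_error(self, balanced4):
        with pytest.raises(DegenerateInputError):
            pairwise_dispersion(balanced4, ["A"])

    def test_clade_group_clustered(self, balanced16):
        clade = list(balanced16.tip_labels[:1])
        # take the 4 tips of one depth-2 subtree: t001..t004
        clade = [f"t{i:03d}" for i in range(1, 5)]
        res = ses_dispersion(
            balanced16, clade, balanced16.tip_labels, n_null=999, seed=0
        )
        assert res.nri > 0 and res.nti > 0

    def test_distant_pair_overdispersed(self, balanced16):
        group = ["t001", "t016"]  # opposite sides of the root
        res = ses_dispersion(
            balanced16, group, balanced16.tip_labels, n_null=999, seed=0
        )
        assert res.nri < 0

    def test_uniform_groups_mean_nri_zero(self, balanced16):
        rng = np.random.default_rng(7)
        pool = balanced16.tip_labels
        nris = []
        for i in range(300):
            group = list(rng.choice(pool, size=6, replace=False))
            res = ses_dispersion(
                balanced16, group, pool, n_null=199, seed=int(rng.integers(2**31))
            )
            nris.append(res.nri)
        assert abs(np.mean(nris)) < 0.1

    def test_group_equal_pool_error(self, balanced4):
        with pytest.raises(DegenerateInputError):
            ses_dispersion(balanced4, list("ABCD"), list("ABCD"))

    def test_group_not_subset_error(self, balanced4):
        with pytest.raises(ValidationError):
            ses_dispersion(balanced4, ["A", "X"], list("ABCD"))

    def test_seeded_reproducibility(self, balanced16):
        group = [f"t{i:03d}" for i in (1, 5, 9, 13)]
        a = ses_dispersion(balanced16, group, balanced16.tip_labels,
                           n_null=199, seed=9)
        b = ses_dispersion(balanced16, group, balanced16.tip_labels,
                           n_null=199, seed=9)
        assert a.nri == b.nri and a.p_mpd == b.p_mpd
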