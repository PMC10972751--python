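"""Phylogenetic core: pruning likelihood against brute-force enumeration,
closed-form distances, NJ on additive metrics, branch-length optimization,
bootstrap, RELL topology tests and strict-clock dating."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgdkit.alignment import Alignment
from wgdkit.phylo import (
    bipartitions,
    bootstrap_support,
    date_nodes,
    distance_matrix,
    from_newick,
    log_likelihood,
    ml_distance,
    neighbor_joining,
    nj_builder,
    optimize_branch_lengths,
    p_distance,
    poisson_correct,
    poisson_model,
    robinson_foulds,
    site_log_likelihoods,
    topology_test,
)
from wgdkit.phylo.likelihood import pattern_log_likelihoods
from wgdkit.phylo.model import SubstitutionModel
from wgdkit.phylo.tree import (
    Node,
    patristic_distances,
    set_ages_from_lengths,
    set_lengths_from_ages,
)
from wgdkit.simulate import evolve_sequences


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_log_likelihood(tree, aln, model):
    """Sum over all internal-state assignments; exponential, tiny trees only."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    tips = tree.leaves()
    pi = model.frequencies
    P = {id(n): model.transition(n.length) for n in tree.postorder() if n.parent is not None}
    total = 0.0
    for site in range(aln.n_sites):
        obs = {t.name: aln.row(t.name)[site] for t in tips}
        lik = 0.0
        for states in itertools.product(range(20), repeat=len(internals)):
            s = {id(n): states[i] for i, n in enumerate(internals)}
            term = pi[s[id(tree)]]
            for n in tree.postorder():
                if n.parent is None:
                    continue
                child_state = obs[n.name] if n.is_leaf else s[id(n)]
                if n.is_leaf and child_state < 0:
                    continue  # gap: marginalised, P rows sum to 1
                term *= P[id(n)][s[id(n.parent)], child_state]
            lik += term
        total += math.log(lik)
    return total


def random_tree(rng, names):
    """Random binary topology with exponential branch lengths."""
    nodes = [Node(n, float(rng.exponential(0.2)) + 0.01) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = Node(None, float(rng.exponential(0.2)) + 0.01)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = 0.0
    return root


def random_alignment(rng, names, n_sites, with_gaps=False):
    mat = rng.integers(0, 20, size=(len(names), n_sites)).astype(np.int8)
    if with_gaps:
        mask = rng.random(mat.shape) < 0.15
        mat[mask] = -1
    return Alignment(list(names), mat)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class TestLikelihood:
    def test_zero_distance_closed_form(self, model):
        """Two identical sequences joined by zero branches: lnL = L ln(1/20)."""
        root = Node()
        for n in ("a", "b"):
            root.add_child(Node(n, 0.0))
        aln = Alignment.from_dict({"a": "ACDEFGHIKL", "b": "ACDEFGHIKL"})
        assert log_likelihood(root, aln, model) == pytest.approx(
            10 * math.log(1 / 20), abs=1e-9
        )

    @pytest.mark.parametrize("n_tips,n_sites", [(3, 10), (4, 8)])
    def test_matches_brute_force(self, model, n_tips, n_sites):
        rng = np.random.default_rng(n_tips * 100 + n_sites)
        names = [f"t{i}" for i in range(n_tips)]
        tree = random_tree(rng, names)
        aln = random_alignment(rng, names, n_sites, with_gaps=True)
        exact = brute_force_log_likelihood(tree, aln, model)
        assert log_likelihood(tree, aln, model) == pytest.approx(exact, abs=1e-8)

    def test_invariant_under_rerooting(self, model):
        rng = np.random.default_rng(5)
        names = [f"t{i}" for i in range(6)]
        tree = random_tree(rng, names)
        aln = random_alignment(rng, names, 40)
        ref = log_likelihood(tree, aln, model)
        rerooted = tree.root_with_outgroup(["t3"])
        assert log_likelihood(rerooted, aln, model) == pytest.approx(ref, abs=1e-7)

    def test_pattern_compression_consistent(self, model):
        """Compressed-pattern lnL times weights equals per-site sums."""
        rng = np.random.default_rng(8)
        names = [f"t{i}" for i in range(5)]
        tree = random_tree(rng, names)
        base = random_alignment(rng, names, 10)
        # duplicate columns to force non-trivial compression
        idx = rng.integers(0, 10, size=60)
        aln = base.take_sites(idx)
        pat_lnl, weights, inverse = pattern_log_likelihoods(tree, aln, model)
        assert len(pat_lnl) < aln.n_sites
        assert float(pat_lnl @ weights) == pytest.approx(
            float(site_log_likelihoods(tree, aln, model).sum()), abs=1e-9
        )

    def test_negative_branch_rejected(self, model):
        root = Node()
        root.add_child(Node("a", -0.1))
        root.add_child(Node("b", 0.1))
        aln = Alignment.from_dict({"a": "AC", "b": "AC"})
        with pytest.raises(ValueError):
            log_likelihood(root, aln, model)

    def test_gamma_categories_average(self):
        """Gamma-rate likelihood is a proper mixture over category rates."""
        plain = poisson_model()
        gamma = poisson_model(gamma_shape=0.8, n_categories=4)
        root = Node()
        root.add_child(Node("a", 0.3))
        root.add_child(Node("b", 0.3))
        aln = Alignment.from_dict({"a": "ACDEF", "b": "ACDEW"})
        l_plain = log_likelihood(root, aln, plain)
        l_gamma = log_likelihood(root, aln, gamma)
        assert l_plain != pytest.approx(l_gamma)
        rates = gamma.category_rates()
        assert rates.mean() == pytest.approx(1.0)
        manual = 0.0
        for site in range(aln.n_sites):
            site_aln = aln.take_sites(np.array([site]))
            liks = []
            for r in rates:
                scaled = root.copy()
                for c in scaled.children:
                    c.length *= r
                liks.append(math.exp(log_likelihood(scaled, site_aln, plain)))
            manual += math.log(np.mean(liks))
        assert l_gamma == pytest.approx(manual, abs=1e-8)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


class TestDistances:
    def test_zero_p_gives_zero(self, model):
        a = np.array([0, 1, 2, 3], dtype=np.int8)
        assert ml_distance(a, a, model) == 0.0

    def test_closed_form_value(self):
        # p = 0.19 -> d = -(19/20) ln(1 - 0.19 * 20/19) = 0.21199...
        assert poisson_correct(0.19) == pytest.approx(0.21199, abs=5e-5)

    def test_saturation_sentinel(self, model):
        rng = np.random.default_rng(0)
        a = np.arange(20, dtype=np.int8).repeat(5)
        b = ((np.arange(20) + 1) % 20).astype(np.int8).repeat(5)
        assert math.isinf(ml_distance(a, b, model))

    def test_no_shared_sites_rejected(self):
        a = np.array([0, -1], dtype=np.int8)
        b = np.array([-1, 3], dtype=np.int8)
        with pytest.raises(ValueError):
            p_distance(a, b)

    def test_numeric_matches_closed_form_for_poisson_exchangeabilities(self):
        """The general 2-sequence ML optimiser agrees with the closed form."""
        rng = np.random.default_rng(3)
        # same Poisson process but scaled exchangeabilities to force the
        # numeric path (is_poisson still true means closed form; perturb pi)
        pi = np.full(20, 1 / 20)
        pi[0] += 1e-3
        pi[1] -= 1e-3
        model = SubstitutionModel(frequencies=pi)
        a = rng.integers(0, 20, 400).astype(np.int8)
        b = a.copy()
        flip = rng.random(400) < 0.2
        b[flip] = rng.integers(0, 20, int(flip.sum())).astype(np.int8)
        p, _ = p_distance(a, b)
        d_closed = poisson_correct(p)
        d_numeric = ml_distance(a, b, model)
        assert d_numeric == pytest.approx(d_closed, rel=0.05)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        # ((a:1,b:2):1,(c:3,d:4)) as an additive distance matrix
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(D, ["a", "b", "c", "d"])
        assert bipartitions(tree) == {frozenset({"a", "b"})}
        P = patristic_distances(tree, ["a", "b", "c", "d"])
        assert np.allclose(P, D, atol=1e-9)

    def test_three_taxa_exact_lengths(self):
        D = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
        tree = neighbor_joining(D, ["a", "b", "c"])
        lengths = {t.name: t.length for t in tree.leaves()}
        assert lengths == pytest.approx({"a": 3.0, "b": 2.0, "c": 6.0})

    def test_taxon_order_invariance(self, rng):
        n = 7
        names = [f"t{i}" for i in range(n)]
        true = random_tree(rng, names)
        D = patristic_distances(true, names)
        t1 = neighbor_joining(D, names)
        perm = list(rng.permutation(n))
        D2 = D[np.ix_(perm, perm)]
        t2 = neighbor_joining(D2, [names[i] for i in perm])
        assert robinson_foulds(t1, t2) == 0

    def test_non_finite_rejected(self):
        D = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(D, ["a", "b"])

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(4, 8))
    def test_recovers_random_additive_metrics(self, seed, n):
        """NJ recovers any additive metric's topology."""
        rng = np.random.default_rng(seed)
        names = [f"t{i}" for i in range(n)]
        true = random_tree(rng, names)
        D = patristic_distances(true, names)
        est = neighbor_joining(D, names)
        assert robinson_foulds(true, est) == 0

    def test_matches_scikit_bio(self, rng):
        """Independent cross-check against scikit-bio's NJ."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        names = [f"t{i}" for i in range(6)]
        true = random_tree(rng, names)
        D = patristic_distances(true, names)
        ours = neighbor_joining(D, names)
        theirs = skbio_nj(DistanceMatrix(D, names))
        theirs_bips = set()
        all_names = frozenset(names)
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            other = all_names - side
            if len(side) >= 2 and len(other) >= 2:
                theirs_bips.add(min(side, other, key=lambda s: tuple(sorted(s))))
        assert bipartitions(ours) == theirs_bips


# ---------------------------------------------------------------------------
# branch-length optimization
# ---------------------------------------------------------------------------


class TestOptimizeBranchLengths:
    def test_recovers_true_lengths(self, model):
        rng = np.random.default_rng(44)
        names = [f"t{i}" for i in range(5)]
        true = random_tree(rng, names)
        for n in true.postorder():
            if n.parent is not None:
                n.length = min(max(n.length, 0.05), 0.6)
        set_ages_from_lengths(_ := true)  # not needed; keep lengths as-is
        aln = _simulate_on(true, model, 10_000, seed=9)
        start = true.copy()
        for n in start.postorder():
            if n.parent is not None:
                n.length = 0.2
        res = optimize_branch_lengths(start, aln, model)
        est = {
            frozenset(n.leaf_names()): n.length
            for n in res.tree.postorder()
            if n.parent is not None and n.parent.parent is not None
        }
        for n in true.postorder():
            if n.parent is None or n.parent.parent is None:
                continue
            key = frozenset(n.leaf_names())
            assert est[key] == pytest.approx(n.length, rel=0.10, abs=0.01)

    def test_monotone_non_decreasing(self, model):
        rng = np.random.default_rng(2)
        names = [f"t{i}" for i in range(6)]
        tree = random_tree(rng, names)
        aln = random_alignment(rng, names, 60)
        l0 = log_likelihood(tree, aln, model)
        res = optimize_branch_lengths(tree, aln, model, max_sweeps=5)
        assert res.log_likelihood >= l0 - 1e-9

    def test_lengths_stay_non_negative(self, model):
        rng = np.random.default_rng(3)
        names = [f"t{i}" for i in range(4)]
        tree = random_tree(rng, names)
        aln = Alignment(
            names, np.zeros((4, 30), dtype=np.int8)
        )  # identical rows: optimum at zero branch lengths
        res = optimize_branch_lengths(tree, aln, model)
        for n in res.tree.postorder():
            if n.parent is not None:
                assert n.length >= 0.0


def _simulate_on(tree, model, n_sites, seed):
    t = tree.copy()
    set_ages_from_lengths(t)
    return evolve_sequences(t, n_sites, model, rate=1.0, seed=seed)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


class TestBootstrap:
    def test_deep_split_near_full_support(self, model):
        tree = from_newick("((a:0.1,b:0.1):0.3,(c:0.1,d:0.1):0.3);")
        aln = _simulate_on(tree, model, 2000, seed=1)
        out = bootstrap_support(aln, model, n_replicates=50, seed=4)
        for node in out.postorder():
            if node.support is not None:
                assert node.support > 90

    def test_single_replicate_support_binary(self, model):
        tree = from_newick("((a:0.2,b:0.2):0.05,(c:0.2,d:0.2):0.05);")
        aln = _simulate_on(tree, model, 100, seed=2)
        out = bootstrap_support(aln, model, n_replicates=1, seed=0)
        for node in out.postorder():
            if node.support is not None:
                assert node.support in (0.0, 100.0)

    def test_seed_determinism(self, model):
        tree = from_newick("((a:0.2,b:0.2):0.05,(c:0.2,d:0.2):0.05);")
        aln = _simulate_on(tree, model, 200, seed=3)
        s1 = bootstrap_support(aln, model, n_replicates=20, seed=7)
        s2 = bootstrap_support(aln, model, n_replicates=20, seed=7)
        sup1 = [n.support for n in s1.postorder() if n.support is not None]
        sup2 = [n.support for n in s2.postorder() if n.support is not None]
        assert sup1 == sup2


# ---------------------------------------------------------------------------
# topology tests
# ---------------------------------------------------------------------------


class TestTopologyTest:
    def test_identical_topologies_not_rejected(self, model):
        tree = from_newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);")
        aln = _simulate_on(tree, model, 500, seed=5)
        res = topology_test([tree, tree.copy()], aln, model, seed=1)
        assert res.deltas == pytest.approx([0.0, 0.0], abs=1e-9)
        assert res.p_values[1 - res.best_index] == 1.0
        assert not any(res.rejected)

    def test_wrong_deep_topology_rejected(self, model):
        true = from_newick("((a:0.2,b:0.2):0.15,(c:0.2,d:0.2):0.15);")
        wrong = from_newick("((a:0.2,c:0.2):0.15,(b:0.2,d:0.2):0.15);")
        aln = _simulate_on(true, model, 5000, seed=6)
        t1 = optimize_branch_lengths(true, aln, model, max_sweeps=5).tree
        t2 = optimize_branch_lengths(wrong, aln, model, max_sweeps=5).tree
        res = topology_test([t1, t2], aln, model, seed=2)
        assert res.best_index == 0
        assert res.rejected[1]

    def test_mismatched_tip_sets_rejected(self, model):
        t1 = from_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        t2 = from_newick("((a:0.1,b:0.1):0.1,(c:0.1,e:0.1):0.1);")
        aln = _simulate_on(t1, model, 50, seed=0)
        with pytest.raises(ValueError):
            topology_test([t1, t2], aln, model)

    def test_best_tree_never_rejected_sh(self, model):
        trees = [
            from_newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);"),
            from_newick("((a:0.2,c:0.2):0.1,(b:0.2,d:0.2):0.1);"),
            from_newick("((a:0.2,d:0.2):0.1,(b:0.2,c:0.2):0.1);"),
        ]
        aln = _simulate_on(trees[0], model, 800, seed=8)
        res = topology_test(trees, aln, model, seed=3)
        assert res.deltas[res.best_index] == 0.0
        assert not res.rejected[res.best_index]
        assert all(0.0 <= p <= 1.0 for p in res.p_values)


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------


class TestDating:
    def _clock_tree(self):
        t = from_newick("((a:0,b:0):0,((c:0,d:0):0,e:0):0);")
        ages = {"a": 0, "b": 0, "c": 0, "d": 0, "e": 0}
        t.children[0].age = 30.0
        inner = t.children[1]
        inner.age = 60.0
        inner.children[0].age = 20.0
        t.age = 100.0
        for tip in t.leaves():
            tip.age = 0.0
        return t

    def test_exact_recovery_with_one_calibration(self):
        t = self._clock_tree()
        set_lengths_from_ages(t, rate=2e-3)
        dated = date_nodes(t, {("c", "d"): (20.0, 20.0)})
        got = {
            frozenset(n.leaf_names()): n.age
            for n in dated.postorder()
            if not n.is_leaf
        }
        assert got[frozenset({"a", "b"})] == pytest.approx(30.0, abs=1e-6)
        assert got[frozenset({"c", "d", "e"})] == pytest.approx(60.0, abs=1e-6)
        assert got[frozenset({"a", "b", "c", "d", "e"})] == pytest.approx(
            100.0, abs=1e-6
        )

    def test_scale_invariance(self):
        t = self._clock_tree()
        set_lengths_from_ages(t, rate=2e-3)
        d1 = date_nodes(t, {("c", "d"): (20.0, 20.0)})
        t2 = self._clock_tree()
        set_lengths_from_ages(t2, rate=2e-2)
        d2 = date_nodes(t2, {("c", "d"): (20.0, 20.0)})
        for n1, n2 in zip(d1.postorder(), d2.postorder()):
            if not n1.is_leaf:
                assert n1.age == pytest.approx(n2.age, abs=1e-6)

    def test_ordering_constraints_enforced(self):
        t = self._clock_tree()
        set_lengths_from_ages(t, rate=1e-3)
        # corrupt one branch to pull a child older than its parent
        t.children[0].length *= 10
        dated = date_nodes(t, {("c", "d"): (20.0, 20.0)})
        for n in dated.postorder():
            if n.parent is not None and not n.is_leaf:
                assert n.age <= n.parent.age + 1e-9

    def test_infeasible_calibrations_rejected(self):
        t = self._clock_tree()
        set_lengths_from_ages(t, rate=1e-3)
        with pytest.raises(ValueError):
            date_nodes(
                t,
                {
                    ("c", "d"): (50.0, 50.0),
                    ("c", "d", "e"): (10.0, 10.0),
                },
            )

    def test_requires_calibration_and_rooting(self):
        t = self._clock_tree()
        set_lengths_from_ages(t, rate=1e-3)
        with pytest.raises(ValueError):
            date_nodes(t, {})
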