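"""Tree inference and scoring: NJ, Fitch, pruning likelihood, exhaustive
ML, trichotomy classification, bootstrap support and stem reports."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from lbalens.alignment import Alignment
from lbalens.io import parse_tree
from lbalens.models import SubstitutionModel
from lbalens.saturation import p_distance_matrix, patristic_matrix
from lbalens.simulate import felsenstein_zone_tree, simulate_alignment
from lbalens.trees import (CladeBranchReport, TreeError, _struct_of_tree,
                           _tree_signature, bootstrap_support,
                           classify_trichotomy, exhaustive_ml_search,
                           fitch_parsimony, gtr_gamma_loglik, nj_tree,
                           optimize_branch_lengths, parsimony_tree,
                           stem_branch_report)
from tests.conftest import random_alignment


def random_additive_tree(rng, n_taxa):
    """Random binary topology with random positive branch lengths."""
    labels = [f"t{i}" for i in range(n_taxa)]
    struct = tuple(labels[:3])

    def insert(s, leaf):
        """Insert leaf on a uniformly chosen edge of the structure."""
        edges = []

        def walk(path, node):
            edges.append(path)
            if not isinstance(node, str):
                for k, child in enumerate(node):
                    walk(path + (k,), child)

        for k, child in enumerate(struct_holder[0]):
            walk((k,), child)
        chosen = edges[rng.integers(len(edges))]

        def rebuild(node, path):
            if not path:
                return (node, leaf)
            return tuple(rebuild(node[k], path[1:]) if k == path[0]
                         else node[k] for k in range(len(node)))

        return rebuild(s, chosen)

    struct_holder = [struct]
    for leaf in labels[3:]:
        struct_holder[0] = insert(struct_holder[0], leaf)
    lengths = {}

    def newick(node):
        if isinstance(node, str):
            return f"{node}:{rng.uniform(0.1, 1.0)}"
        inner = ",".join(newick(c) for c in node)
        return f"({inner}):{rng.uniform(0.1, 1.0)}"

    parts = ",".join(newick(c) for c in struct_holder[0])
    return parse_tree(f"({parts});")


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive matrix
        D = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float)
        tree = nj_tree(D)
        assert _tree_signature(tree) == frozenset({frozenset({"a", "b"})})
        np.testing.assert_allclose(
            patristic_matrix(tree).loc[list("abcd"), list("abcd")], D,
            atol=1e-12)

    def test_three_taxa_solved_exactly(self):
        D = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        tree = nj_tree(D)
        pat = patristic_matrix(tree)
        np.testing.assert_allclose(pat.loc[list("abc"), list("abc")], D)

    def test_missing_entry_rejected(self):
        D = pd.DataFrame([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]],
                         index=list("abc"), columns=list("abc"))
        with pytest.raises(TreeError):
            nj_tree(D)

    def test_matches_scikit_bio_topology(self, rng):
        """Independent NJ cross-check on noisy (non-additive) matrices."""
        skbio = pytest.importorskip("skbio")
        for _ in range(5):
            n = 6
            M = rng.uniform(0.1, 1.0, (n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            ids = [f"t{i}" for i in range(n)]
            ours = nj_tree(pd.DataFrame(D, index=ids, columns=ids))
            theirs = parse_tree(str(skbio.tree.nj(
                skbio.DistanceMatrix(D, ids))))
            assert _tree_signature(ours) == _tree_signature(theirs)

    def test_ultrametric_matrix_matches_upgma_topology(self, rng):
        """On ultrametric distances NJ and UPGMA agree on the topology
        (scipy average-linkage as the independent UPGMA)."""
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform
        for seed in range(5):
            r = np.random.default_rng(seed)
            # random ultrametric: random binary dendrogram heights
            n = 6
            ids = [f"t{i}" for i in range(n)]
            Z = hierarchy.linkage(r.random((n, 3)), method="average")
            D = squareform(hierarchy.cophenet(Z))
            nj = nj_tree(pd.DataFrame(D, index=ids, columns=ids))
            # UPGMA splits from the linkage matrix
            clusters = {i: {ids[i]} for i in range(n)}
            splits = set()
            for k, (a, b, _, _) in enumerate(Z):
                merged = clusters[int(a)] | clusters[int(b)]
                clusters[n + k] = merged
                if 1 < len(merged) < n - 1:
                    splits.add(frozenset(merged))
            upgma_sig = frozenset(
                min(s, frozenset(set(ids) - s), key=sorted) for s in splits)
            assert _tree_signature(nj) == upgma_sig

    def test_negative_branch_clamped(self, rng):
        M = rng.uniform(0.0, 0.2, (5, 5))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        ids = [f"t{i}" for i in range(5)]
        tree = nj_tree(pd.DataFrame(D, index=ids, columns=ids))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


def fitch_bruteforce(tree, aln):
    """Oracle: minimise changes over all internal-state assignments."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    edges = [(n, c) for n in tree.preorder_node_iter()
             for c in n.child_nodes()]
    total = 0
    for j in range(aln.n_columns):
        obs = {t: aln.matrix[i, j] for i, t in enumerate(aln.taxa)}
        best = np.inf
        for assign in itertools.product("ACGT", repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, assign)}
            for label, lf in leaves.items():
                state[id(lf)] = obs[label]
            changes = 0
            ok = True
            for parent, child in edges:
                s1, s2 = state[id(parent)], state[id(child)]
                if s1 not in "ACGT" or s2 not in "ACGT":
                    continue  # missing observed state: free
                if s1 != s2:
                    changes += 1
            # leaves with missing data: allow any state at zero cost by
            # re-minimising over their states too
            best = min(best, changes)
        total += best
    return total


class TestFitch:
    @pytest.mark.parametrize("newick,expected", [
        ("((t0,t1),(t2,t3));", 1),
        ("((t0,t2),(t1,t3));", 2),
    ])
    def test_hand_counts_informative_column(self, newick, expected):
        aln = Alignment.from_dict({"t0": "A", "t1": "A",
                                   "t2": "C", "t3": "C"})
        assert fitch_parsimony(parse_tree(newick), aln) == expected

    def test_invariant_alignment_zero(self, rng):
        aln = Alignment.from_dict({f"t{i}": "AAAA" for i in range(4)})
        assert fitch_parsimony(parse_tree("((t0,t1),(t2,t3));"), aln) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_five_taxa(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, 5, 12)
        tree = parse_tree("(((t0,t1),t2),(t3,t4));")
        assert fitch_parsimony(tree, aln) == fitch_bruteforce(tree, aln)

    def test_missing_data_bruteforce(self):
        rng = np.random.default_rng(9)
        aln = random_alignment(rng, 5, 10, alphabet="ACGT-N")
        tree = parse_tree("(((t0,t1),t2),(t3,t4));")
        # gap/N is a free wildcard in both implementations
        assert fitch_parsimony(tree, aln) == fitch_bruteforce(tree, aln)


def pruning_bruteforce(tree, aln, model):
    """Oracle: explicit summation over internal-state assignments."""
    cat_rates = model.category_rates()
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    edges = [(n, c) for n in tree.preorder_node_iter()
             for c in n.child_nodes()]
    row = {t: i for i, t in enumerate(aln.taxa)}
    codes = aln.encoded()
    total = 0.0
    for j in range(aln.n_columns):
        site = 0.0
        for rate in cat_rates:
            Ps = {id(c): model.transition_matrix(c.edge.length * rate)
                  for _, c in edges}
            cat_lik = 0.0
            for assign in itertools.product(range(4),
                                            repeat=len(internals)):
                state = {id(n): s for n, s in zip(internals, assign)}
                lik = model.freqs[state[id(tree.seed_node)]]
                for parent, child in edges:
                    sp = state[id(parent)]
                    if child.is_leaf():
                        obs = codes[row[child.taxon.label], j]
                        if obs < 0:
                            continue  # missing: sums to 1
                        lik *= Ps[id(child)][sp, obs]
                    else:
                        lik *= Ps[id(child)][sp, state[id(child)]]
                cat_lik += lik
            site += cat_lik / len(cat_rates)
        total += np.log(site)
    return total


class TestLikelihood:
    def test_two_taxon_closed_form(self):
        jc = SubstitutionModel.jc69()
        d = 0.37
        tree = parse_tree(f"(a:{d},b:0);", rooting="default-rooted")
        match = Alignment.from_dict({"a": "A", "b": "A"})
        mismatch = Alignment.from_dict({"a": "A", "b": "C"})
        p_same = 0.25 * (0.25 + 0.75 * np.exp(-4 * d / 3))
        p_diff = 0.25 * (0.25 - 0.25 * np.exp(-4 * d / 3))
        assert gtr_gamma_loglik(tree, match, jc) == pytest.approx(
            np.log(p_same))
        assert gtr_gamma_loglik(tree, mismatch, jc) == pytest.approx(
            np.log(p_diff))

    @pytest.mark.parametrize("seed,alpha", [(0, None), (1, 0.5), (2, None)])
    def test_matches_bruteforce(self, seed, alpha):
        rng = np.random.default_rng(seed)
        model = SubstitutionModel(
            freqs=np.array([0.3, 0.2, 0.2, 0.3]),
            rates=np.array([1.0, 2.5, 0.7, 1.1, 3.0, 1.0]), alpha=alpha)
        for newick, n in [("((a:0.1,b:0.3):0.15,(c:0.2,d:0.4):0.0);", 4),
                          ("(((a:0.1,b:0.2):0.1,c:0.3):0.2,"
                           "(d:0.25,e:0.15):0.0);", 5)]:
            tree = parse_tree(newick, rooting="default-rooted")
            aln = random_alignment(rng, n, 3, alphabet="ACGT")
            aln = Alignment(list("abcde")[:n], aln.matrix)
            assert abs(gtr_gamma_loglik(tree, aln, model)
                       - pruning_bruteforce(tree, aln, model)) < 1e-8

    def test_rerooting_invariance(self, rng):
        """Reversibility: the likelihood ignores root placement."""
        jc = SubstitutionModel.jc69(alpha=0.8)
        aln = random_alignment(rng, 4, 30)
        aln = Alignment(list("abcd"), aln.matrix)
        t1 = parse_tree("((a:0.1,b:0.3):0.2,(c:0.2,d:0.4):0.0);",
                        rooting="default-rooted")
        # the same unrooted tree, rooted on a different edge
        t2 = parse_tree("((b:0.3,(c:0.2,d:0.4):0.2):0.1,a:0.0);",
                        rooting="default-rooted")
        assert gtr_gamma_loglik(t1, aln, jc) == pytest.approx(
            gtr_gamma_loglik(t2, aln, jc))


class TestMLSearch:
    def test_topology_counts(self, rng):
        aln = random_alignment(rng, 5, 10)
        jc = SubstitutionModel.jc69()
        _, _, n_scored, _ = exhaustive_ml_search(aln, jc, tol=1e-3)
        assert n_scored == 15

    def test_refuses_large(self, rng):
        aln = random_alignment(rng, 10, 10)
        with pytest.raises(TreeError):
            exhaustive_ml_search(aln, SubstitutionModel.jc69())

    def test_strong_signal_recovery(self):
        jc = SubstitutionModel.jc69()
        tree = parse_tree("((a:0.05,b:0.05):0.3,(c:0.05,d:0.05):0.0);",
                          rooting="default-rooted")
        aln = simulate_alignment(tree, jc, 800, seed=7)
        best, _, _, _ = exhaustive_ml_search(aln, jc)
        assert _tree_signature(best) == frozenset({frozenset({"a", "b"})})

    def test_branch_length_recovery(self):
        jc = SubstitutionModel.jc69()
        true = parse_tree("((a:0.10,b:0.20):0.15,(c:0.12,d:0.25):0.0);",
                          rooting="default-rooted")
        aln = simulate_alignment(true, jc, 50000, seed=3)
        perturbed = parse_tree(
            "((a:0.3,b:0.05):0.5,(c:0.3,d:0.08):0.0001);",
            rooting="default-rooted")
        fitted = optimize_branch_lengths(perturbed, aln, jc)
        pat_true = patristic_matrix(true)
        pat_fit = patristic_matrix(fitted)
        taxa = list("abcd")
        ratio = (pat_fit.loc[taxa, taxa].to_numpy()[np.triu_indices(4, 1)]
                 / pat_true.loc[taxa, taxa].to_numpy()[np.triu_indices(4, 1)])
        assert np.all(np.abs(ratio - 1) < 0.05)


class TestTrichotomy:
    CLADES = {"J": {"j1", "j2"}, "C": {"c1", "c2"}, "H": {"h1", "h2"}}
    OUT = {"out"}

    def test_each_resolution(self):
        t = parse_tree("((j1,j2),((c1,c2),(h1,h2)),out);")
        assert classify_trichotomy(t, self.CLADES, self.OUT) == "J(C,H)"
        t = parse_tree("((h1,h2),((c1,c2),(j1,j2)),out);")
        assert classify_trichotomy(t, self.CLADES, self.OUT) == "H(J,C)"

    def test_singleton_clades(self):
        t = parse_tree("((J,(C,H)),out);")
        clades = {"J": {"J"}, "C": {"C"}, "H": {"H"}}
        assert classify_trichotomy(t, clades, {"out"}) == "J(C,H)"

    def test_paraphyletic_clade_is_other(self):
        t = parse_tree("((j1,c1),((j2,c2),(h1,h2)),out);")
        assert classify_trichotomy(t, self.CLADES, self.OUT) == "other"

    def test_coverage_check(self):
        t = parse_tree("((j1,j2),((c1,c2),(h1,h2)),out);")
        with pytest.raises(ValueError):
            classify_trichotomy(t, self.CLADES, {"missing"})


class TestBootstrap:
    def _data(self):
        tree = parse_tree(
            "(out:0.4,((j1:0.05,j2:0.05):0.2,((c1:0.05,c2:0.05):0.2,"
            "(h1:0.05,h2:0.05):0.05):0.1):0.05);",
            rooting="default-rooted")
        return simulate_alignment(tree, SubstitutionModel.jc69(), 2000,
                                  seed=11)

    def test_strong_signal_and_determinism(self):
        aln = self._data()
        clades = {"J": {"j1", "j2"}, "C": {"c1", "c2"}, "H": {"h1", "h2"}}
        s1 = bootstrap_support(aln, clades, {"out"}, infer="nj",
                               n_reps=50, seed=5, distance_model="JC69")
        s2 = bootstrap_support(aln, clades, {"out"}, infer="nj",
                               n_reps=50, seed=5, distance_model="JC69")
        assert s1.counts == s2.counts
        assert s1.proportions["J(C,H)"] >= 0.95
        assert sum(s1.counts.values()) == 50

    def test_zero_reps_rejected(self):
        aln = self._data()
        with pytest.raises(ValueError):
            bootstrap_support(aln, {"J": {"j1"}, "C": {"c1"}, "H": {"h1"}},
                              {"out"}, n_reps=0)


class TestStemReport:
    def test_toy_ratios(self):
        t = parse_tree(
            "(out:1.0,((j1:0.1,j2:0.1):0.30,((c1:0.1,c2:0.1):0.20,"
            "(h1:0.1,h2:0.1):0.10):0.05):0.05);")
        clades = {"J": {"j1", "j2"}, "C": {"c1", "c2"}, "H": {"h1", "h2"}}
        rep = stem_branch_report(t, clades, reference="H", outgroup={"out"})
        assert rep.entries["H"]["ratio"] == pytest.approx(1.0)
        assert rep.entries["J"]["ratio"] == pytest.approx(3.0)
        assert rep.entries["C"]["ratio"] == pytest.approx(2.0)

    def test_nonmonophyletic_flagged(self):
        t = parse_tree("((j1,c1),((j2,c2),(h1,h2)),out);")
        for e in t.preorder_edge_iter():
            e.length = 0.1
        clades = {"J": {"j1", "j2"}, "C": {"c1", "c2"}, "H": {"h1", "h2"}}
        rep = stem_branch_report(t, clades, reference="H", outgroup={"out"})
        assert rep.entries["J"]["monophyletic"] is False
        assert rep.entries["J"]["stem_length"] is None


class TestFelsensteinZoneContrast:
    """Classic inconsistency contrast: parsimony unites the long branches,
    ML with the generating model recovers the truth."""

    def test_parsimony_vs_ml(self):
        jc = SubstitutionModel.jc69()
        tree = felsenstein_zone_tree(0.8, 0.05)
        pars_wrong = ml_right = 0
        n_seeds = 12
        for seed in range(n_seeds):
            aln = simulate_alignment(tree, jc, 2000, seed=seed)
            ptree = parsimony_tree(aln)
            sig = _tree_signature(ptree)
            if frozenset({"A", "C"}) in sig or frozenset({"B", "D"}) in sig:
                pars_wrong += 1
            best, _, _, _ = exhaustive_ml_search(aln, jc, tol=1e-4)
            msig = _tree_signature(best)
            if frozenset({"A", "B"}) in msig or frozenset({"C", "D"}) in msig:
                ml_right += 1
        assert pars_wrong > n_seeds / 2
        assert ml_right > n_seeds / 2
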