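"""Desk-scale tree inference and scoring.

Large-scale ML search engines are deliberately *not* re-implemented here;
the package works at the scale where neighbor-joining, Fitch parsimony
(with NNI hill climbing), and exhaustive maximum-likelihood search over
all unrooted topologies are exact enough to study long-branch-attraction
behaviour.  The likelihood is Felsenstein's pruning algorithm under
GTR (+ discrete-Gamma with equal-probability category means).

Rival-topology support for a focal trichotomy is measured by column
bootstrap: each replicate tree is classified as one of the three
resolutions (or "other"), and the stem-branch report gives each clade's
subtending branch length and its ratio to a reference clade — the
branch-length diagnostic of long-branch artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

from .alignment import Alignment
from .models import SubstitutionModel

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING = 15


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the adjacent (pair) branch, preserving the pair's path
    length.  Returns an unrooted tree (trifurcating seed node).
    """
    taxa = list(d.index)
    D = d.to_numpy(dtype=float).copy()
    if np.isnan(D).any():
        raise TreeError("incomplete distance matrix")
    if len(taxa) < 3:
        raise TreeError("need >= 3 taxa")
    if not np.allclose(D, D.T):
        raise TreeError("matrix not symmetric")
    tns = dendropy.TaxonNamespace(taxa)
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in taxa]

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj = max(lj + li, 0.0)
            li = 0.0
        if lj < 0:
            li = max(li + lj, 0.0)
            lj = 0.0
        return li, lj

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([np.hstack([D[np.ix_(keep, keep)],
                                  dnew[keep, None]]),
                       np.hstack([dnew[keep], [0.0]])])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-way join with exact branch lengths
    (a, b, c) = (0, 1, 2)
    la = max(0.5 * (D[a, b] + D[a, c] - D[b, c]), 0.0)
    lb = max(0.5 * (D[a, b] + D[b, c] - D[a, c]), 0.0)
    lc = max(0.5 * (D[a, c] + D[b, c] - D[a, b]), 0.0)
    root = dendropy.Node()
    for node, ln in zip(nodes, (la, lb, lc)):
        root.add_child(node)
        node.edge.length = ln
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def _bit_encode(aln: Alignment) -> dict[str, np.ndarray]:
    out = {}
    for i, t in enumerate(aln.taxa):
        row = np.full(aln.n_columns, _MISSING, dtype=np.uint8)
        for s, b in _BITS.items():
            row[aln.matrix[i] == s] = b
        out[t] = row
    return out


def fitch_parsimony(tree: dendropy.Tree, aln: Alignment) -> int:
    """Minimum number of state changes over all columns (Fitch count).

    Gaps and ambiguity codes are treated as missing (any state), so fully
    uninformative columns contribute nothing.
    """
    leaf_states = _bit_encode(aln)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = labels - set(aln.taxa)
    if missing:
        raise TreeError(f"taxa absent from alignment: {sorted(missing)}")
    score = np.zeros(aln.n_columns, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = leaf_states[node.taxon.label]
            continue
        children = node.child_nodes()
        acc = sets[id(children[0])]
        for child in children[1:]:
            inter = acc & sets[id(child)]
            empty = inter == 0
            score += empty
            acc = np.where(empty, acc | sets[id(child)], inter)
        sets[id(node)] = acc
    return int(score.sum())


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def gtr_gamma_loglik(tree: dendropy.Tree, aln: Alignment,
                     model: SubstitutionModel) -> float:
    """Felsenstein pruning log-likelihood under GTR(+Gamma)."""
    codes = aln.encoded()
    taxon_row = {t: i for i, t in enumerate(aln.taxa)}
    cat_rates = model.category_rates()
    ncat, L = len(cat_rates), aln.n_columns
    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in taxon_row:
                raise TreeError(f"taxon {label!r} absent from alignment")
            row = codes[taxon_row[label]]
            P = np.zeros((ncat, L, 4))
            P[:, row < 0, :] = 1.0
            valid = row >= 0
            P[:, np.flatnonzero(valid), row[valid]] = 1.0
            partials[id(node)] = P
            continue
        acc = np.ones((ncat, L, 4))
        for child in node.child_nodes():
            t = child.edge.length
            if t is None:
                raise TreeError("edge without branch length")
            child_partial = partials[id(child)]
            lifted = np.empty_like(child_partial)
            for c, rate in enumerate(cat_rates):
                Pm = model.transition_matrix(t * rate)
                lifted[c] = child_partial[c] @ Pm.T
            acc *= lifted
        partials[id(node)] = acc
    root = partials[id(tree.seed_node)]
    site_lik = (root @ model.freqs).mean(axis=0)
    site_lik = np.maximum(site_lik, 1e-310)
    return float(np.log(site_lik).sum())


def optimize_branch_lengths(tree: dendropy.Tree, aln: Alignment,
                            model: SubstitutionModel,
                            tol: float = 1e-6, max_sweeps: int = 30,
                            max_branch: float = 20.0) -> dendropy.Tree:
    """Cyclic one-dimensional branch-length optimisation (Brent)."""
    tree = tree.clone(depth=1)
    edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
    for e in edges:
        if e.length is None or e.length <= 0:
            e.length = 0.01
    prev = gtr_gamma_loglik(tree, aln, model)
    for _ in range(max_sweeps):
        for e in edges:
            def nll(x: float) -> float:
                e.length = x
                return -gtr_gamma_loglik(tree, aln, model)
            res = optimize.minimize_scalar(
                nll, bounds=(1e-9, max_branch), method="bounded",
                options={"xatol": 1e-8})
            e.length = float(res.x)
        cur = gtr_gamma_loglik(tree, aln, model)
        if abs(cur - prev) <= tol * (abs(prev) + 1.0):
            break
        prev = cur
    return tree


def _enumerate_unrooted_topologies(taxa: list[str],
                                   tns: dendropy.TaxonNamespace):
    """Yield every unrooted binary topology (nested-tuple form).

    An unrooted topology is a trifurcating root tuple ``(a, b, c)``;
    topologies are generated by stepwise addition of each taxon onto every
    edge, which enumerates each topology exactly once.
    """
    def build(struct_list, remaining):
        if not remaining:
            yield from struct_list
            return
        leaf, rest = remaining[0], remaining[1:]
        nxt = []
        for struct in struct_list:
            for k, part in enumerate(struct):
                for sub in _insert(part, leaf):
                    nxt.append(tuple(sub if m == k else struct[m]
                                     for m in range(3)))
        yield from build(nxt, rest)

    def _insert(struct, leaf):
        """Insert leaf on the edge above `struct` or recursively inside."""
        results = [(struct, leaf)]
        if not isinstance(struct, str):
            for k, child in enumerate(struct):
                for sub in _insert(child, leaf):
                    results.append(tuple(sub if m == k else struct[m]
                                         for m in range(len(struct))))
        return results

    base = (taxa[0], taxa[1], taxa[2])
    yield from build([base], taxa[3:])


def _struct_to_tree(struct, tns: dendropy.TaxonNamespace,
                    init_length: float = 0.1) -> dendropy.Tree:
    def make(node_struct):
        if isinstance(node_struct, str):
            node = dendropy.Node(taxon=tns.get_taxon(node_struct))
        else:
            node = dendropy.Node()
            for child_struct in node_struct:
                child = make(child_struct)
                node.add_child(child)
                child.edge.length = init_length
        return node

    root = dendropy.Node()
    for part in struct:
        child = make(part)
        root.add_child(child)
        child.edge.length = init_length
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def exhaustive_ml_search(aln: Alignment, model: SubstitutionModel,
                         max_taxa: int = 9, tol: float = 1e-6):
    """Score every unrooted topology; return (best tree, loglik, n_scored).

    Ties (within 1e-9 log units) are broken first-found and reported via
    the returned tie list.
    """
    taxa = list(aln.taxa)
    if len(taxa) > max_taxa:
        raise TreeError(f"{len(taxa)} taxa exceeds exhaustive limit "
                        f"{max_taxa}; use a heuristic")
    if len(taxa) < 3:
        raise TreeError("need >= 3 taxa")
    tns = dendropy.TaxonNamespace(taxa)
    best, best_ll, n_scored, ties = None, -np.inf, 0, []
    for struct in _enumerate_unrooted_topologies(taxa, tns):
        tree = _struct_to_tree(struct, tns)
        tree = optimize_branch_lengths(tree, aln, model, tol=tol)
        ll = gtr_gamma_loglik(tree, aln, model)
        n_scored += 1
        if ll > best_ll + 1e-9:
            best, best_ll, ties = tree, ll, []
        elif abs(ll - best_ll) <= 1e-9:
            ties.append(tree)
    return best, best_ll, n_scored, ties


# ---------------------------------------------------------------------------
# NNI search (parsimony / quartet-score hill climbing)
# ---------------------------------------------------------------------------

def _tree_signature(tree: dendropy.Tree) -> frozenset:
    """Unrooted topology signature: the set of nontrivial leaf bipartitions."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits = set()
    sets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*[sets[id(c)] for c in node.child_nodes()])
            sets[id(node)] = s
            if 1 < len(s) < len(leaves) - 1:
                splits.add(min(s, leaves - s, key=sorted))
    return frozenset(splits)


def _struct_of_tree(tree: dendropy.Tree):
    """Nested-tuple structure of a tree (for NNI by re-building)."""
    def rec(node):
        if node.is_leaf():
            return node.taxon.label
        return tuple(rec(c) for c in node.child_nodes())
    root = tree.seed_node
    parts = tuple(rec(c) for c in root.child_nodes())
    return parts


def _struct_nni_neighbors(struct):
    """All NNI neighbors of a nested-tuple unrooted topology."""
    # Collect internal edges as (path, ) where path addresses a non-leaf
    # child subtree; an NNI swaps one of its children with a sibling.
    neighbors = []

    def at(s, path):
        for p in path:
            s = s[p]
        return s

    def replace(s, path, new):
        if not path:
            return new
        return tuple(replace(s[k], path[1:], new) if k == path[0] else s[k]
                     for k in range(len(s)))

    def walk(path):
        node = at(struct, path)
        if isinstance(node, str):
            return
        # edge above `node` (if path nonempty => parent exists) is internal
        if path:
            parent_path = path[:-1]
            parent = at(struct, parent_path)
            siblings = [k for k in range(len(parent)) if k != path[-1]]
            # swap each child of `node` with each sibling subtree
            for ci in range(len(node)):
                for sk in siblings:
                    new_node = tuple(parent[sk] if m == ci else node[m]
                                     for m in range(len(node)))
                    new_parent = tuple(
                        node[ci] if k == sk else
                        (new_node if k == path[-1] else parent[k])
                        for k in range(len(parent)))
                    neighbors.append(replace(struct, parent_path, new_parent))
        for k in range(len(node)):
            walk(path + (k,))

    walk(())
    return neighbors


def parsimony_tree(aln: Alignment, model: SubstitutionModel | None = None,
                   max_rounds: int = 50) -> dendropy.Tree:
    """Parsimony inference: NNI hill climbing on the Fitch score from an
    NJ starting tree (p-distances)."""
    from .saturation import p_distance_matrix
    start = nj_tree(p_distance_matrix(aln).fillna(0.75))
    tns = start.taxon_namespace
    struct = _struct_of_tree(start)
    best_score = fitch_parsimony(start, aln)
    for _ in range(max_rounds):
        improved = False
        for cand in _struct_nni_neighbors(struct):
            tree = _struct_to_tree(cand, tns)
            score = fitch_parsimony(tree, aln)
            if score < best_score:
                struct, best_score, improved = cand, score, True
                break
        if not improved:
            break
    return _struct_to_tree(struct, tns)


# ---------------------------------------------------------------------------
# trichotomy classification and support
# ---------------------------------------------------------------------------

def _leaf_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits = set()
    sets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*[sets[id(c)] for c in node.child_nodes()])
            sets[id(node)] = s
            splits.add(s)
            splits.add(leaves - s)
    for lf in leaves:
        splits.add(frozenset([lf]))
        splits.add(leaves - frozenset([lf]))
    return splits


def classify_trichotomy(tree: dendropy.Tree, clades: dict[str, set],
                        outgroup: set) -> str:
    """Classify a tree by the resolution of the focal trichotomy.

    ``clades`` maps three names to disjoint taxon sets which, with the
    outgroup, cover all leaves.  Returns ``"A(B,C)"`` (clade A sister to
    the B+C pair) in clade-name notation, or ``"other"`` when any clade is
    non-monophyletic or the trichotomy is unresolved.
    """
    if len(clades) != 3:
        raise ValueError("exactly three clades required")
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    sets = {k: frozenset(v) for k, v in clades.items()}
    out = frozenset(outgroup)
    union = frozenset().union(out, *sets.values())
    if union != leaves:
        raise ValueError("clades + outgroup must cover all leaves")
    splits = _leaf_bipartitions(tree)
    for s in sets.values():
        if s not in splits:
            return "other"
    names = list(sets)
    for a in names:
        b, c = [n for n in names if n != a]
        if (sets[b] | sets[c]) in splits:
            return f"{a}({b},{c})"
    return "other"


@dataclass
class HypothesisSupport:
    """Bootstrap proportions for the three rival trichotomy resolutions."""

    counts: dict[str, int]
    n_reps: int
    seed: int
    method: str

    @property
    def proportions(self) -> dict[str, float]:
        return {k: v / self.n_reps for k, v in self.counts.items()}


def bootstrap_support(aln: Alignment, clades: dict[str, set], outgroup: set,
                      infer: str = "nj", n_reps: int = 100, seed: int = 0,
                      model: SubstitutionModel | None = None,
                      distance_model: str = "GTR") -> HypothesisSupport:
    """Column-bootstrap support for the rival trichotomy resolutions.

    Each replicate resamples columns with replacement, infers a tree
    (``nj``, ``parsimony`` or ``ml``), and classifies the focal
    trichotomy.  Deterministic given the seed.
    """
    from .saturation import ml_distance_matrix
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    rng = np.random.default_rng(seed)
    names = list(clades)
    labels = [f"{a}({b},{c})"
              for a in names
              for b, c in [[n for n in names if n != a]]]
    counts = {lab: 0 for lab in labels}
    counts["other"] = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_columns, aln.n_columns)
        rep = Alignment(aln.taxa, aln.matrix[:, cols], aln.molecule)
        if infer == "nj":
            D = ml_distance_matrix(rep, model=distance_model)
            tree = nj_tree(D.fillna(5.0))
        elif infer == "parsimony":
            tree = parsimony_tree(rep)
        elif infer == "ml":
            if model is None:
                raise ValueError("ml bootstrap needs a substitution model")
            tree, _, _, _ = exhaustive_ml_search(rep, model)
        else:
            raise ValueError(f"unknown inference method {infer!r}")
        label = classify_trichotomy(tree, clades, outgroup)
        counts[label] = counts.get(label, 0) + 1
    return HypothesisSupport(counts=counts, n_reps=n_reps, seed=seed,
                             method=infer)


# ---------------------------------------------------------------------------
# stem-branch diagnostics
# ---------------------------------------------------------------------------

@dataclass
class CladeBranchReport:
    """Per-clade stem branch lengths and ratios to a reference clade."""

    entries: dict[str, dict] = field(default_factory=dict)
    reference: str = ""


def root_by_outgroup(tree: dendropy.Tree, outgroup: set) -> dendropy.Tree:
    """Clone and root the tree on the edge subtending the outgroup MRCA."""
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    out = set(outgroup)
    taxa = [t for t in tree.taxon_namespace if t.label in out]
    if not taxa:
        raise TreeError("outgroup taxa not in tree")
    if len(taxa) == 1:
        node = tree.find_node_with_taxon_label(taxa[0].label)
    else:
        node = tree.mrca(taxa=taxa)
    if node is tree.seed_node:
        # outgroup wraps the current root: root on the ingroup MRCA instead
        in_taxa = [t for t in tree.taxon_namespace if t.label not in out]
        node = tree.mrca(taxa=in_taxa)
        if node is tree.seed_node:
            return tree
    length = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=length / 2.0,
                        length2=length / 2.0,
                        update_bipartitions=False)
    return tree


def stem_branch_report(tree: dendropy.Tree, clades: dict[str, set],
                       reference: str, outgroup: set) -> CladeBranchReport:
    """Stem (subtending) branch length of each clade, and ratios.

    The tree is rooted on the outgroup edge first; a clade's stem is the
    edge above its MRCA.  Non-monophyletic clades are flagged with a
    missing length.
    """
    if reference not in clades:
        raise ValueError(f"reference clade {reference!r} not defined")
    rooted = root_by_outgroup(tree, outgroup)
    leafsets: dict[int, frozenset] = {}
    for node in rooted.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = frozenset([node.taxon.label])
        else:
            leafsets[id(node)] = frozenset().union(
                *[leafsets[id(c)] for c in node.child_nodes()])
    report = CladeBranchReport(reference=reference)
    stems: dict[str, float | None] = {}
    for name, taxa in clades.items():
        target = frozenset(taxa)
        stem = None
        for node in rooted.postorder_node_iter():
            if leafsets[id(node)] == target:
                stem = node.edge.length
                break
        stems[name] = stem
        report.entries[name] = {
            "monophyletic": stem is not None,
            "stem_length": stem,
        }
    ref = stems.get(reference)
    for name in clades:
        stem = stems[name]
        if ref in (None, 0.0) or stem is None:
            report.entries[name]["ratio"] = None
        else:
            report.entries[name]["ratio"] = stem / ref
    return report
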