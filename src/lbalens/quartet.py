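"""Quartet-agreement species-tree estimation.

The objective is the summary-coalescent quartet score: the number of
induced four-taxon topologies, over all gene trees and all 4-subsets of
taxa present in a gene, that agree with a candidate species tree.  Under
the multispecies coalescent the most probable gene-tree quartet topology
always matches the species tree, so the argmax species tree is a
statistically consistent estimate.  The search is exhaustive for small
taxon counts and an NNI hill climb from a gene-tree-distance NJ start
otherwise; gene trees contribute topology only (branch lengths and
support values are ignored).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

from .trees import (_enumerate_unrooted_topologies, _struct_nni_neighbors,
                    _struct_of_tree, _struct_to_tree, nj_tree)

UNRESOLVED = "unresolved"


class QuartetError(ValueError):
    pass


def _leaf_splits(tree: dendropy.Tree) -> list[frozenset]:
    """Leaf sets of one side of every split (trivial ones included)."""
    sets: dict[int, frozenset] = {}
    splits = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset([node.taxon.label])
        else:
            sets[id(node)] = frozenset().union(
                *[sets[id(c)] for c in node.child_nodes()])
        splits.append(sets[id(node)])
    return splits


def induced_quartet(tree: dendropy.Tree, quartet) -> str:
    """Topology of the tree restricted to four taxa.

    Returns ``"ab|cd"``-style labels built from the given taxon names in
    sorted pairing order, or ``"unresolved"`` for a star restriction.
    """
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    q = list(quartet)
    if len(set(q)) != 4:
        raise QuartetError("need four distinct taxa")
    missing = set(q) - labels
    if missing:
        raise QuartetError(f"taxa not in tree: {sorted(missing)}")
    return _quartet_from_splits(_leaf_splits(tree), q)


def _quartet_from_splits(splits, q) -> str:
    a, b, c, d = q
    pairings = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    qset = frozenset(q)
    for (x, y), (u, v) in pairings:
        side1, side2 = frozenset((x, y)), frozenset((u, v))
        for s in splits:
            inter = qset & s
            if inter == side1 or inter == side2:
                return f"{x},{y}|{u},{v}"
    return UNRESOLVED


def _gene_quartet_table(tree: dendropy.Tree) -> dict[frozenset, frozenset]:
    """Map each resolved 4-subset of the gene's taxa to its sister pair
    {x, y} (one side of the induced split)."""
    splits = _leaf_splits(tree)
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    table: dict[frozenset, frozenset] = {}
    for q in combinations(labels, 4):
        qset = frozenset(q)
        for s in splits:
            inter = qset & s
            if len(inter) == 2:
                other = qset - inter
                # a valid split: check the complement side is consistent
                table[qset] = frozenset([frozenset(inter), frozenset(other)])
                break
    return table


def quartet_score(species: dendropy.Tree,
                  genes: list[dendropy.Tree]) -> int:
    """Number of gene-tree quartets agreeing with the species tree.

    Gene trees may miss taxa (those quartets are skipped); unresolved
    gene quartets contribute zero.
    """
    sp_splits = _leaf_splits(species)
    score = 0
    for gene in genes:
        table = _gene_quartet_table(gene)
        for qset, pairing in table.items():
            sides = None
            for s in sp_splits:
                inter = qset & s
                if len(inter) == 2:
                    sides = frozenset([frozenset(inter),
                                       frozenset(qset - inter)])
                    break
            if sides is not None and sides == pairing:
                score += 1
    return score


@dataclass
class QuartetScoreResult:
    """Species tree maximising the quartet score."""

    species_tree: dendropy.Tree
    score: int
    n_quartets_total: int
    search: str
    ties: list = field(default_factory=list)

    @property
    def normalized_score(self) -> float:
        return self.score / self.n_quartets_total if self.n_quartets_total \
            else float("nan")


def _all_taxa(genes: list[dendropy.Tree]) -> list[str]:
    taxa = set()
    for g in genes:
        taxa |= {lf.taxon.label for lf in g.leaf_node_iter()}
    return sorted(taxa)


def _n_quartets_total(genes: list[dendropy.Tree], n_taxa: int) -> int:
    from math import comb
    return len(genes) * comb(n_taxa, 4)


def exact_species_tree(genes: list[dendropy.Tree],
                       max_taxa: int = 9) -> QuartetScoreResult:
    """Exhaustive search over all unrooted topologies for the quartet-score
    optimum; ties are reported as a list."""
    taxa = _all_taxa(genes)
    if len(taxa) > max_taxa:
        raise QuartetError(f"{len(taxa)} taxa exceeds exhaustive limit "
                           f"{max_taxa}")
    if len(taxa) < 4:
        raise QuartetError("need >= 4 taxa")
    tns = dendropy.TaxonNamespace(taxa)
    best, best_score, ties = None, -1, []
    for struct in _enumerate_unrooted_topologies(taxa, tns):
        tree = _struct_to_tree(struct, tns)
        s = quartet_score(tree, genes)
        if s > best_score:
            best, best_score, ties = tree, s, []
        elif s == best_score:
            ties.append(tree)
    return QuartetScoreResult(species_tree=best, score=best_score,
                              n_quartets_total=_n_quartets_total(
                                  genes, len(taxa)),
                              search="exact", ties=ties)


def _mean_internode_distance(genes: list[dendropy.Tree],
                             taxa: list[str]) -> pd.DataFrame:
    """Average topological (internode-count) distance between taxon pairs
    over the gene trees containing both."""
    n = len(taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for gene in genes:
        pdm = gene.phylogenetic_distance_matrix()
        for t1, t2 in combinations(gene.taxon_namespace, 2):
            steps = pdm.path_edge_count(t1, t2)
            i, j = idx[t1.label], idx[t2.label]
            total[i, j] += steps
            total[j, i] += steps
            count[i, j] += 1
            count[j, i] += 1
    with np.errstate(invalid="ignore"):
        D = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=taxa, columns=taxa)


def heuristic_species_tree(genes: list[dendropy.Tree],
                           seed: int = 0,
                           max_rounds: int = 100) -> QuartetScoreResult:
    """NNI hill climb on the quartet score from an NJ start on mean
    gene-tree internode distances.  Deterministic given the seed (the
    seed only breaks ties among equally scoring neighbors)."""
    taxa = _all_taxa(genes)
    if len(taxa) < 4:
        raise QuartetError("need >= 4 taxa")
    D = _mean_internode_distance(genes, taxa)
    start = nj_tree(D.fillna(float(np.nanmax(D.to_numpy()) or 1.0)))
    tns = start.taxon_namespace
    struct = _struct_of_tree(start)
    best_score = quartet_score(_struct_to_tree(struct, tns), genes)
    rng = np.random.default_rng(seed)
    for _ in range(max_rounds):
        neighbors = _struct_nni_neighbors(struct)
        scores = [quartet_score(_struct_to_tree(c, tns), genes)
                  for c in neighbors]
        top = max(scores, default=best_score)
        if top <= best_score:
            break
        candidates = [c for c, s in zip(neighbors, scores) if s == top]
        struct = candidates[int(rng.integers(len(candidates)))]
        best_score = top
    return QuartetScoreResult(
        species_tree=_struct_to_tree(struct, tns), score=best_score,
        n_quartets_total=_n_quartets_total(genes, len(taxa)),
        search="heuristic")
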