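"""Synthetic data generation: GTR+Gamma sequence simulation on trees,
Felsenstein-zone and three-crown (J-C-HCX-shaped) scenarios, multispecies
coalescent gene trees, and exact-count fixture alignments.

Everything is deterministic given a seed.  The simulator draws root states
from the model's stationary frequencies, assigns each site a Gamma rate
category once, and propagates states down the tree with ``exp(Q t r)``
transition probabilities.  Codon structure in simulated genes is positional
rate scaling (third positions evolve faster by a configurable factor), not
a codon model — enough to give codon-position filtering something real to
remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import NT_STATES, Alignment
from .models import SubstitutionModel

DEFAULT_THIRD_POSITION_RATE = 5.0


def _check_rooted_with_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            raise ValueError("simulation tree needs branch lengths on all edges")
        if edge.length < 0:
            raise ValueError("negative branch length")


def simulate_alignment(tree: dendropy.Tree, model: SubstitutionModel,
                       length: int, seed: int = 0,
                       site_rate_multipliers: np.ndarray | None = None
                       ) -> Alignment:
    """Evolve ``length`` sites along ``tree`` under ``model``.

    ``site_rate_multipliers`` (optional, length ``length``) scales each
    site's rate on top of the Gamma category draw — used for codon-position
    rate structure.
    """
    _check_rooted_with_lengths(tree)
    rng = np.random.default_rng(seed)
    cat_rates = model.category_rates()
    cats = rng.integers(0, len(cat_rates), length)
    rates = cat_rates[cats]
    if site_rate_multipliers is not None:
        mult = np.asarray(site_rate_multipliers, dtype=float)
        if mult.shape != (length,):
            raise ValueError("one rate multiplier per site required")
        rates = rates * mult

    root_states = rng.choice(4, size=length, p=model.freqs)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}
    unique_rates = np.unique(rates)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = states[id(node.parent_node)]
        child = np.empty(length, dtype=np.int64)
        t = node.edge.length
        u = rng.random(length)
        for r in unique_rates:
            mask = rates == r
            P = model.transition_matrix(t * r)
            cum = np.cumsum(P, axis=1)
            cum[:, -1] = 1.0
            child[mask] = (u[mask, None] > cum[parent[mask]]).sum(axis=1)
        states[id(node)] = child

    leaves = [n for n in tree.leaf_node_iter()]
    taxa = [leaf.taxon.label for leaf in leaves]
    lookup = np.array(list(NT_STATES))
    mat = np.stack([lookup[states[id(leaf)]] for leaf in leaves])
    return Alignment(taxa, mat, "nt")


def codon_rate_multipliers(length: int,
                           third_rate: float = DEFAULT_THIRD_POSITION_RATE
                           ) -> np.ndarray:
    """Per-site multipliers giving third codon positions a faster rate,
    normalised to mean 1 over each codon."""
    if length % 3:
        raise ValueError("length must be divisible by 3")
    triplet = np.array([1.0, 1.0, third_rate])
    triplet = triplet / triplet.mean()
    return np.tile(triplet, length // 3)


def felsenstein_zone_tree(p: float, q: float) -> dendropy.Tree:
    """Unrooted 4-taxon tree ((A:p, B:q):q, C:p, D:q).

    The two long branches (A and C) are non-adjacent, separated by the
    short internal branch — the classic regime where parsimony is
    inconsistent.  Warns (does not fail) when p <= q.
    """
    if q <= 0 or p <= 0:
        raise ValueError("branch lengths must be positive")
    if p <= q:
        import logging
        logging.getLogger(__name__).warning(
            "p=%g <= q=%g: not in the Felsenstein zone", p, q)
    nwk = f"((A:{p},B:{q}):{q},C:{p},D:{q});"
    return dendropy.Tree.get(data=nwk, schema="newick",
                             rooting="default-rooted")


@dataclass
class SimScenario:
    """A fully specified generative scenario.

    ``species_tree`` carries branch lengths in expected substitutions per
    site; for coalescent gene-tree sampling ``coalescent_tree`` carries
    internal branch lengths in coalescent units.
    """

    species_tree: dendropy.Tree
    model: SubstitutionModel
    n_genes: int = 20
    gene_length: int = 300
    seed: int = 0
    clades: dict[str, list[str]] = field(default_factory=dict)
    outgroup: list[str] = field(default_factory=list)
    true_resolution: str = ""
    heterotachy: bool = False
    heterotachy_sigma: float = 0.4
    third_position_rate: float = DEFAULT_THIRD_POSITION_RATE
    coalescent_tree: dendropy.Tree | None = None

    def simulate_supermatrix(self):
        """Simulate ``n_genes`` codon-structured genes and concatenate.

        Returns ``(alignment, partition_map, gene_alignments)``.
        """
        from .alignment import concatenate
        rng = np.random.default_rng(self.seed)
        genes, names = [], []
        mult = codon_rate_multipliers(self.gene_length,
                                      self.third_position_rate)
        for g in range(self.n_genes):
            tree = self.species_tree
            if self.heterotachy:
                tree = self.species_tree.clone(depth=1)
                for edge in tree.preorder_edge_iter():
                    if edge.tail_node is not None and edge.length:
                        edge.length *= float(rng.lognormal(
                            0.0, self.heterotachy_sigma))
            aln = simulate_alignment(
                tree, self.model, self.gene_length,
                seed=int(rng.integers(2 ** 31)),
                site_rate_multipliers=mult)
            order = sorted(aln.taxa)
            idx = [aln.taxa.index(t) for t in order]
            genes.append(Alignment(order, aln.matrix[idx]))
            names.append(f"gene{g + 1:03d}")
        return (*concatenate(genes, names), genes)


_RESOLUTIONS = {
    "J(C,HCX)": ("J", "C", "HCX"),
    "C(J,HCX)": ("C", "J", "HCX"),
    "HCX(J,C)": ("HCX", "J", "C"),
}


def jcx_scenario(stem_J: float = 0.45, stem_C: float = 0.35,
                 stem_HCX: float = 0.06,
                 internal_1: float = 0.008, internal_2: float = 0.008,
                 crown_length: float = 0.03, outgroup_length: float = 0.3,
                 true_resolution: str = "J(C,HCX)",
                 model: SubstitutionModel | None = None,
                 n_genes: int = 20, gene_length: int = 300,
                 seed: int = 0, heterotachy: bool = False) -> SimScenario:
    """Three-crown LBA scenario: two long-stemmed crowns (J, C) and one
    short-stemmed crown (HCX) separated by short internals, plus one
    outgroup — a 10-taxon caricature of a long-branch-attraction-prone
    subfamily radiation.

    The default stems put the two long branches on non-sister lineages
    under the default ``J(C,HCX)`` resolution, with terminal-change
    probabilities whose square exceeds the internal-change probability —
    the inconsistency condition for parsimony — while the homoplasy is
    concentrated on fast (Gamma + third-position) sites so that fast-site
    filtering genuinely removes it.
    """
    if true_resolution not in _RESOLUTIONS:
        raise ValueError(f"unknown resolution {true_resolution!r}; "
                         f"one of {sorted(_RESOLUTIONS)}")
    first, second, third = _RESOLUTIONS[true_resolution]
    stems = {"J": stem_J, "C": stem_C, "HCX": stem_HCX}

    def crown(name: str) -> str:
        t = crown_length
        return (f"(({name}1:{t},{name}2:{t}):{t},{name}3:{2 * t})"
                f":{stems[name]}")

    nwk = (f"(OUT1:{outgroup_length},({crown(first)},"
           f"({crown(second)},{crown(third)}):{internal_2})"
           f":{internal_1});")
    tree = dendropy.Tree.get(data=nwk, schema="newick",
                             rooting="default-rooted")
    if model is None:
        model = SubstitutionModel(
            freqs=np.array([0.31, 0.19, 0.19, 0.31]),
            rates=np.array([1.2, 3.5, 0.9, 1.1, 3.8, 1.0]),
            alpha=0.4, name="GTR+G")
    clades = {name: [f"{name}1", f"{name}2", f"{name}3"]
              for name in ("J", "C", "HCX")}
    return SimScenario(species_tree=tree, model=model, n_genes=n_genes,
                       gene_length=gene_length, seed=seed, clades=clades,
                       outgroup=["OUT1"], true_resolution=true_resolution,
                       heterotachy=heterotachy)


# ---------------------------------------------------------------------------
# multispecies coalescent
# ---------------------------------------------------------------------------

def simulate_msc_gene_trees(species: dendropy.Tree, n_genes: int,
                            seed: int = 0) -> list[dendropy.Tree]:
    """Sample gene trees under the multispecies coalescent.

    ``species`` must be rooted with internal branch lengths in coalescent
    units (terminal branch lengths are irrelevant with one sample per
    species and may be any value).  Gene-tree node ages are in coalescent
    units; topologies are what downstream quartet methods consume.
    """
    for node in species.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("species tree needs branch lengths (coalescent "
                             "units) on all edges")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(
        [lf.taxon.label for lf in species.leaf_node_iter()])
    trees = []
    for _ in range(n_genes):
        trees.append(_sample_one_gene_tree(species, rng, tns))
    return trees


def _sample_one_gene_tree(species: dendropy.Tree, rng: np.random.Generator,
                          tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    # lineage = (gene-tree node, age); populations processed postorder
    lineages: dict[int, list] = {}

    def coalesce(pool: list, start_age: float, max_len: float) -> list:
        age = start_age
        pool = list(pool)
        while len(pool) > 1:
            k = len(pool)
            wait = rng.exponential(1.0 / (k * (k - 1) / 2.0))
            if age + wait > start_age + max_len:
                break
            age += wait
            i, j = sorted(rng.choice(k, 2, replace=False))
            node = dendropy.Node()
            a, b = pool[j], pool[i]
            for child, child_age in (a, b):
                node.add_child(child)
                child.edge.length = age - child_age
            del pool[j], pool[i]
            pool.append((node, age))
        return pool

    # species node ages from branch lengths (root age = max path)
    depth = {}
    for node in species.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
    max_depth = max(depth[id(lf)] for lf in species.leaf_node_iter())
    age_of = {k: max_depth - v for k, v in depth.items()}

    for node in species.postorder_node_iter():
        if node.is_leaf():
            gnode = dendropy.Node(taxon=tns.get_taxon(node.taxon.label))
            lineages[id(node)] = [(gnode, age_of[id(node)])]
        else:
            pool = []
            for child in node.child_nodes():
                pool.extend(lineages[id(child)])
            if node.parent_node is None:
                pool = coalesce(pool, age_of[id(node)], np.inf)
            else:
                pool = coalesce(pool, age_of[id(node)], node.edge.length)
            lineages[id(node)] = pool

    root_pool = lineages[id(species.seed_node)]
    assert len(root_pool) == 1
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root_pool[0][0]
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# exact-count fixtures
# ---------------------------------------------------------------------------

def fixture_alignment(n_taxa: int, n_constant: int,
                      n_variable_uninformative: int, n_pis: int,
                      seed: int = 0) -> Alignment:
    """Alignment with exactly the requested count of each site class.

    Constant columns carry one random base; variable-uninformative
    columns a single-taxon singleton state; parsimony-informative columns
    a two-state split whose minor-side size varies (2..n_taxa-2), giving
    the informative sites a genuine spread of observed variability for
    rate ranking.  Column order is shuffled by the seed.
    """
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa (informative sites need 2+2)")
    for name, n in (("constant", n_constant),
                    ("variable", n_variable_uninformative),
                    ("pis", n_pis)):
        if n < 0:
            raise ValueError(f"negative count for {name}")
    rng = np.random.default_rng(seed)
    total = n_constant + n_variable_uninformative + n_pis
    codes = np.empty((n_taxa, total), dtype=np.int8)
    j = 0
    if n_constant:
        codes[:, j:j + n_constant] = rng.integers(0, 4, n_constant)[None, :]
        j += n_constant
    if n_variable_uninformative:
        base = rng.integers(0, 4, n_variable_uninformative)
        block = np.broadcast_to(base, (n_taxa, n_variable_uninformative)).copy()
        rows = rng.integers(0, n_taxa, n_variable_uninformative)
        block[rows, np.arange(n_variable_uninformative)] = \
            (base + rng.integers(1, 4, n_variable_uninformative)) % 4
        codes[:, j:j + n_variable_uninformative] = block
        j += n_variable_uninformative
    if n_pis:
        base = rng.integers(0, 4, n_pis)
        alt = (base + rng.integers(1, 4, n_pis)) % 4
        block = np.broadcast_to(base, (n_taxa, n_pis)).copy()
        minor = rng.integers(2, n_taxa - 1, n_pis)  # 2..n_taxa-2 inclusive
        # assign the alt state to a random subset of `minor` rows per column
        for col in range(n_pis):
            rows = rng.choice(n_taxa, minor[col], replace=False)
            block[rows, col] = alt[col]
        codes[:, j:j + n_pis] = block
    perm = rng.permutation(total)
    codes = codes[:, perm]
    lookup = np.array(list(NT_STATES))
    taxa = [f"t{i + 1:02d}" for i in range(n_taxa)]
    return Alignment(taxa, lookup[codes])
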