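"""Species tree search: greedy placement, NNI refinement, constrained DP.

Pipeline: random-order stepwise placement builds R initial binary trees,
each is hill-climbed with nearest-neighbor interchanges, and a dynamic
program over the bipartition set harvested from the refined trees returns
the binary tree with the maximum quartet score within that constraint set.

All candidate trees here are kept rooted at an internal trifurcation (the
standard representation of an unrooted binary tree); every non-root node
corresponds to one unrooted edge.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .treeio import PhyloTree, TreeNode, Bipartition
from .quartet_core import (
    GeneTreeSet,
    WeightScheme,
    UNIT,
    Score,
    fast_score,
    species_tree_tripartitions,
)

__all__ = [
    "SearchConfig",
    "ConstraintSet",
    "place_taxon",
    "build_initial_trees",
    "nni_improve",
    "build_constraint_set",
    "dp_optimal_tree",
    "infer",
]


@dataclass
class SearchConfig:
    """Knobs of the three-stage search; identical seed => identical tree."""

    n_initial: int = 4
    seed: int = 0
    nni_max_rounds: int = 50
    scheme: WeightScheme = field(default_factory=lambda: UNIT)

    def __post_init__(self):
        if self.n_initial < 1:
            raise ValueError("need at least one initial tree")


# ---------------------------------------------------------------------------
# scoring helpers (numerator only: denominators cancel on a fixed taxon set)


def _numerator(tree: PhyloTree, genes: GeneTreeSet, scheme: WeightScheme) -> float:
    trips = species_tree_tripartitions(tree, genes)
    return sum(genes.gain(t, scheme) for t in trips) / 2.0


def _leafset_below(node: TreeNode) -> frozenset:
    return frozenset(l.label for l in node.leaves())


def _canonical_edge_key(node: TreeNode):
    return tuple(sorted(_leafset_below(node)))


# ---------------------------------------------------------------------------
# stepwise placement


def _attach(node: TreeNode, leaf_label: str) -> TreeNode:
    """Split the edge above ``node`` and hang a new leaf; return the new
    internal node (for undo)."""
    parent = node.parent
    mid = TreeNode()
    idx = parent.children.index(node)
    parent.children[idx] = mid
    mid.parent = parent
    mid.add_child(node)
    mid.add_child(TreeNode(label=leaf_label))
    return mid


def _detach(mid: TreeNode) -> None:
    node = mid.children[0]
    parent = mid.parent
    idx = parent.children.index(mid)
    parent.children[idx] = node
    node.parent = parent


def place_taxon(
    partial: PhyloTree, species: str, genes: GeneTreeSet, scheme: WeightScheme = UNIT
) -> PhyloTree:
    """Attach ``species`` to the edge of ``partial`` maximizing the score.

    Ties break on the lexicographically smallest edge (by the sorted
    leafset below it).  The input tree is modified in place and returned.
    """
    edges = [n for n in partial.postorder() if n.parent is not None]
    edges.sort(key=_canonical_edge_key)
    best = None
    for node in edges:
        mid = _attach(node, species)
        s = _numerator(partial, genes, scheme)
        _detach(mid)
        if best is None or s > best[0]:
            best = (s, node)
    _attach(best[1], species)
    return partial


def _star3(labels: Sequence[str]) -> PhyloTree:
    root = TreeNode()
    for l in labels:
        root.add_child(TreeNode(label=l))
    return PhyloTree(root)


def build_initial_trees(genes: GeneTreeSet, config: SearchConfig) -> List[PhyloTree]:
    """R binary trees from independent random placement orders."""
    rng = random.Random(config.seed)
    out = []
    for _ in range(config.n_initial):
        order = list(genes.species)
        rng.shuffle(order)
        tree = _star3(order[:3])
        for sp in order[3:]:
            place_taxon(tree, sp, genes, config.scheme)
        out.append(tree)
    return out


# ---------------------------------------------------------------------------
# NNI hill climbing


def _nni_swap(u: TreeNode, v: TreeNode, s: TreeNode, x: TreeNode) -> None:
    """Exchange subtree ``s`` (child of u) with ``x`` (child of v)."""
    iu = u.children.index(s)
    iv = v.children.index(x)
    u.children[iu], v.children[iv] = x, s
    x.parent, s.parent = u, v


def nni_improve(
    tree: PhyloTree,
    genes: GeneTreeSet,
    scheme: WeightScheme = UNIT,
    max_rounds: int = 50,
) -> Tuple[PhyloTree, float]:
    """Best-improvement NNI sweeps until a local optimum (or max_rounds).

    Returns the improved tree (modified in place) and its score numerator;
    the returned score is never below the input score.
    """
    current = _numerator(tree, genes, scheme)
    for _ in range(max_rounds):
        best_gain = 0.0
        best_move = None
        internal_edges = [
            v for v in tree.postorder() if v.children and v.parent is not None
        ]
        internal_edges.sort(key=_canonical_edge_key)
        for v in internal_edges:
            u = v.parent
            s = next(c for c in u.children if c is not v)
            for x in list(v.children):
                _nni_swap(u, v, s, x)
                score = _numerator(tree, genes, scheme)
                _nni_swap(u, v, x, s)  # undo
                if score - current > best_gain:
                    best_gain = score - current
                    best_move = (u, v, s, x)
        if best_move is None:
            break
        _nni_swap(*best_move)
        current += best_gain
    return tree, current


# ---------------------------------------------------------------------------
# constraint set and dynamic programming


@dataclass
class ConstraintSet:
    """Clusters (as species bitmasks) the DP may use, rooted at a reference
    species (bit 0 of the mask space, excluded from every cluster)."""

    genes: GeneTreeSet
    clusters: Set[int]

    @property
    def full(self) -> int:
        return self.genes.full_mask & ~1  # all species minus the reference

    def bipartitions(self) -> Set[Bipartition]:
        out = set()
        n = self.genes.full_mask
        for c in self.clusters:
            other = n ^ c
            if c and other and bin(c).count("1") >= 2 and bin(other).count("1") >= 2:
                out.add(
                    Bipartition(
                        self.genes.labels_of_mask(c), self.genes.labels_of_mask(other)
                    )
                )
        return out


def build_constraint_set(
    trees: Sequence[PhyloTree], genes: GeneTreeSet, complete: bool = True
) -> ConstraintSet:
    """Union of all input-tree clusters, plus trivial clusters, plus one
    round of pairwise intersection/difference completion."""
    full = genes.full_mask & ~1
    clusters: Set[int] = {full}
    for i in range(1, len(genes.species)):
        clusters.add(1 << i)
    for tree in trees:
        t = tree.unrooted()
        below: Dict[int, int] = {}
        for node in t.postorder():
            if node.is_leaf:
                below[id(node)] = 1 << genes.sp_index[node.label]
            else:
                below[id(node)] = 0
                for c in node.children:
                    below[id(node)] |= below[id(c)]
            m = below[id(node)]
            if m & 1:  # canonical side: the one without the reference
                m = genes.full_mask ^ m
            if m:
                clusters.add(m)
    clusters.discard(0)
    if complete:
        base = sorted(clusters)
        new: Set[int] = set()
        for i, a in enumerate(base):
            for b in base[i + 1 :]:
                for cand in (a & b, a & ~b, b & ~a, full & ~(a | b)):
                    if cand and cand not in clusters:
                        new.add(cand)
        clusters |= new
    return ConstraintSet(genes, clusters)


class NoTreeInConstraintSet(ValueError):
    pass


def dp_optimal_tree(
    X: ConstraintSet, genes: GeneTreeSet, scheme: WeightScheme = UNIT
) -> Tuple[PhyloTree, float]:
    """Highest-scoring binary tree whose bipartitions all lie in ``X``.

    Recursion on clusters: best(A) maximizes best(A1) + best(A2) +
    gain((A1, A2, complement)) over splits with both halves in ``X``;
    provably optimal within the constraint set.
    """
    full = X.full
    universe = genes.full_mask
    clusters = sorted(X.clusters | {full}, key=lambda m: (bin(m).count("1"), m))
    cluster_set = set(clusters)
    best: Dict[int, float] = {}
    split: Dict[int, Tuple[int, int]] = {}
    for a in clusters:
        if bin(a).count("1") == 1:
            best[a] = 0.0
            continue
        for a1 in clusters:
            if a1 == a or a1 & a != a1 or a1 not in best:
                continue
            a2 = a & ~a1
            if a1 > a2:
                continue  # canonical order; a2 visited as a1 in its turn
            if a2 not in cluster_set or a2 not in best:
                continue
            g = genes.gain((a1, a2, universe ^ a), scheme)
            s = best[a1] + best[a2] + g
            if a not in best or s > best[a]:
                best[a] = s
                split[a] = (a1, a2)
    if full not in best:
        raise NoTreeInConstraintSet(
            "constraint set admits no binary tree; add more initial trees"
        )

    def build(mask: int) -> TreeNode:
        if bin(mask).count("1") == 1:
            return TreeNode(label=genes.species[mask.bit_length() - 1])
        a1, a2 = split[mask]
        node = TreeNode()
        node.add_child(build(a1))
        node.add_child(build(a2))
        return node

    root = TreeNode()
    root.add_child(TreeNode(label=genes.species[0]))
    a1, a2 = split[full]
    root.add_child(build(a1))
    root.add_child(build(a2))
    return PhyloTree(root), best[full] / 2.0


# ---------------------------------------------------------------------------
# full pipeline


def infer(
    genes: GeneTreeSet,
    config: Optional[SearchConfig] = None,
    log=None,
) -> Tuple[PhyloTree, Score]:
    """Three-stage search for the maximum-quartet-score species tree."""
    if config is None:
        config = SearchConfig()
    if len(genes.species) < 4:
        raise ValueError("need >= 4 species to infer a tree")
    scheme = config.scheme

    initial = build_initial_trees(genes, config)
    refined = []
    for i, t in enumerate(initial):
        t, s = nni_improve(t, genes, scheme, config.nni_max_rounds)
        refined.append(t)
        if log:
            log(f"initial tree {i + 1}: score {s:.6g}")
    X = build_constraint_set(refined, genes)
    tree, value = dp_optimal_tree(X, genes, scheme)
    if log:
        log(f"DP over {len(X.clusters)} clusters: score {value:.6g}")
    score = fast_score(tree, genes, scheme)
    return tree, score
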