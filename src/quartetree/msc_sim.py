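"""Multispecies-coalescent gene tree simulation with optional error models.

Provides every synthetic fixture the test suite needs: gene trees drawn
under the MSC on a rooted species tree with coalescent-unit branch
lengths, optional topological error (random NNI), synthetic branch
supports, and random taxon dropout.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .treeio import PhyloTree, TreeNode, write_newick_file
from .quartet_core import GeneTreeSet

__all__ = [
    "SpeciesTreeModel",
    "ErrorModel",
    "simulate_gene_tree",
    "apply_error",
    "simulate_dataset",
    "balanced_model",
]


@dataclass
class SpeciesTreeModel:
    """Rooted binary species tree with coalescent-unit branch lengths.

    Missing terminal branch lengths default to ``default_terminal`` (the
    coalescent process below species level never matters with one sampled
    lineage, but multi-individual sampling does coalesce there).
    """

    tree: PhyloTree
    default_terminal: float = 1.0

    def __post_init__(self):
        t = self.tree
        if len(t) < 4:
            raise ValueError("species tree model needs >= 4 leaves")
        for node in t.postorder():
            if len(node.children) not in (0, 2) and node is not t.root:
                raise ValueError("species tree model must be rooted binary")
            if node.parent is not None:
                if node.length is None:
                    if node.is_leaf:
                        node.length = self.default_terminal
                    else:
                        raise ValueError(
                            "internal species-tree branches need coalescent-unit lengths"
                        )
                elif node.length < 0:
                    raise ValueError("branch lengths must be >= 0")
        if len(t.root.children) != 2:
            raise ValueError("species tree model must be rooted binary")


@dataclass
class ErrorModel:
    """Gene-tree error: one random NNI with prob ``nni_prob``, synthetic
    supports (high for untouched branches, low for perturbed ones), and
    independent species dropout with prob ``p_miss`` (>= 4 leaves kept)."""

    nni_prob: float = 0.0
    p_miss: float = 0.0
    support_correct: Tuple[float, float] = (20.0, 1.0)  # Beta params
    support_perturbed: Tuple[float, float] = (2.0, 2.0)
    attach_supports: bool = True

    def __post_init__(self):
        for p in (self.nni_prob, self.p_miss):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0,1]")


def _coalesce_branch(
    lineages: List[Tuple[TreeNode, float]],
    length: float,
    bottom_age: float,
    rng: random.Random,
) -> List[Tuple[TreeNode, float]]:
    """Coalesce (node, height) lineages along one branch; rate j(j-1)/2."""
    t = 0.0
    lineages = list(lineages)
    while len(lineages) > 1:
        j = len(lineages)
        t += rng.expovariate(j * (j - 1) / 2.0)
        if t > length:
            break
        i1 = rng.randrange(j)
        i2 = rng.randrange(j - 1)
        if i2 >= i1:
            i2 += 1
        if i1 > i2:
            i1, i2 = i2, i1
        (n2, h2) = lineages.pop(i2)
        (n1, h1) = lineages.pop(i1)
        age = bottom_age + t
        parent = TreeNode()
        n1.length = age - h1
        n2.length = age - h2
        parent.add_child(n1)
        parent.add_child(n2)
        lineages.append((parent, age))
    return lineages


def simulate_gene_tree(
    model: SpeciesTreeModel, rng: random.Random, individuals: int = 1
) -> PhyloTree:
    """One gene tree under the MSC (one lineage per species by default).

    With ``individuals`` > 1, leaves are labeled ``<species>_<i>`` and
    ``individuals`` lineages enter the coalescent at each species tip.
    """
    ages: Dict[int, float] = {}
    active: Dict[int, List[Tuple[TreeNode, float]]] = {}
    st = model.tree
    for node in st.postorder():
        if node.is_leaf:
            ages[id(node)] = 0.0
            if individuals == 1:
                lineages = [(TreeNode(label=node.label), 0.0)]
            else:
                lineages = [
                    (TreeNode(label=f"{node.label}_{i + 1}"), 0.0)
                    for i in range(individuals)
                ]
        else:
            age = max(ages[id(c)] + c.length for c in node.children)
            ages[id(node)] = age
            lineages = []
            for c in node.children:
                lineages.extend(active.pop(id(c)))
        if node.parent is not None:
            active[id(node)] = _coalesce_branch(
                lineages, node.length, ages[id(node)], rng
            )
        else:  # above the root everything coalesces
            final = _coalesce_branch(lineages, math.inf, ages[id(node)], rng)
            root, _ = final[0]
            root.length = None
            return PhyloTree(root, rooted=True)
    raise AssertionError("unreachable")


def _random_nni(tree: PhyloTree, rng: random.Random) -> List[TreeNode]:
    """Apply one uniform random NNI in place; returns the perturbed nodes."""
    internal_edges = [
        v for v in tree.postorder() if v.children and v.parent is not None
    ]
    if not internal_edges:
        return []
    v = internal_edges[rng.randrange(len(internal_edges))]
    u = v.parent
    others = [c for c in u.children if c is not v]
    s = others[rng.randrange(len(others))]
    x = v.children[rng.randrange(len(v.children))]
    iu, iv = u.children.index(s), v.children.index(x)
    u.children[iu], v.children[iv] = x, s
    x.parent, s.parent = u, v
    # swapped subtrees keep their lengths; the edge lengths around v are
    # now only loosely meaningful, which mimics estimation error
    return [v]


def _prune_to(tree: PhyloTree, keep: set) -> PhyloTree:
    """Remove leaves outside ``keep``; suppress unary nodes (lengths sum)."""
    root = tree.root
    changed = True
    while changed:
        changed = False
        for node in list(root.postorder()):
            if node.is_leaf and node.label not in keep and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
            elif not node.is_leaf and len(node.children) == 1 and node.parent is not None:
                child = node.children[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                parent = node.parent
                parent.children[parent.children.index(node)] = child
                child.parent = parent
                changed = True
        while len(root.children) == 1:
            root = root.children[0]
            root.parent = None
            root.length = None
    return PhyloTree(root, rooted=tree.rooted)


def apply_error(tree: PhyloTree, err: ErrorModel, rng: random.Random) -> PhyloTree:
    """Perturb a gene tree: optional NNI, synthetic supports, dropout."""
    t = tree.unrooted()
    perturbed: set = set()
    if err.nni_prob > 0 and rng.random() < err.nni_prob:
        perturbed = {id(n) for n in _random_nni(t, rng)}
    if err.attach_supports:
        a_hi, b_hi = err.support_correct
        a_lo, b_lo = err.support_perturbed
        for node in t.postorder():
            if node.children and node.parent is not None:
                if id(node) in perturbed:
                    node.support = rng.betavariate(a_lo, b_lo)
                else:
                    node.support = rng.betavariate(a_hi, b_hi)
    if err.p_miss > 0:
        leaves = t.leaf_labels()
        keep = [l for l in leaves if rng.random() >= err.p_miss]
        if len(keep) < 4:
            dropped = [l for l in leaves if l not in keep]
            rng.shuffle(dropped)
            keep.extend(dropped[: 4 - len(keep)])
        if len(keep) < len(leaves):
            t = _prune_to(t, set(keep))
    return t


def simulate_dataset(
    model: SpeciesTreeModel,
    k: int,
    err: Optional[ErrorModel] = None,
    seed: int = 0,
    individuals: int = 1,
    rng: Optional[random.Random] = None,
) -> GeneTreeSet:
    """k independent MSC gene trees as a ready-to-score GeneTreeSet."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if rng is None:
        rng = random.Random(seed)
    trees = []
    for _ in range(k):
        g = simulate_gene_tree(model, rng, individuals=individuals)
        if err is not None:
            g = apply_error(g, err, rng)
        trees.append(g)
    taxon_map = None
    if individuals > 1:
        taxon_map = {
            f"{sp}_{i + 1}": sp
            for sp in model.tree.leaf_labels()
            for i in range(individuals)
        }
    return GeneTreeSet(trees, taxon_map=taxon_map)


def write_dataset(genes: GeneTreeSet, path) -> None:
    write_newick_file(genes.trees, path)


def balanced_model(n: int, internal: float = 1.0, terminal: float = 1.0) -> SpeciesTreeModel:
    """A caterpillar species tree on ``s1..sn`` with uniform internal
    branch lengths — a convenient synthetic truth."""
    if n < 4:
        raise ValueError("need >= 4 species")
    node = TreeNode()
    node.add_child(TreeNode(label="s1", length=terminal))
    node.add_child(TreeNode(label="s2", length=terminal))
    for i in range(3, n + 1):
        parent = TreeNode()
        node.length = internal
        parent.add_child(node)
        parent.add_child(TreeNode(label=f"s{i}", length=terminal))
        node = parent
    return SpeciesTreeModel(PhyloTree(node, rooted=True))
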