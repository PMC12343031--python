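"""Shared generators and independent oracles for the test suite."""

import random

import pytest

from quartetree.treeio import PhyloTree, TreeNode, bipartitions


def random_binary_tree(labels, rng, with_supports=False, with_lengths=False):
    """Uniform-ish random unrooted binary tree (trifurcation-rooted)."""
    nodes = [TreeNode(label=l) for l in labels]
    rng.shuffle(nodes)
    while len(nodes) > 3:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        p = TreeNode()
        p.add_child(a)
        p.add_child(b)
        nodes.append(p)
    root = TreeNode()
    for x in nodes:
        root.add_child(x)
    t = PhyloTree(root)
    for n in t.postorder():
        if n.parent is not None:
            if with_lengths and rng.random() < 0.85:
                n.length = rng.uniform(0.01, 3.0)
            if with_supports and not n.is_leaf and rng.random() < 0.85:
                n.support = rng.uniform(0.05, 1.0)
    return t


def collapse_random_edges(tree, rng, p):
    """Introduce polytomies by collapsing internal edges with prob p."""
    for n in list(tree.postorder()):
        if not n.is_leaf and n.parent is not None and rng.random() < p:
            parent = n.parent
            i = parent.children.index(n)
            parent.children[i : i + 1] = n.children
            for c in n.children:
                c.parent = parent
    return tree


def all_unrooted_binary_trees(labels):
    """Every unrooted binary tree on the labels, by stepwise addition.

    (2n-5)!! trees: 3 labels -> 1, 6 -> 105, 7 -> 945.
    """
    root = TreeNode()
    for l in labels[:3]:
        root.add_child(TreeNode(label=l))
    trees = [PhyloTree(root)]
    for l in labels[3:]:
        nxt = []
        for t in trees:
            n_edges = sum(1 for n in t.postorder() if n.parent is not None)
            for i in range(n_edges):
                t2 = t.copy()
                node = [n for n in t2.postorder() if n.parent is not None][i]
                mid = TreeNode()
                parent = node.parent
                parent.children[parent.children.index(node)] = mid
                mid.parent = parent
                mid.add_child(node)
                mid.add_child(TreeNode(label=l))
                nxt.append(t2)
        trees = nxt
    return trees


def rf_distance(t1, t2):
    """Robinson-Foulds distance (symmetric difference of bipartitions)."""
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def same_topology(t1, t2):
    return set(t1.leaf_labels()) == set(t2.leaf_labels()) and rf_distance(t1, t2) == 0


def quartet_oracle(tree, quad):
    """Third, fully independent route to the induced pairing: scan the
    tree's bipartitions for one separating two quad members from the other
    two.  Returns a frozenset pairing or None (unresolved)."""
    quad = set(quad)
    for bp in bipartitions(tree):
        a = quad & bp.blockA
        b = quad & bp.blockB
        if len(a) == 2 and len(b) == 2:
            return frozenset((frozenset(a), frozenset(b)))
    return None


@pytest.fixture
def rng():
    return random.Random(20240917)
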