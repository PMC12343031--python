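"""Tree I/O and split primitives.

Trees are stored as mutable rooted node structures but are interpreted as
unrooted for all scoring purposes (a degree-2 root is suppressed on
:meth:`PhyloTree.unrooted`).  Polytomies are allowed everywhere.  Internal
nodes may carry a numeric support and/or a name; branches may carry a
length (``None`` means *missing*, never 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Sequence, Set

import dendropy

__all__ = [
    "TreeNode",
    "PhyloTree",
    "Bipartition",
    "Tripartition",
    "TreeParseError",
    "parse_newick",
    "parse_newick_file",
    "write_newick",
    "contract_low_support",
    "bipartitions",
    "read_taxon_map",
    "identity_taxon_map",
    "detect_support_scale",
    "normalize_supports",
]


class TreeParseError(ValueError):
    """Raised for malformed Newick or invalid tree structure."""


class TreeNode:
    """A node of a :class:`PhyloTree`.

    ``label`` is the taxon name on leaves and an optional name on internal
    nodes (non-numeric Newick internal labels are kept here).  ``support``
    is the numeric internal-branch support (on the edge to the parent);
    ``length`` the branch length to the parent, ``None`` when absent.
    """

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label=None, length=None, support=None):
        self.label: Optional[str] = label
        self.length: Optional[float] = length
        self.support: Optional[float] = support
        self.children: List["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> List["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "TreeNode":
        new = TreeNode(self.label, self.length, self.support)
        for c in self.children:
            new.add_child(c.copy())
        return new


class PhyloTree:
    """A phylogenetic tree with unique leaf labels; polytomies allowed."""

    def __init__(self, root: TreeNode, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        self._validate()

    def _validate(self) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeParseError(f"duplicate leaf labels: {dups}")
        if any(lbl is None for lbl in labels):
            raise TreeParseError("unlabeled leaf")

    # -- basic queries ---------------------------------------------------
    def leaves(self) -> List[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> List[str]:
        return [n.label for n in self.leaves()]

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def internal_nodes(self) -> List[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def __len__(self) -> int:
        return len(self.leaves())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.rooted)

    def is_binary_unrooted(self) -> bool:
        t = self.unrooted()
        for n in t.postorder():
            if n.is_leaf:
                continue
            deg = len(n.children) + (0 if n is t.root else 1)
            if deg != 3:
                return False
        return True

    # -- unrooted view ---------------------------------------------------
    def unrooted(self) -> "PhyloTree":
        """Copy with a degree-2 root suppressed.

        The two edges incident to a bifurcating root denote the same
        unrooted branch: their lengths are summed and the first
        non-missing support is kept.
        """
        t = self.copy()
        root = t.root
        while len(root.children) == 2 and len(t) > 2:
            a, b = root.children
            keep, merge = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:  # two-leaf tree: nothing to suppress
                break
            # graft `merge` under `keep`, fusing the two root edges
            length = None
            if keep.length is not None or merge.length is not None:
                length = (keep.length or 0.0) + (merge.length or 0.0)
            support = keep.support if keep.support is not None else merge.support
            merge.length = length
            merge.support = support
            merge.parent = keep
            keep.children.append(merge)
            keep.parent = None
            keep.length = None
            keep.support = None
            root = keep
        t.root = root
        t.rooted = False
        return t


# ---------------------------------------------------------------------------
# splits


def _canonical_pair(blockA: frozenset, blockB: frozenset):
    a, b = frozenset(blockA), frozenset(blockB)
    if min(a) <= min(b):
        return a, b
    return b, a


@dataclass(frozen=True)
class Bipartition:
    """A canonical two-block split of a taxon set.

    ``blockA`` is the block containing the globally smallest taxon label.
    """

    blockA: frozenset
    blockB: frozenset

    def __init__(self, blockA, blockB):
        a, b = _canonical_pair(blockA, blockB)
        if a & b:
            raise ValueError("bipartition blocks overlap")
        if not a or not b:
            raise ValueError("bipartition blocks must be nonempty")
        object.__setattr__(self, "blockA", a)
        object.__setattr__(self, "blockB", b)

    @property
    def taxa(self) -> frozenset:
        return self.blockA | self.blockB

    def is_trivial(self) -> bool:
        return len(self.blockA) == 1 or len(self.blockB) == 1

    def __repr__(self):
        fmt = lambda s: ",".join(sorted(s))
        return f"Bipartition({fmt(self.blockA)} | {fmt(self.blockB)})"


@dataclass(frozen=True)
class Tripartition:
    """An unordered three-block split around an internal node."""

    blocks: frozenset  # frozenset of 3 frozensets

    def __init__(self, a, b, c):
        a, b, c = frozenset(a), frozenset(b), frozenset(c)
        if (a & b) or (a & c) or (b & c):
            raise ValueError("tripartition blocks overlap")
        if not (a and b and c):
            raise ValueError("tripartition blocks must be nonempty")
        object.__setattr__(self, "blocks", frozenset((a, b, c)))

    def as_tuple(self):
        return tuple(sorted(self.blocks, key=lambda s: sorted(s)))

    def __repr__(self):
        fmt = lambda s: ",".join(sorted(s))
        return "Tripartition(%s)" % " | ".join(fmt(s) for s in self.as_tuple())


# ---------------------------------------------------------------------------
# Newick parsing / writing


def _try_float(text: Optional[str]) -> Optional[float]:
    if text is None:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick string into a :class:`PhyloTree`.

    Numeric internal-node labels are interpreted as branch supports;
    non-numeric ones are preserved as names.  Quoted labels and missing
    branch lengths are accepted; ``[...]`` comments are ignored.
    """
    text = text.strip()
    if not text or text == ";":
        raise TreeParseError("empty tree")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeParseError(f"newick parse error: {exc}") from None

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = TreeNode(label=label, length=dnode.edge.length)
        else:
            raw = dnode.label
            support = _try_float(raw)
            node = TreeNode(
                label=None if support is not None else raw,
                length=dnode.edge.length,
                support=support,
            )
            for child in dnode.child_nodes():
                node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    if root.is_leaf and root.label is None:
        raise TreeParseError("empty tree")
    return PhyloTree(root, rooted=len(root.children) == 2)


def parse_newick_file(path) -> List[PhyloTree]:
    """Read one tree per non-empty line."""
    trees = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(parse_newick(line))
            except TreeParseError as exc:
                raise TreeParseError(f"{path}:{lineno}: {exc}") from None
    if not trees:
        raise TreeParseError(f"{path}: no trees found")
    return trees


_NEWICK_SPECIALS = set("();:,[]' \t\n=")


def _format_label(label: str) -> str:
    if any(ch in _NEWICK_SPECIALS for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_float(x: float) -> str:
    s = repr(float(x))
    return s


def write_newick(tree: PhyloTree, support_precision: int = 6) -> str:
    """Serialize to Newick; supports become internal labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            s = _format_label(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None:
                s += _format_float(round(node.support, support_precision))
            elif node.label is not None:
                s += _format_label(node.label)
        if node.length is not None:
            s += ":" + _format_float(node.length)
        return s

    return fmt(tree.root) + ";"


def write_newick_file(trees: Sequence[PhyloTree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# manipulation


def contract_low_support(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Collapse internal branches whose support is < ``threshold``.

    Branches with no support value are kept; leaf branches are never
    contracted.  The threshold must be on the same scale as the supports.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    t = tree.copy()
    for node in list(t.postorder()):
        if node.is_leaf or node.parent is None:
            continue
        if node.support is not None and node.support < threshold:
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx : idx + 1] = node.children
            for c in node.children:
                c.parent = parent
    return t


def bipartitions(tree: PhyloTree) -> Set[Bipartition]:
    """Canonical non-trivial bipartitions of the unrooted view, one per
    internal branch."""
    t = tree.unrooted()
    all_taxa = frozenset(t.leaf_labels())
    out: Set[Bipartition] = set()
    below: Dict[TreeNode, frozenset] = {}
    for node in t.postorder():
        if node.is_leaf:
            below[node] = frozenset([node.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
    for node in t.postorder():
        if node.is_leaf or node is t.root:
            continue
        side = below[node]
        other = all_taxa - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(Bipartition(side, other))
    return out


# ---------------------------------------------------------------------------
# taxon maps


def read_taxon_map(path) -> Dict[str, str]:
    """Read an ``individual<ws>species`` two-column map file."""
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            ind, sp = parts
            if ind in mapping and mapping[ind] != sp:
                raise ValueError(
                    f"{path}:{lineno}: individual {ind!r} mapped to both "
                    f"{mapping[ind]!r} and {sp!r}"
                )
            mapping[ind] = sp
    return mapping


def identity_taxon_map(trees: Sequence[PhyloTree]) -> Dict[str, str]:
    """Each leaf label is its own species."""
    labels = set()
    for t in trees:
        labels.update(t.leaf_labels())
    return {x: x for x in labels}


# ---------------------------------------------------------------------------
# support scales


def detect_support_scale(trees: Sequence[PhyloTree]) -> float:
    """Return the divisor that brings supports onto [0, 1].

    If any support exceeds 1 the file is taken to be on a percent scale
    (divisor 100), else probabilities (divisor 1).
    """
    for t in trees:
        for node in t.postorder():
            if node.support is not None and node.support > 1.0 + 1e-12:
                return 100.0
    return 1.0


def normalize_supports(trees: Sequence[PhyloTree], scale: Optional[float] = None):
    """Divide all supports by ``scale`` (auto-detected when None) in place."""
    if scale is None:
        scale = detect_support_scale(trees)
    if scale != 1.0:
        for t in trees:
            for node in t.postorder():
                if node.support is not None:
                    node.support = node.support / scale
    for t in trees:
        for node in t.postorder():
            if node.support is not None and not (-1e-12 <= node.support <= 1 + 1e-12):
                raise ValueError(
                    f"support {node.support} outside [0,1] after scaling"
                )
    return trees
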