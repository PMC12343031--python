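"""Branch annotation: quartet frequencies, coalescent lengths, local PP.

Each internal branch of a binary species tree defines a quadripartition
(A,B | C,D) of the species set.  Quartet-frequency masses f1,f2,f3 are
accumulated over all gene trees and all one-per-block species quadruples
(f1 = the species-tree pairing); the coalescent-unit branch length is the
standard inversion of the expected agreeing-quartet frequency, and the
local posterior probability comes from numerical Bayesian integration over
the branch length.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import logsumexp

from .treeio import PhyloTree, TreeNode
from .quartet_core import GeneTreeSet, WeightScheme, UNIT, _PathIndex, _quad_masses

__all__ = [
    "BranchAnnotation",
    "branch_frequencies",
    "coalescent_length",
    "local_pp",
    "annotate_tree",
    "D_MAX",
]

D_MAX = 10.0
_EPS = 1e-6


@dataclass
class BranchAnnotation:
    f1: float  # mass of the species-tree pairing (normalized)
    f2: float
    f3: float
    n_eff: float  # total contributing mass
    d_coal: float
    local_pp: float


def _quadripartition(node: TreeNode, root: TreeNode) -> Optional[Tuple[List[str], ...]]:
    """Blocks (C, D, A, B) around the edge above ``node``: C,D below it,
    A,B on the far side.  None for branches that are not internal."""
    if node.is_leaf or node.parent is None:
        return None
    if len(node.children) != 2:
        raise ValueError("annotation requires a binary species tree")
    C, D = (sorted(l.label for l in c.leaves()) for c in node.children)
    parent = node.parent
    others = [c for c in parent.children if c is not node]
    if parent is root:
        if len(others) != 2:
            raise ValueError("annotation requires a binary species tree")
        A, B = (sorted(l.label for l in c.leaves()) for c in others)
    else:
        if len(others) != 1:
            raise ValueError("annotation requires a binary species tree")
        A = sorted(l.label for l in others[0].leaves())
        below = {l.label for l in parent.leaves()}
        B = sorted(set(_all_leaf_labels(root)) - below)
    if not (A and B):
        return None
    return C, D, A, B


def _all_leaf_labels(root: TreeNode) -> List[str]:
    return [n.label for n in root.leaves()]


def _masses_around(
    quadri: Tuple[List[str], ...], genes: GeneTreeSet, scheme: WeightScheme
) -> Tuple[float, float, float]:
    """(m1, m2, m3): m1 = mass of the CD|AB (species-tree) pairing."""
    C, D, A, B = quadri
    by_sp = genes.individuals_by_species()
    m1 = m2 = m3 = 0.0
    for tree in genes.trees:
        idx = _PathIndex(tree)
        for quad in itertools.product(A, B, C, D):
            masses = _quad_masses(idx, quad, by_sp, scheme)
            if not masses:
                continue
            a, b, c, d = quad
            m1 += masses.get(frozenset((frozenset((a, b)), frozenset((c, d)))), 0.0)
            m2 += masses.get(frozenset((frozenset((a, c)), frozenset((b, d)))), 0.0)
            m3 += masses.get(frozenset((frozenset((a, d)), frozenset((b, c)))), 0.0)
    return m1, m2, m3


def branch_frequencies(
    species_tree: PhyloTree,
    node: TreeNode,
    genes: GeneTreeSet,
    scheme: WeightScheme = UNIT,
) -> Tuple[float, float, float, float]:
    """Normalized pairing frequencies (f1, f2, f3) and total mass n_eff for
    the internal branch above ``node`` (a node of the *unrooted* tree)."""
    st = species_tree if species_tree.root.parent is None else species_tree
    quadri = _quadripartition(node, st.root)
    if quadri is None:
        raise ValueError("not an internal branch")
    m1, m2, m3 = _masses_around(quadri, genes, scheme)
    n_eff = m1 + m2 + m3
    if n_eff == 0:
        return math.nan, math.nan, math.nan, 0.0
    return m1 / n_eff, m2 / n_eff, m3 / n_eff, n_eff


def coalescent_length(f1: float, n_eff: float = math.inf) -> float:
    """Coalescent-unit branch length from the agreeing-quartet frequency.

    Inverts E[f1] = 1 - (2/3)exp(-d): d = -ln(1.5 (1 - f1)), clamped to 0
    below f1 = 1/3 and to ``D_MAX`` near f1 = 1.
    """
    if math.isnan(f1):
        return 0.0
    if not (0.0 <= f1 <= 1.0 + 1e-12):
        raise ValueError(f"f1 must be in [0,1], got {f1}")
    if f1 <= 1.0 / 3.0:
        return 0.0
    if f1 >= 1.0 - _EPS:
        return D_MAX
    return min(-math.log(1.5 * (1.0 - f1)), D_MAX)


_GRID = np.logspace(math.log10(1e-6), math.log10(20.0), 201)


def local_pp(m1: float, m2: float, m3: float) -> float:
    """Posterior probability that pairing 1 is the species-tree pairing.

    Uniform 1/3 prior over the three pairings, Exp(1) prior on the branch
    length d, per-observation probabilities (1 - (2/3)e^-d) for the true
    pairing and (1/3)e^-d for each alternative; integrated numerically on a
    fixed log-spaced grid (log-space arithmetic for large masses).
    """
    if min(m1, m2, m3) < 0:
        raise ValueError("masses must be >= 0")
    total = m1 + m2 + m3
    if total == 0:
        return math.nan
    d = _GRID
    log_p_match = np.log1p(-(2.0 / 3.0) * np.exp(-d))
    log_p_alt = math.log(1.0 / 3.0) - d
    # trapezoid weights on the grid, plus the Exp(1) prior density
    w = np.empty_like(d)
    w[1:-1] = 0.5 * (d[2:] - d[:-2])
    w[0] = 0.5 * (d[1] - d[0])
    w[-1] = 0.5 * (d[-1] - d[-2])
    log_prior = -d + np.log(w)
    logL = []
    for mt in (m1, m2, m3):
        rest = total - mt
        logL.append(logsumexp(mt * log_p_match + rest * log_p_alt + log_prior))
    logL = np.array(logL)
    post = np.exp(logL - logsumexp(logL))
    return float(post[0])


def annotate_tree(
    species_tree: PhyloTree,
    genes: GeneTreeSet,
    scheme: WeightScheme = UNIT,
    label_mode: str = "full",
) -> PhyloTree:
    """Annotate every internal branch of a binary species tree.

    ``label_mode``: "full" writes 'q1=..;q2=..;q3=..;pp=..;n=..' labels
    (quoted Newick), "pp" and "support" write the scalar pp / f1.  The
    coalescent-unit length is stored as the branch length in all modes.
    """
    if label_mode not in ("full", "pp", "support"):
        raise ValueError(f"unknown label mode {label_mode!r}")
    st = species_tree.unrooted()
    for node in list(st.postorder()):
        if node.is_leaf or node.parent is None:
            continue
        quadri = _quadripartition(node, st.root)
        if quadri is None:
            continue
        m1, m2, m3 = _masses_around(quadri, genes, scheme)
        n_eff = m1 + m2 + m3
        if n_eff > 0:
            f1, f2, f3 = m1 / n_eff, m2 / n_eff, m3 / n_eff
            d = coalescent_length(f1, n_eff)
            pp = local_pp(m1, m2, m3)
        else:
            f1 = f2 = f3 = math.nan
            d = 0.0
            pp = math.nan
        node.length = d
        if label_mode == "full":
            node.label = (
                f"q1={f1:.6g};q2={f2:.6g};q3={f3:.6g};pp={pp:.6g};n={n_eff:.6g}"
            )
            node.support = None
        elif label_mode == "pp":
            node.support = None if math.isnan(pp) else round(pp, 6)
            node.label = None
        else:
            node.support = None if math.isnan(f1) else round(f1, 6)
            node.label = None
    return st
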