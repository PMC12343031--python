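"""Quartet support scores for species trees against gene tree sets.

Two routes compute the same quantity:

* :func:`brute_force_score` — the oracle: enumerate every species quadruple
  in every gene tree and compare induced pairings directly.
* :func:`fast_score` — the production scorer: no quartet is ever listed.
  Every gene-tree-resolved quartet that agrees with the species tree is
  anchored at exactly the two species-tree internal nodes where its pairs
  coalesce, so the score equals the sum of per-node tripartition gains
  divided by two.  Each gain is computed per gene tree with a two-pass
  dynamic program that aggregates block-restricted leaf masses and
  support/length-weighted pair masses at every gene-tree node.

Agreement of the two routes (exact in unit mode, 1e-9 relative otherwise)
is the central correctness contract and is enforced by the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .treeio import (
    PhyloTree,
    TreeNode,
    identity_taxon_map,
    normalize_supports,
)

__all__ = [
    "WeightScheme",
    "QuartetTopology",
    "Score",
    "GeneTreeSet",
    "induced_quartet",
    "quartet_weight",
    "multi_individual_quartet",
    "brute_force_score",
    "fast_score",
    "tripartition_gain",
]


# ---------------------------------------------------------------------------
# weight schemes


@dataclass(frozen=True)
class WeightScheme:
    """Rule mapping a resolved gene-tree quartet to a nonnegative weight.

    ``unit``    — every resolved quartet weighs 1.
    ``support`` — product of the supports of the internal branches on the
                  path joining the quartet's two pairs in the gene tree;
                  missing supports are replaced by ``default_missing_support``.
    ``hybrid``  — the support weight times ``exp(-L)`` where ``L`` is the
                  total length of the four terminal paths of the induced
                  quartet subtree (edges lacking lengths count 0).
    """

    mode: str = "unit"
    default_missing_support: float = 1.0

    def __post_init__(self):
        if self.mode not in ("unit", "support", "hybrid"):
            raise ValueError(f"unknown weight mode {self.mode!r}")
        if not (0.0 <= self.default_missing_support <= 1.0):
            raise ValueError("default_missing_support must be in [0,1]")

    @property
    def key(self):
        return (self.mode, self.default_missing_support)

    @property
    def uses_support(self) -> bool:
        return self.mode in ("support", "hybrid")

    @property
    def uses_length(self) -> bool:
        return self.mode == "hybrid"


UNIT = WeightScheme("unit")


# ---------------------------------------------------------------------------
# quartet topologies


@dataclass(frozen=True)
class QuartetTopology:
    """Four taxa plus one of the three pairings, or unresolved."""

    taxa: frozenset
    pairing: Optional[frozenset]  # frozenset of two 2-element frozensets

    @property
    def resolved(self) -> bool:
        return self.pairing is not None

    @staticmethod
    def make(pair1: Iterable, pair2: Iterable) -> "QuartetTopology":
        p1, p2 = frozenset(pair1), frozenset(pair2)
        return QuartetTopology(p1 | p2, frozenset((p1, p2)))

    @staticmethod
    def unresolved(taxa: Iterable) -> "QuartetTopology":
        return QuartetTopology(frozenset(taxa), None)


@dataclass
class Score:
    """Quartet support score with its normalization denominator."""

    value: float
    denominator: float

    @property
    def normalized(self) -> float:
        if self.denominator == 0:
            return math.nan
        return self.value / self.denominator


# ---------------------------------------------------------------------------
# path index: the oracle's view of a tree (independent of the fast DP)


class _PathIndex:
    """Root-paths per leaf of a tree, for quartet path queries."""

    def __init__(self, tree: PhyloTree):
        self.nodes: List[TreeNode] = list(tree.postorder())
        self.ids = {id(n): i for i, n in enumerate(self.nodes)}
        self.paths: Dict[str, List[int]] = {}
        parent_of = {}
        for n in self.nodes:
            for c in n.children:
                parent_of[id(c)] = n
        for leaf in tree.leaves():
            path = []
            n = leaf
            while n is not None:
                path.append(self.ids[id(n)])
                n = parent_of.get(id(n))
            path.reverse()  # root -> leaf
            self.paths[leaf.label] = path

    def has(self, label: str) -> bool:
        return label in self.paths

    def path_between(self, x: str, y: str) -> List[int]:
        """Ordered node ids x .. lca .. y."""
        pa, pb = self.paths[x], self.paths[y]
        cp = 0
        for na, nb in zip(pa, pb):
            if na != nb:
                break
            cp += 1
        left = pa[cp - 1 :]
        return left[::-1] + pb[cp:]

    def _edge_support(self, i: int, j: int) -> Optional[float]:
        ni, nj = self.nodes[i], self.nodes[j]
        child = nj if nj.parent is ni else ni
        return child.support

    def _edge_length(self, i: int, j: int) -> float:
        ni, nj = self.nodes[i], self.nodes[j]
        child = nj if nj.parent is ni else ni
        return child.length if child.length is not None else 0.0

    def median(self, x: str, y: str, z: str) -> int:
        common = (
            set(self.path_between(x, y))
            & set(self.path_between(x, z))
            & set(self.path_between(y, z))
        )
        assert len(common) == 1
        return next(iter(common))

    def topology(self, quad: Sequence[str]) -> QuartetTopology:
        a, b, c, d = quad
        winners = []
        for p1, p2 in (((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))):
            s1 = set(self.path_between(*p1))
            s2 = set(self.path_between(*p2))
            if not (s1 & s2):
                winners.append((p1, p2))
        if not winners:
            return QuartetTopology.unresolved(quad)
        assert len(winners) == 1
        return QuartetTopology.make(*winners[0])

    def weight(self, topo: QuartetTopology, scheme: WeightScheme) -> float:
        """Weight of a resolved quartet under ``scheme`` (oracle route)."""
        if not topo.resolved:
            return 0.0
        if scheme.mode == "unit":
            return 1.0
        pair1, pair2 = tuple(topo.pairing)
        (x, y), (z1, z2) = tuple(pair1), tuple(pair2)
        anchor_a = self.median(x, y, z1)
        anchor_b = self.median(z1, z2, x)
        w = 1.0
        # support product along the internal path joining the two anchors
        path = self.path_between(x, z1)
        ia, ib = path.index(anchor_a), path.index(anchor_b)
        if ia > ib:
            ia, ib = ib, ia
        for i in range(ia, ib):
            sup = self._edge_support(path[i], path[i + 1])
            w *= sup if sup is not None else scheme.default_missing_support
        if scheme.uses_length:
            total = 0.0
            for leaf, anchor in ((x, anchor_a), (y, anchor_a), (z1, anchor_b), (z2, anchor_b)):
                # walk leaf -> anchor; any path toward another quartet member
                # passes through the leaf's own anchor
                q = self.path_between(leaf, _any_other(leaf, (x, y, z1, z2)))
                dist = 0.0
                prev = None
                for node_id in q:
                    if prev is not None:
                        dist += self._edge_length(prev, node_id)
                    if node_id == anchor:
                        break
                    prev = node_id
                total += dist
            w *= math.exp(-total)
        return w


def _any_other(leaf, quad):
    for t in quad:
        if t != leaf:
            return t
    raise AssertionError


def induced_quartet(tree: PhyloTree, quad: Iterable[str]) -> Optional[QuartetTopology]:
    """Pairing induced on four taxa, ``None`` when any taxon is absent.

    An unresolved topology (four leaves meeting at a polytomy) is returned
    as a :class:`QuartetTopology` with ``pairing is None`` — distinct from
    the *missing* signal ``None``.
    """
    quad = tuple(quad)
    if len(set(quad)) != 4:
        raise ValueError("quartet requires 4 distinct taxa")
    idx = _PathIndex(tree.unrooted())
    if not all(idx.has(t) for t in quad):
        return None
    return idx.topology(quad)


def quartet_weight(tree: PhyloTree, quad: Iterable[str], scheme: WeightScheme) -> float:
    """Weight of the induced quartet; 0 for unresolved or missing."""
    quad = tuple(quad)
    idx = _PathIndex(tree.unrooted())
    if not all(idx.has(t) for t in quad):
        return 0.0
    topo = idx.topology(quad)
    return idx.weight(topo, scheme)


# ---------------------------------------------------------------------------
# preprocessed gene trees (fast route)


class _PrepTree:
    """Array view of one unrooted gene tree for the anchored DP."""

    def __init__(self, tree: PhyloTree, sp_index: Dict[str, int], taxon_map: Dict[str, str]):
        self.nodes = list(tree.postorder())  # children before parents
        ids = {id(n): i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.children: List[List[int]] = [[] for _ in range(n)]
        self.parent = [-1] * n
        self.leaf_sp = [-1] * n
        self.edge_len: List[Optional[float]] = [None] * n
        self.edge_sup: List[Optional[float]] = [None] * n
        self.root = ids[id(tree.root)]
        counts: Dict[int, int] = {}
        for i, node in enumerate(self.nodes):
            for c in node.children:
                ci = ids[id(c)]
                self.children[i].append(ci)
                self.parent[ci] = i
            if node.is_leaf:
                sp = sp_index[taxon_map[node.label]]
                self.leaf_sp[i] = sp
                counts[sp] = counts.get(sp, 0) + 1
            self.edge_len[i] = node.length
            self.edge_sup[i] = node.support
        self.sp_counts = counts
        self.dup_species = {s for s, c in counts.items() if c > 1}
        self.multi = bool(self.dup_species)
        self.leaf_w = [0.0] * n
        for i in range(n):
            s = self.leaf_sp[i]
            if s >= 0:
                self.leaf_w[i] = 1.0 / counts[s]
        self.present_mask = 0
        for s in counts:
            self.present_mask |= 1 << s
        self.internal = [i for i in range(n) if self.children[i]]
        self._factor_cache: Dict[tuple, tuple] = {}

    def factors(self, scheme: WeightScheme):
        """Per-edge (length-factor, support-factor) arrays for a scheme."""
        key = scheme.key
        cached = self._factor_cache.get(key)
        if cached is not None:
            return cached
        n = len(self.nodes)
        f = [1.0] * n
        sig = [1.0] * n
        for i in range(n):
            if scheme.uses_length and self.edge_len[i] is not None:
                f[i] = math.exp(-self.edge_len[i])
            if scheme.uses_support and self.leaf_sp[i] < 0 and self.parent[i] >= 0:
                sup = self.edge_sup[i]
                sig[i] = sup if sup is not None else scheme.default_missing_support
        self._factor_cache[key] = (f, sig)
        return f, sig


def _tree_gain(prep: _PrepTree, blk: List[int], f: List[float], sig: List[float]) -> float:
    """Anchored agreeing-quartet mass of one gene tree for one tripartition.

    ``blk`` maps species index -> block 0/1/2 (or -1 outside the
    tripartition).  Counts, at every gene-tree node, configurations with
    single leaves from two blocks in two distinct components and a
    same-block pair in a third; this tallies every agreeing quartet once,
    at the anchor on its singles side.
    """
    n = len(prep.nodes)
    lam = [None] * n
    P = [None] * n
    track = prep.dup_species and any(blk[s] >= 0 for s in prep.dup_species)
    lamsp = [None] * n if track else None

    for u in range(n):  # postorder by construction
        kids = prep.children[u]
        if not kids:
            b = blk[prep.leaf_sp[u]] if prep.leaf_sp[u] >= 0 else -1
            v = [0.0, 0.0, 0.0]
            if b >= 0:
                v[b] = prep.leaf_w[u]
            lam[u] = v
            P[u] = [0.0, 0.0, 0.0]
            if track:
                s = prep.leaf_sp[u]
                lamsp[u] = {s: prep.leaf_w[u]} if (s in prep.dup_species and b >= 0) else {}
            continue
        lv = [0.0, 0.0, 0.0]
        pv = [0.0, 0.0, 0.0]
        sq = [0.0, 0.0, 0.0]
        for c in kids:
            fc, lc = f[c], lam[c]
            for b in range(3):
                x = fc * lc[b]
                lv[b] += x
                sq[b] += x * x
            for b in range(3):
                pv[b] += sig[c] * P[c][b]
        for b in range(3):
            pv[b] += 0.5 * (lv[b] * lv[b] - sq[b])
        if track:
            d: Dict[int, float] = {}
            dsq: Dict[int, float] = {}
            for c in kids:
                lsc = lamsp[c]
                if lsc:
                    fc = f[c]
                    for s, w in lsc.items():
                        x = fc * w
                        d[s] = d.get(s, 0.0) + x
                        dsq[s] = dsq.get(s, 0.0) + x * x
            for s, tot in d.items():
                pv[blk[s]] -= 0.5 * (tot * tot - dsq[s])
            lamsp[u] = d
        lam[u] = lv
        P[u] = pv

    # up pass: parents before children
    lam_up = [None] * n
    P_up = [None] * n
    lamsp_up = [None] * n if track else None
    lam_up[prep.root] = [0.0, 0.0, 0.0]
    P_up[prep.root] = [0.0, 0.0, 0.0]
    if track:
        lamsp_up[prep.root] = {}
    total = 0.0

    for u in reversed(range(n)):
        kids = prep.children[u]
        if not kids:
            continue
        lu, pu, lup, pup = lam[u], P[u], lam_up[u], P_up[u]
        # sums over child components (x_c = f_c * lam_c), by block
        S = [lu[b] for b in range(3)]  # equals sum of x_c by construction
        SP = [0.0, 0.0, 0.0]
        sq = [0.0, 0.0, 0.0]
        for c in kids:
            fc, lc = f[c], lam[c]
            for b in range(3):
                x = fc * lc[b]
                sq[b] += x * x
                SP[b] += sig[c] * P[c][b]
        if track:
            spS: Dict[int, float] = {}
            spsq: Dict[int, float] = {}
            for c in kids:
                lsc = lamsp[c]
                if lsc:
                    fc = f[c]
                    for s, w in lsc.items():
                        x = fc * w
                        spS[s] = spS.get(s, 0.0) + x
                        spsq[s] = spsq.get(s, 0.0) + x * x

        for v in kids:
            if not prep.children[v]:
                continue
            fv, sv = f[v], sig[v]
            lu_v = [0.0, 0.0, 0.0]
            pu_v = [0.0, 0.0, 0.0]
            for b in range(3):
                xv = fv * lam[v][b]
                rest = S[b] - xv
                lu_v[b] = fv * (rest + lup[b])
                pairs = 0.5 * (rest * rest - (sq[b] - xv * xv)) + rest * lup[b]
                pu_v[b] = sv * (pairs + (SP[b] - sv * P[v][b]) + pup[b])
            if track:
                dv: Dict[int, float] = {}
                lsv = lamsp[v]
                for s in set(spS) | set(lamsp_up[u]):
                    xv = fv * lsv.get(s, 0.0) if lsv else 0.0
                    rest = spS.get(s, 0.0) - xv
                    upv = lamsp_up[u].get(s, 0.0)
                    val = fv * (rest + upv)
                    if val:
                        dv[s] = val
                    excl = 0.5 * (rest * rest - (spsq.get(s, 0.0) - xv * xv)) + rest * upv
                    pu_v[blk[s]] -= sv * excl
                lamsp_up[v] = dv
            lam_up[v] = lu_v
            P_up[v] = pu_v

        # anchor accumulation at u: components = child subtrees + "up"
        comps_lam = [[f[c] * lam[c][b] for b in range(3)] for c in kids]
        comps_W = [[sig[c] * P[c][b] for b in range(3)] for c in kids]
        if u != prep.root:
            comps_lam.append(lup)
            comps_W.append(pup)
        Sb = [sum(cl[b] for cl in comps_lam) for b in range(3)]
        Tqr = {}
        for q, r in ((1, 2), (0, 2), (0, 1)):
            Tqr[(q, r)] = sum(cl[q] * cl[r] for cl in comps_lam)
        for p in range(3):
            q, r = (1, 2) if p == 0 else ((0, 2) if p == 1 else (0, 1))
            T = Tqr[(q, r)]
            acc = 0.0
            for cl, cw in zip(comps_lam, comps_W):
                wp = cw[p]
                if wp:
                    acc += wp * (
                        (Sb[q] - cl[q]) * (Sb[r] - cl[r]) - (T - cl[q] * cl[r])
                    )
            total += acc
    return total


def _tree_resolved_mass(prep: _PrepTree, scope: List[bool], f: List[float], sig: List[float]) -> float:
    """Total weighted resolved-quartet mass of one single-individual tree,
    restricted to species inside ``scope`` — the normalization denominator
    contribution.  Counts each resolved quartet at both anchors with both
    orders of the singles, hence the /4.
    """
    n = len(prep.nodes)
    lam = [0.0] * n
    P = [0.0] * n
    for u in range(n):
        kids = prep.children[u]
        if not kids:
            s = prep.leaf_sp[u]
            lam[u] = prep.leaf_w[u] if (s >= 0 and scope[s]) else 0.0
            continue
        S = sqs = pv = 0.0
        for c in kids:
            x = f[c] * lam[c]
            S += x
            sqs += x * x
            pv += sig[c] * P[c]
        lam[u] = S
        P[u] = pv + 0.5 * (S * S - sqs)

    lam_up = [0.0] * n
    P_up = [0.0] * n
    total = 0.0
    for u in reversed(range(n)):
        kids = prep.children[u]
        if not kids:
            continue
        S = lam[u]
        sqs = SP = 0.0
        for c in kids:
            x = f[c] * lam[c]
            sqs += x * x
            SP += sig[c] * P[c]
        lup, pup = lam_up[u], P_up[u]
        for v in kids:
            if not prep.children[v]:
                continue
            xv = f[v] * lam[v]
            rest = S - xv
            lam_up[v] = f[v] * (rest + lup)
            pairs = 0.5 * (rest * rest - (sqs - xv * xv)) + rest * lup
            P_up[v] = sig[v] * (pairs + (SP - sig[v] * P[v]) + pup)

        comps = [(f[c] * lam[c], sig[c] * P[c]) for c in kids]
        if u != prep.root:
            comps.append((lup, pup))
        Sb = sum(x for x, _ in comps)
        sq2 = sum(x * x for x, _ in comps)
        for x, w in comps:
            if w:
                rest = Sb - x
                total += w * (rest * rest - (sq2 - x * x))
    return total / 4.0


# ---------------------------------------------------------------------------
# gene tree sets


class GeneTreeSet:
    """Parsed gene trees plus the global species index and fast-count caches.

    Every leaf label must map to a species (identity when no map is given);
    a species may be absent from any given tree.  Supports are normalized
    onto [0,1] (``support_scale``: "auto", "prob", "percent", or a numeric
    divisor).
    """

    def __init__(
        self,
        trees: Sequence[PhyloTree],
        taxon_map: Optional[Dict[str, str]] = None,
        support_scale="auto",
    ):
        if not trees:
            raise ValueError("need at least one gene tree")
        self.trees: List[PhyloTree] = [t.unrooted() for t in trees]
        if support_scale == "auto":
            normalize_supports(self.trees, None)
        elif support_scale == "prob":
            normalize_supports(self.trees, 1.0)
        elif support_scale == "percent":
            normalize_supports(self.trees, 100.0)
        else:
            normalize_supports(self.trees, float(support_scale))

        if taxon_map is None:
            self.taxon_map = identity_taxon_map(self.trees)
        else:
            self.taxon_map = dict(taxon_map)
            missing = sorted(
                {lbl for t in self.trees for lbl in t.leaf_labels() if lbl not in self.taxon_map}
            )
            if missing:
                raise ValueError(f"leaf labels absent from taxon map: {missing}")

        seen = {self.taxon_map[lbl] for t in self.trees for lbl in t.leaf_labels()}
        self.species: List[str] = sorted(seen)
        if len(self.species) < 4:
            raise ValueError(f"need >= 4 species, got {len(self.species)}")
        self.sp_index = {s: i for i, s in enumerate(self.species)}
        self.full_mask = (1 << len(self.species)) - 1
        self.preps = [_PrepTree(t, self.sp_index, self.taxon_map) for t in self.trees]
        self.presence_masks = [p.present_mask for p in self.preps]
        self._gain_cache: Dict[tuple, float] = {}
        self._denom_cache: Dict[tuple, float] = {}
        self._individuals: Optional[Dict[str, List[str]]] = None

    # -- species/mask helpers -------------------------------------------
    def __len__(self):
        return len(self.trees)

    def mask(self, labels: Iterable[str]) -> int:
        m = 0
        for lbl in labels:
            m |= 1 << self.sp_index[lbl]
        return m

    def labels_of_mask(self, mask: int) -> List[str]:
        return [s for i, s in enumerate(self.species) if mask >> i & 1]

    def individuals_by_species(self) -> Dict[str, List[str]]:
        if self._individuals is None:
            by_sp: Dict[str, List[str]] = {}
            for ind, sp in sorted(self.taxon_map.items()):
                by_sp.setdefault(sp, []).append(ind)
            self._individuals = by_sp
        return self._individuals

    @property
    def has_multi_individuals(self) -> bool:
        return any(p.multi for p in self.preps)

    # -- cached aggregates ----------------------------------------------
    def gain(self, trip_masks: Tuple[int, int, int], scheme: WeightScheme) -> float:
        m1, m2, m3 = trip_masks
        if (m1 & m2) or (m1 & m3) or (m2 & m3):
            raise ValueError("tripartition blocks overlap")
        if not (m1 and m2 and m3):
            raise ValueError("tripartition blocks must be nonempty")
        key = (tuple(sorted((m1, m2, m3))), scheme.key)
        cached = self._gain_cache.get(key)
        if cached is not None:
            return cached
        blk = [-1] * len(self.species)
        for b, m in enumerate(key[0]):
            mm = m
            while mm:
                low = mm & -mm
                blk[low.bit_length() - 1] = b
                mm ^= low
        total = 0.0
        for prep in self.preps:
            pm = prep.present_mask
            # a quartet needs singles in two blocks and a pair in a third
            if sum(1 for m in key[0] if pm & m) < 3:
                continue
            f, sig = prep.factors(scheme)
            total += _tree_gain(prep, blk, f, sig)
        self._gain_cache[key] = total
        return total

    def denominator(self, scope_mask: int, scheme: WeightScheme) -> float:
        key = (scope_mask, scheme.key)
        cached = self._denom_cache.get(key)
        if cached is not None:
            return cached
        scope = [bool(scope_mask >> i & 1) for i in range(len(self.species))]
        total = 0.0
        for tree, prep in zip(self.trees, self.preps):
            if bin(prep.present_mask & scope_mask).count("1") < 4:
                continue
            if not prep.multi:
                f, sig = prep.factors(scheme)
                total += _tree_resolved_mass(prep, scope, f, sig)
            else:
                # all-four-distinct-species constraint does not factor over
                # anchors with duplicate species: enumerate quadruples
                labels = [
                    s
                    for i, s in enumerate(self.species)
                    if scope[i] and (prep.present_mask >> i & 1)
                ]
                idx = _PathIndex(tree)
                by_sp = self.individuals_by_species()
                for quad in itertools.combinations(labels, 4):
                    masses = _quad_masses(idx, quad, by_sp, scheme)
                    total += sum(masses.values())
        self._denom_cache[key] = total
        return total


# ---------------------------------------------------------------------------
# multi-individual masses


def _quad_masses(
    idx: _PathIndex,
    quad: Sequence[str],
    by_species: Dict[str, List[str]],
    scheme: WeightScheme,
) -> Dict[frozenset, float]:
    """Pairing -> mass for one gene tree, averaged over one-individual-per-
    species choices.  Keys are species-level pairings."""
    choices = []
    for sp in quad:
        inds = [i for i in by_species.get(sp, [sp]) if idx.has(i)]
        if not inds:
            return {}
        choices.append(inds)
    n_choices = 1
    for c in choices:
        n_choices *= len(c)
    masses: Dict[frozenset, float] = {}
    for pick in itertools.product(*choices):
        topo = idx.topology(pick)
        if not topo.resolved:
            continue
        w = idx.weight(topo, scheme) / n_choices
        ind2sp = dict(zip(pick, quad))
        pairing = frozenset(
            frozenset(ind2sp[i] for i in pair) for pair in topo.pairing
        )
        masses[pairing] = masses.get(pairing, 0.0) + w
    return masses


def multi_individual_quartet(
    genes: GeneTreeSet, quad: Sequence[str], scheme: WeightScheme = UNIT
) -> List[Dict[frozenset, float]]:
    """Per gene tree, the weight mass on each pairing of four species,
    averaged over all choices of one individual per species."""
    quad = tuple(quad)
    if len(set(quad)) != 4:
        raise ValueError("need 4 distinct species")
    by_sp = genes.individuals_by_species()
    out = []
    for tree in genes.trees:
        idx = _PathIndex(tree)
        out.append(_quad_masses(idx, quad, by_sp, scheme))
    return out


# ---------------------------------------------------------------------------
# scoring


def _check_species_tree(species_tree: PhyloTree, genes: GeneTreeSet) -> PhyloTree:
    st = species_tree.unrooted()
    unknown = sorted(set(st.leaf_labels()) - set(genes.species))
    if unknown:
        raise ValueError(f"species tree taxa absent from gene trees: {unknown}")
    for node in st.postorder():
        if node.is_leaf:
            continue
        deg = len(node.children) + (0 if node is st.root else 1)
        if deg != 3 and len(st) > 3:
            raise ValueError("species tree must be binary")
    return st


def species_tree_tripartitions(
    species_tree: PhyloTree, genes: GeneTreeSet
) -> List[Tuple[int, int, int]]:
    """Mask tripartition at every internal node of the unrooted tree."""
    st = species_tree.unrooted()
    scope = genes.mask(st.leaf_labels())
    below: Dict[int, int] = {}
    order = list(st.postorder())
    for node in order:
        if node.is_leaf:
            below[id(node)] = 1 << genes.sp_index[node.label]
        else:
            m = 0
            for c in node.children:
                m |= below[id(c)]
            below[id(node)] = m
    trips = []
    for node in order:
        if node.is_leaf:
            continue
        masks = [below[id(c)] for c in node.children]
        if node is not st.root:
            masks.append(scope ^ below[id(node)])
        if len(masks) == 3 and all(masks):
            trips.append(tuple(masks))
    return trips


def fast_score(
    species_tree: PhyloTree, genes: GeneTreeSet, scheme: WeightScheme = UNIT
) -> Score:
    """Quartet support score without quartet enumeration.

    Sums cached tripartition gains over the internal nodes of the species
    tree and halves the total (each agreeing quartet is anchored at the two
    nodes where its pairs coalesce).
    """
    st = _check_species_tree(species_tree, genes)
    if len(st) < 4:
        return Score(0.0, 0.0)
    trips = species_tree_tripartitions(st, genes)
    value = sum(genes.gain(t, scheme) for t in trips) / 2.0
    denom = genes.denominator(genes.mask(st.leaf_labels()), scheme)
    return Score(value, denom)


def tripartition_gain(
    trip_blocks: Sequence[Iterable[str]], genes: GeneTreeSet, scheme: WeightScheme = UNIT
) -> float:
    """Additive score contribution of a node with the given tripartition."""
    if len(trip_blocks) != 3:
        raise ValueError("a tripartition has exactly 3 blocks")
    masks = tuple(genes.mask(b) for b in trip_blocks)
    return genes.gain(masks, scheme)


def brute_force_score(
    species_tree: PhyloTree, genes: GeneTreeSet, scheme: WeightScheme = UNIT
) -> Score:
    """Oracle scorer: enumerate every species quadruple in every gene tree."""
    st = _check_species_tree(species_tree, genes)
    scope = sorted(st.leaf_labels())
    if len(scope) < 4:
        return Score(0.0, 0.0)
    st_idx = _PathIndex(st)
    st_pairing: Dict[tuple, frozenset] = {}
    for quad in itertools.combinations(scope, 4):
        topo = st_idx.topology(quad)
        assert topo.resolved
        st_pairing[quad] = topo.pairing

    by_sp = genes.individuals_by_species()
    value = 0.0
    denom = 0.0
    for tree in genes.trees:
        idx = _PathIndex(tree)
        present = {
            sp
            for sp in scope
            if any(idx.has(i) for i in by_sp.get(sp, [sp]))
        }
        for quad in itertools.combinations(sorted(present), 4):
            masses = _quad_masses(idx, quad, by_sp, scheme)
            if not masses:
                continue
            denom += sum(masses.values())
            value += masses.get(st_pairing[quad], 0.0)
    return Score(value, denom)
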