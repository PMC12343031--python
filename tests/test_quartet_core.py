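import itertools
import math
import random

import pytest

from quartetree.treeio import parse_newick
from quartetree.quartet_core import (
    GeneTreeSet,
    QuartetTopology,
    WeightScheme,
    UNIT,
    brute_force_score,
    fast_score,
    induced_quartet,
    multi_individual_quartet,
    quartet_weight,
    tripartition_gain,
)
from conftest import (
    collapse_random_edges,
    quartet_oracle,
    random_binary_tree,
)


def pairing(p1, p2):
    return frozenset((frozenset(p1), frozenset(p2)))


def random_gene_set(rng, n, k, mode, p_missing=0.25, p_polytomy=0.4):
    labels = [f"s{i:02d}" for i in range(n)]
    genes = []
    for _ in range(k):
        keep = [l for l in labels if rng.random() > p_missing]
        if len(keep) < 4:
            keep = rng.sample(labels, 4)
        g = random_binary_tree(
            keep, rng,
            with_supports=(mode != "unit"),
            with_lengths=(mode == "hybrid"),
        )
        if rng.random() < 0.5:
            collapse_random_edges(g, rng, p_polytomy)
        genes.append(g)
    return GeneTreeSet(genes)


class TestInducedQuartet:
    def test_basic(self):
        t = parse_newick("((a,b),(c,d));")
        topo = induced_quartet(t, "abcd")
        assert topo.pairing == pairing("ab", "cd")

    def test_star_unresolved(self):
        topo = induced_quartet(parse_newick("(a,b,c,d);"), "abcd")
        assert topo is not None and topo.pairing is None

    def test_five_taxon_subquartet(self):
        # induced subtree on {a,c,d,e} of (((a,b),c),(d,e)) is ((a,c),(d,e))
        t = parse_newick("(((a,b),c),(d,e));")
        topo = induced_quartet(t, "acde")
        assert topo.pairing == pairing("ac", "de")

    def test_missing_species(self):
        assert induced_quartet(parse_newick("((a,b),(c,d));"), "abcx") is None

    def test_agrees_with_bipartition_oracle(self, rng):
        for _ in range(30):
            n = rng.randint(5, 9)
            t = random_binary_tree([f"t{i}" for i in range(n)], rng)
            if rng.random() < 0.5:
                collapse_random_edges(t, rng, 0.4)
            labels = t.leaf_labels()
            for quad in itertools.combinations(sorted(labels), 4):
                topo = induced_quartet(t, quad)
                assert topo.pairing == quartet_oracle(t, quad)


class TestQuartetWeight:
    def test_unit(self):
        t = parse_newick("((a,b),(c,d));")
        assert quartet_weight(t, "abcd", UNIT) == 1.0

    def test_support_all_one(self):
        t = parse_newick("((a,b)1.0,(c,d)1.0);")
        assert quartet_weight(t, "abcd", WeightScheme("support")) == 1.0

    def test_single_branch_support(self):
        t = parse_newick("((a,b)0.8,(c,d));")
        w = quartet_weight(t, "abcd", WeightScheme("support"))
        assert w == pytest.approx(0.8)

    def test_two_branch_path_product(self):
        # path between the (a,b) and (d,e) anchors crosses supports 0.9, 0.5
        t = parse_newick("(((a,b)0.9,c)0.5,(d,e));")
        w = quartet_weight(t, "abde", WeightScheme("support"))
        assert w == pytest.approx(0.45)

    def test_unresolved_weighs_zero(self):
        assert quartet_weight(parse_newick("(a,b,c,d);"), "abcd", UNIT) == 0.0

    def test_hybrid_length_factor(self):
        t = parse_newick("((a:1,b:2):0.5,(c:0.25,d:0.25));")
        w = quartet_weight(t, "abcd", WeightScheme("hybrid"))
        assert w == pytest.approx(math.exp(-(1 + 2 + 0.25 + 0.25)))

    def test_missing_lengths_factor_one(self):
        t = parse_newick("((a,b),(c,d));")
        assert quartet_weight(t, "abcd", WeightScheme("hybrid")) == pytest.approx(1.0)


class TestBruteForce:
    def test_identical_genes_max_score(self, rng):
        n, k = 7, 5
        st = random_binary_tree([f"s{i}" for i in range(n)], rng)
        genes = GeneTreeSet([st.copy() for _ in range(k)])
        sc = brute_force_score(st, genes, UNIT)
        assert sc.value == k * math.comb(n, 4)
        assert sc.normalized == 1.0

    def test_star_genes_nan(self):
        genes = GeneTreeSet([parse_newick("(a,b,c,d,e);")] * 3)
        sc = brute_force_score(parse_newick("(((a,b),c),(d,e));"), genes, UNIT)
        assert sc.value == 0 and sc.denominator == 0
        assert math.isnan(sc.normalized)

    def test_matches_independent_enumeration(self, rng):
        # third route: bipartition-restriction oracle over all quadruples
        labels = [f"s{i}" for i in range(6)]
        st = random_binary_tree(labels, rng)
        genes_trees = [random_binary_tree(labels, rng) for _ in range(3)]
        genes = GeneTreeSet(genes_trees)
        expect_val = 0
        expect_den = 0
        for g in genes_trees:
            for quad in itertools.combinations(labels, 4):
                gp = quartet_oracle(g, quad)
                if gp is None:
                    continue
                expect_den += 1
                if gp == quartet_oracle(st, quad):
                    expect_val += 1
        sc = brute_force_score(st, genes, UNIT)
        assert sc.value == expect_val
        assert sc.denominator == expect_den


class TestOracleEquivalence:
    """fast_score must reproduce brute_force_score exactly."""

    @pytest.mark.parametrize("mode", ["unit", "support", "hybrid"])
    def test_random_instances(self, mode):
        rng = random.Random(hash(mode) % 2**31)
        for _ in range(40):
            n = rng.randint(4, 10)
            k = rng.randint(1, 8)
            genes = random_gene_set(rng, n, k, mode)
            st = random_binary_tree(list(genes.species), rng)
            scheme = WeightScheme(mode, default_missing_support=rng.choice([1.0, 0.8]))
            bs = brute_force_score(st, genes, scheme)
            fs = fast_score(st, genes, scheme)
            if mode == "unit":
                assert fs.value == bs.value
                assert fs.denominator == bs.denominator
            else:
                assert fs.value == pytest.approx(bs.value, rel=1e-9, abs=1e-12)
                assert fs.denominator == pytest.approx(bs.denominator, rel=1e-9, abs=1e-12)

    def test_unit_value_is_integer(self, rng):
        for _ in range(20):
            genes = random_gene_set(rng, rng.randint(4, 9), 4, "unit")
            st = random_binary_tree(list(genes.species), rng)
            sc = fast_score(st, genes, UNIT)
            assert sc.value == int(sc.value) >= 0

    def test_single_gene_equals_species_tree_n4(self):
        t = parse_newick("((a,b),(c,d));")
        sc = fast_score(t, GeneTreeSet([t.copy()]), UNIT)
        assert sc.value == 1 and sc.denominator == 1


class TestScoreInvariances:
    def _score(self, st, genes):
        return fast_score(st, genes, UNIT).value

    def test_gene_order_permutation(self, rng):
        trees = [random_binary_tree([f"s{i}" for i in range(6)], rng) for _ in range(6)]
        st = random_binary_tree([f"s{i}" for i in range(6)], rng)
        v1 = self._score(st, GeneTreeSet(trees))
        v2 = self._score(st, GeneTreeSet(trees[::-1]))
        assert v1 == v2

    def test_gene_rerooting(self, rng):
        labels = [f"s{i}" for i in range(7)]
        g = random_binary_tree(labels, rng)
        st = random_binary_tree(labels, rng)
        # reroot by re-parsing a rotated newick of the same unrooted tree
        import quartetree.treeio as tio

        g2 = tio.parse_newick(tio.write_newick(g.unrooted()))
        assert self._score(st, GeneTreeSet([g])) == self._score(st, GeneTreeSet([g2]))

    def test_species_tree_rerooting(self, rng):
        labels = [f"s{i}" for i in range(7)]
        genes = GeneTreeSet([random_binary_tree(labels, rng) for _ in range(4)])
        st = random_binary_tree(labels, rng)
        import quartetree.treeio as tio

        st2 = tio.parse_newick(tio.write_newick(st.unrooted()))
        assert self._score(st, genes) == self._score(st2, genes)

    def test_adding_identical_gene_increases_by_choose4(self, rng):
        labels = [f"s{i}" for i in range(8)]
        st = random_binary_tree(labels, rng)
        base = [random_binary_tree(labels, rng) for _ in range(3)]
        v1 = self._score(st, GeneTreeSet(base))
        v2 = self._score(st, GeneTreeSet(base + [st.copy()]))
        assert v2 - v1 == math.comb(8, 4)


class TestTripartitionGain:
    def test_anchored_count_single_tree(self):
        genes = GeneTreeSet([parse_newick("((a,b),(c,d));")])
        g = tripartition_gain([{"a"}, {"b"}, {"c", "d"}], genes, UNIT)
        assert g == 1.0

    def test_block_permutation_symmetry(self, rng):
        genes = random_gene_set(rng, 7, 4, "unit")
        sp = list(genes.species)
        blocks = [{sp[0], sp[1]}, {sp[2]}, {sp[3], sp[4]}]
        gains = {
            tripartition_gain(list(p), genes, UNIT)
            for p in itertools.permutations(blocks)
        }
        assert len(gains) == 1

    def test_star_gene_zero_gain(self):
        genes = GeneTreeSet([parse_newick("(a,b,c,d);")])
        assert tripartition_gain([{"a"}, {"b"}, {"c", "d"}], genes, UNIT) == 0.0

    def test_overlapping_blocks_error(self, rng):
        genes = random_gene_set(rng, 5, 2, "unit")
        sp = list(genes.species)
        with pytest.raises(ValueError):
            tripartition_gain([{sp[0]}, {sp[0]}, {sp[1]}], genes, UNIT)

    def test_sum_of_gains_is_twice_score(self, rng):
        from quartetree.quartet_core import species_tree_tripartitions

        genes = random_gene_set(rng, 8, 5, "unit")
        st = random_binary_tree(list(genes.species), rng)
        trips = species_tree_tripartitions(st, genes)
        total = sum(genes.gain(t, UNIT) for t in trips)
        assert total / 2.0 == fast_score(st, genes, UNIT).value


class TestMultiIndividual:
    def test_single_individual_reduces_to_induced(self):
        g = parse_newick("((a,b),(c,d));")
        genes = GeneTreeSet([g])
        masses = multi_individual_quartet(genes, "abcd")
        assert masses[0] == {pairing("ab", "cd"): 1.0}

    def test_two_individuals_consistent_placement(self):
        g = parse_newick("(((a1,a2),b),(c,d));")
        genes = GeneTreeSet([g], taxon_map={"a1": "A", "a2": "A", "b": "B", "c": "C", "d": "D"})
        masses = multi_individual_quartet(genes, ["A", "B", "C", "D"])
        assert masses[0] == {pairing("AB", "CD"): pytest.approx(1.0)}

    def test_three_one_split(self):
        # of the 4 one-per-species choices, 3 give AC|BD and 1 gives AB|CD
        g = parse_newick("((a1,c),((a2,b2),(b1,d)));")
        tmap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c": "C", "d": "D"}
        genes = GeneTreeSet([g], taxon_map=tmap)
        masses = multi_individual_quartet(genes, ["A", "B", "C", "D"])[0]
        assert masses[pairing("AC", "BD")] == pytest.approx(0.75)
        assert masses[pairing("AB", "CD")] == pytest.approx(0.25)
        assert pairing("AD", "BC") not in masses

    def test_fast_equals_brute_with_map(self, rng):
        species = [f"S{i}" for i in range(5)]
        tmap = {}
        inds = []
        for s in species:
            for j in range(rng.randint(1, 3)):
                lbl = f"{s}x{j}"
                tmap[lbl] = s
                inds.append(lbl)
        for _ in range(10):
            trees = []
            for _ in range(3):
                keep = [l for l in inds if rng.random() > 0.2]
                if len(keep) < 4:
                    keep = rng.sample(inds, 4)
                trees.append(random_binary_tree(keep, rng))
            try:
                genes = GeneTreeSet(trees, taxon_map=tmap)
            except ValueError:
                continue
            st = random_binary_tree(list(genes.species), rng)
            bs = brute_force_score(st, genes, UNIT)
            fs = fast_score(st, genes, UNIT)
            assert fs.value == pytest.approx(bs.value, rel=1e-9, abs=1e-12)
            assert fs.denominator == pytest.approx(bs.denominator, rel=1e-9, abs=1e-12)


class TestGeneTreeSetValidation:
    def test_too_few_species(self):
        with pytest.raises(ValueError):
            GeneTreeSet([parse_newick("(a,b,c);")])

    def test_unmapped_leaf(self):
        with pytest.raises(ValueError, match="absent from taxon map"):
            GeneTreeSet(
                [parse_newick("((a,b),(c,d));")],
                taxon_map={"a": "A", "b": "B", "c": "C"},
            )

    def test_percent_supports_normalized(self):
        genes = GeneTreeSet([parse_newick("((a,b)90,(c,d));")])
        node = next(
            n for t in genes.trees for n in t.postorder() if n.support is not None
        )
        assert node.support == pytest.approx(0.9)

    def test_empty(self):
        with pytest.raises(ValueError):
            GeneTreeSet([])


class TestMSCStatisticalProperty:
    def test_true_tree_beats_alternatives_on_average(self):
        # normalized score of the truth >= mean normalized score of the two
        # NNI alternatives around the internal branch (k large)
        from quartetree.msc_sim import SpeciesTreeModel, simulate_dataset

        model = SpeciesTreeModel(parse_newick("((a:1,b:1):0.4,(c:1,d:1):0.4);").copy())
        model.tree.rooted = True
        genes = simulate_dataset(model, 2000, seed=11)
        scores = {
            nwk: fast_score(parse_newick(nwk), genes, UNIT).normalized
            for nwk in ["((a,b),(c,d));", "((a,c),(b,d));", "((a,d),(b,c));"]
        }
        truth = scores["((a,b),(c,d));"]
        others = [v for k, v in scores.items() if k != "((a,b),(c,d));"]
        assert truth >= sum(others) / 2
        assert truth > 1 / 3
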