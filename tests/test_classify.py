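"""Subfamily assignment, kinase-domain distances, neighbour joining and
HMM-vs-tree concordance.

NJ is validated on additive distance matrices: distances induced by a known
tree must give back exactly that tree's splits (the defining property of
the algorithm), with an extra cross-check against scikit-bio's independent
implementation.
"""

import numpy as np
import pytest

from kinomescan.classify import (DistanceMatrix, SubfamilyAssignment,
                                 assign_subfamily, classification_concordance,
                                 distance_matrix, nj_tree,
                                 pairwise_kinase_distance)
from kinomescan.groups import group_for_subfamily
from kinomescan.simulate import sample_background, sample_domain


class TestAssignSubfamily:
    def test_generative_recovery(self, hmm_library):
        clan, library = hmm_library
        rng = np.random.default_rng(42)
        models = [library[n] for n in sorted(library)]
        for name in sorted(library):
            seq = sample_background(rng, 20) + sample_domain(library[name], rng)
            a = assign_subfamily(seq, models, gene_id="g")
            assert a.subfamily == name
            assert a.margin > 0 and not a.ambiguous

    def test_background_is_unclassified(self, hmm_library):
        _, library = hmm_library
        rng = np.random.default_rng(9)
        models = [library[n] for n in sorted(library)]
        a = assign_subfamily(sample_background(rng, 60), models)
        assert a.subfamily == "Unclassified"
        assert a.group == "Unclassified"

    def test_tie_is_flagged_ambiguous_and_broken_lexicographically(self, hmm_library):
        _, library = hmm_library
        name = sorted(library)[0]
        model = library[name]
        import dataclasses
        twin_a = dataclasses.replace(model, model_id="AAA_twin")
        twin_b = dataclasses.replace(model, model_id="BBB_twin")
        rng = np.random.default_rng(5)
        seq = sample_domain(model, rng)
        a = assign_subfamily(seq, [twin_b, twin_a])
        assert a.subfamily == "AAA_twin"
        assert a.margin == 0.0
        assert a.ambiguous

    def test_empty_library_raises(self):
        with pytest.raises(ValueError):
            assign_subfamily("MKKA", [])

    def test_determinism(self, hmm_library):
        _, library = hmm_library
        models = [library[n] for n in sorted(library)]
        rng = np.random.default_rng(3)
        seq = sample_domain(models[2], rng)
        a1 = assign_subfamily(seq, models)
        a2 = assign_subfamily(seq, list(reversed(models)))
        assert (a1.subfamily, a1.best_score, a1.margin) == \
               (a2.subfamily, a2.best_score, a2.margin)


def test_group_prefix_lookup():
    assert group_for_subfamily("RLK-Pelle_DLSV") == "RLK-Pelle"
    assert group_for_subfamily("CMGC_CDK") == "CMGC"
    assert group_for_subfamily("Group-Pl-2") == "Plant-specific"
    assert group_for_subfamily("Unclassified") == "Unclassified"


class TestPairwiseDistance:
    def test_identical_sequences(self):
        assert pairwise_kinase_distance("KINASE", "KINASE") == 0.0

    def test_single_mismatch(self):
        # gapless optimum: one mismatched column of six
        assert pairwise_kinase_distance("KINASE", "KINASA") == pytest.approx(1 / 6)

    def test_symmetry(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = sample_background(rng, int(rng.integers(10, 40)))
            b = sample_background(rng, int(rng.integers(10, 40)))
            assert pairwise_kinase_distance(a, b) == pytest.approx(
                pairwise_kinase_distance(b, a))

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            pairwise_kinase_distance("", "KINASE")


# --- NJ -------------------------------------------------------------------

def random_additive_tree(rng, n):
    """Random binary tree over n leaves; returns (distance matrix, splits)."""
    nodes = {i: [f"L{i}"] for i in range(n)}
    dist = np.zeros((n, n))
    active = list(range(n))
    depth = {i: 0.0 for i in range(n)}  # not needed; use pair merging
    # build by random joins, tracking leaf-to-leaf distances
    lengths = {}
    next_id = n
    leaf_sets = {i: frozenset([i]) for i in range(n)}
    children = {}
    while len(active) > 1:
        i, j = sorted(rng.choice(active, size=2, replace=False))
        li = rng.uniform(0.1, 1.0)
        lj = rng.uniform(0.1, 1.0)
        for a in leaf_sets[i]:
            for b in leaf_sets[j]:
                dist[a, b] = dist[b, a] = (
                    _depth_to(children, lengths, i, a) + li
                    + _depth_to(children, lengths, j, b) + lj)
        children[next_id] = (i, j)
        lengths[(next_id, i)] = li
        lengths[(next_id, j)] = lj
        leaf_sets[next_id] = leaf_sets[i] | leaf_sets[j]
        active = [a for a in active if a not in (i, j)] + [next_id]
        next_id += 1
    labels = [f"L{i}" for i in range(n)]
    splits = set()
    for node, leaves in leaf_sets.items():
        if node < n or len(leaves) in (0, 1, n, n - 1):
            continue
        side = frozenset(f"L{i}" for i in leaves)
        other = frozenset(labels) - side
        splits.add(frozenset([side, other]))
    return DistanceMatrix(labels=labels, d=dist), splits


def _depth_to(children, lengths, node, leaf):
    if node == leaf:
        return 0.0
    i, j = children[node]
    for child in (i, j):
        stack = [child]
        found = False
        # check membership by walking down
        seen = []
        while stack:
            x = stack.pop()
            if x == leaf:
                found = True
                break
            if x in children:
                stack.extend(children[x])
        if found:
            return lengths[(node, child)] + _depth_to(children, lengths, child, leaf)
    raise AssertionError("leaf not under node")


def tree_splits(unrooted):
    names = set(unrooted.leaf_names)
    splits = set()
    for clade in unrooted.tree.get_nonterminals():
        if clade is unrooted.tree.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        if 1 < len(side) < len(names) - 1:
            splits.add(frozenset([side, frozenset(names - side)]))
    return splits


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        dm = DistanceMatrix(labels=["a", "b", "c"], d=d)
        tree = nj_tree(dm)
        lengths = {t.name: t.branch_length for t in tree.tree.get_terminals()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_recovers_additive_topologies(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(10):
            dm, true_splits = random_additive_tree(rng, n)
            tree = nj_tree(dm)
            assert tree_splits(tree) == true_splits

    def test_matches_scikit_bio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(77)
        dm, true_splits = random_additive_tree(rng, 7)
        ours = tree_splits(nj_tree(dm))
        sk_dm = skbio.DistanceMatrix(dm.d, ids=dm.labels)
        sk_tree = skbio.tree.nj(sk_dm)
        sk_splits = set()
        names = set(dm.labels)
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(names) - 1:
                sk_splits.add(frozenset([side, frozenset(names - side)]))
        assert ours == sk_splits == true_splits

    def test_too_few_taxa_and_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=["a", "b"], d=np.zeros((2, 2))))
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], d=bad)

    def test_newick_export_parses(self):
        rng = np.random.default_rng(4)
        dm, _ = random_additive_tree(rng, 5)
        text = nj_tree(dm).to_newick()
        from io import StringIO

        from Bio import Phylo
        parsed = Phylo.read(StringIO(text), "newick")
        assert {t.name for t in parsed.get_terminals()} == set(dm.labels)


class TestConcordance:
    @staticmethod
    def _cluster_matrix():
        # two tight clusters of three; the third member of cluster A is a
        # little farther out than the a1-a2 pair
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        d = np.full((6, 6), 1.0)
        np.fill_diagonal(d, 0.0)
        for i, j, v in [(0, 1, 0.05), (0, 2, 0.10), (1, 2, 0.10),
                        (3, 4, 0.05), (3, 5, 0.10), (4, 5, 0.10)]:
            d[i, j] = d[j, i] = v
        return DistanceMatrix(labels=labels, d=d)

    @staticmethod
    def _assign(labels_to_subfamily):
        return [SubfamilyAssignment(g, s, "G", 50.0, 10.0, False)
                for g, s in labels_to_subfamily.items()]

    def test_perfect_concordance(self):
        tree = nj_tree(self._cluster_matrix())
        assignments = self._assign({f"a{i}": "A" for i in (1, 2, 3)}
                                   | {f"b{i}": "B" for i in (1, 2, 3)})
        frac, discordant = classification_concordance(tree, assignments)
        assert frac == 1.0
        assert discordant == []

    def test_single_mislabeled_leaf(self):
        tree = nj_tree(self._cluster_matrix())
        labels = {f"a{i}": "A" for i in (1, 2, 3)}
        labels |= {f"b{i}": "B" for i in (1, 2, 3)}
        labels["a3"] = "B"  # mislabeled: nearest leaves are still A
        frac, discordant = classification_concordance(tree, self._assign(labels))
        assert frac == pytest.approx(5 / 6)
        assert discordant == ["a3"]

    def test_missing_assignment_raises(self):
        tree = nj_tree(self._cluster_matrix())
        with pytest.raises(KeyError):
            classification_concordance(tree, self._assign({"a1": "A"}))

    def test_generative_two_subfamily_concordance(self, hmm_library):
        _, library = hmm_library
        rng = np.random.default_rng(321)
        names = sorted(library)[:2]
        seqs, assignments = {}, []
        for name in names:
            for i in range(5):
                gene = f"{name}-{i}"
                seqs[gene] = sample_domain(library[name], rng)
                assignments.append(SubfamilyAssignment(gene, name, "G", 50, 10, False))
        tree = nj_tree(distance_matrix(seqs))
        frac, _ = classification_concordance(tree, assignments)
        assert frac >= 0.95
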