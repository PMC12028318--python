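"""BBH families, pangenome graph, synteny, taxonomy thresholds, Dollo."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import phagekit as pk
from phagekit.genomes import GeneCall, Proteome
from phagekit.pangenome import _as_rooted_tree
from phagekit.similarity import SimilarityHit


def proteome(genome_id, gene_ids):
    return Proteome(
        genome_id,
        [
            GeneCall(genome_id, gid, i, "+", 100 * i, 100 * i + 30, "M" + "A" * 9)
            for i, gid in enumerate(gene_ids)
        ],
    )


def hit(qg, q, tg, t, ident=95.0, cov=100.0, score=100.0):
    return SimilarityHit((qg, q), (tg, t), ident, cov, score)


class TestBBHEdges:
    def test_mutual_best_kept(self):
        hits = [hit("A", "a", "B", "b"), hit("B", "b", "A", "a")]
        assert pk.bbh_edges(hits) == [(("A", "a"), ("B", "b"))]

    def test_non_mutual_rejected(self):
        # a's best is b, but b's best is a2
        hits = [
            hit("A", "a", "B", "b", score=100),
            hit("B", "b", "A", "a", score=100),
            hit("B", "b", "A", "a2", score=150),
            hit("A", "a2", "B", "b", score=150),
        ]
        assert pk.bbh_edges(hits) == [(("A", "a2"), ("B", "b"))]

    @pytest.mark.parametrize(
        "ident,cov,expect",
        [(19.0, 100.0, 0), (20.0, 100.0, 0), (21.0, 100.0, 1), (95.0, 50.0, 0), (95.0, 51.0, 1)],
    )
    def test_strict_cutoffs(self, ident, cov, expect):
        hits = [hit("A", "a", "B", "b", ident, cov), hit("B", "b", "A", "a", ident, cov)]
        assert len(pk.bbh_edges(hits)) == expect

    def test_tie_break_score_identity_then_id(self):
        hits = [
            hit("A", "a", "B", "b2", ident=90, score=100),
            hit("A", "a", "B", "b1", ident=90, score=100),
            hit("B", "b1", "A", "a", score=100),
            hit("B", "b2", "A", "a", score=100),
        ]
        # equal score and identity: lexicographically smaller target b1 wins
        assert pk.bbh_edges(hits) == [(("A", "a"), ("B", "b1"))]

    def test_intra_genome_hits_ignored(self):
        hits = [hit("A", "a", "A", "a2"), hit("A", "a2", "A", "a")]
        assert pk.bbh_edges(hits) == []


class TestBBHGroups:
    def test_no_edges_gives_singletons(self):
        p = proteome("A", ["a1", "a2", "a3", "a4", "a5"])
        groups, _ = pk.bbh_groups([], [p])
        assert len(groups) == 5
        assert all(len(g.members) == 1 for g in groups)

    def test_transitive_component(self):
        pa, pb, pc = proteome("A", ["a"]), proteome("B", ["b"]), proteome("C", ["c"])
        edges = [(("A", "a"), ("B", "b")), (("B", "b"), ("C", "c"))]
        groups, _ = pk.bbh_groups(edges, [pa, pb, pc])
        assert len(groups) == 1
        assert groups[0].members == frozenset({("A", "a"), ("B", "b"), ("C", "c")})
        assert groups[0].is_core and groups[0].is_single_copy

    def test_matches_brute_force_reachability(self):
        """Components equal brute-force transitive closure on random edge sets."""
        rng = np.random.default_rng(17)
        genomes = [proteome(g, [f"{g}{i}" for i in range(6)]) for g in "ABCD"]
        genes = [gene.key for p in genomes for gene in p]
        for _ in range(20):
            n_edges = int(rng.integers(0, 15))
            edges = []
            for _ in range(n_edges):
                i, j = rng.choice(len(genes), size=2, replace=False)
                a, b = genes[i], genes[j]
                if a[0] != b[0]:
                    edges.append((a, b))
            groups, _ = pk.bbh_groups(edges, genomes)
            # brute-force reachability
            reach = {g: {g} for g in genes}
            changed = True
            while changed:
                changed = False
                for a, b in edges:
                    union = reach[a] | reach[b]
                    for node in union:
                        if reach[node] != union:
                            reach[node] |= union
                            changed = True
                brute = {frozenset(v) for v in reach.values()}
            assert {g.members for g in groups} == brute
            assert sum(len(g.members) for g in groups) == len(genes)

    def test_spectrum_fractions_sum_to_one(self, small_genomes):
        hits = pk.all_vs_all_similarity(small_genomes.proteomes)
        groups, spectrum = pk.bbh_groups(pk.bbh_edges(hits), small_genomes.proteomes)
        assert sum(spectrum.values()) == pytest.approx(1.0)


class TestAdjacencyGraph:
    def groups_for(self, proteomes, mapping):
        groups = []
        fams = {}
        for key, fam in mapping.items():
            fams.setdefault(fam, set()).add(key)
        n_genomes = len(proteomes)
        for i, (fam, members) in enumerate(sorted(fams.items())):
            genomes = {g for g, _ in members}
            groups.append(
                pk.BBHGroup(fam, frozenset(members), len(genomes),
                            len(genomes) == n_genomes, len(members) == len(genomes))
            )
        return groups

    def test_hand_example_two_genomes(self):
        p1 = proteome("G1", ["x", "y", "z"])  # families a, b, c
        p2 = proteome("G2", ["u", "v", "w"])  # families a, c, b
        mapping = {
            ("G1", "x"): "a", ("G1", "y"): "b", ("G1", "z"): "c",
            ("G2", "u"): "a", ("G2", "v"): "c", ("G2", "w"): "b",
        }
        g = pk.pangenome_adjacency_graph(self.groups_for([p1, p2], mapping), [p1, p2])
        assert g.edge_weight("a", "b") == 1
        assert g.edge_weight("b", "c") == 2
        assert g.edge_weight("a", "c") == 1

    def test_single_genome_edge(self):
        p = proteome("G", ["x", "y"])
        mapping = {("G", "x"): "a", ("G", "y"): "b"}
        g = pk.pangenome_adjacency_graph(self.groups_for([p], mapping), [p])
        assert g.edge_weight("a", "b") == 1
        assert g.total_weight() == 1

    def test_circular_adds_wrap_edge(self):
        p = proteome("G", ["x", "y", "z"])
        mapping = {("G", "x"): "a", ("G", "y"): "b", ("G", "z"): "c"}
        groups = self.groups_for([p], mapping)
        linear = pk.pangenome_adjacency_graph(groups, [p])
        circular = pk.pangenome_adjacency_graph(groups, [p], circular=True)
        assert linear.edge_weight("a", "c") == 0
        assert circular.edge_weight("a", "c") == 1

    def test_tandem_same_family_self_loop(self):
        p = proteome("G", ["x", "y"])
        mapping = {("G", "x"): "a", ("G", "y"): "a"}
        g = pk.pangenome_adjacency_graph(self.groups_for([p], mapping), [p])
        assert g.edge_weight("a", "a") == 1

    def test_weight_conservation_matches_enumeration(self):
        """Sum of weights equals sum(n_genes - 1); weights match an oracle."""
        rng = np.random.default_rng(31)
        fams = [f"f{i}" for i in range(8)]
        proteomes, mapping = [], {}
        for g in "ABCDE":
            n = int(rng.integers(2, 12))
            ids = [f"{g}{i}" for i in range(n)]
            proteomes.append(proteome(g, ids))
            for i in ids:
                mapping[(g, i)] = fams[int(rng.integers(len(fams)))]
        groups = self.groups_for(proteomes, mapping)
        g = pk.pangenome_adjacency_graph(groups, proteomes)
        assert g.total_weight() == sum(len(p) - 1 for p in proteomes)
        # direct adjacency enumeration oracle
        from collections import Counter
        oracle = Counter()
        for p in proteomes:
            keys = [gene.key for gene in p]
            for a, b in zip(keys, keys[1:]):
                oracle[frozenset((mapping[a], mapping[b])) if mapping[a] != mapping[b]
                       else frozenset((mapping[a],))] += 1
        for pair, count in oracle.items():
            fs = sorted(pair)
            a, b = (fs[0], fs[0]) if len(fs) == 1 else fs
            assert g.edge_weight(a, b) == count


class TestSynteny:
    def test_identical_genomes_link_every_gene(self, small_genomes):
        proteomes = small_genomes.proteomes[:3]
        hits = pk.all_vs_all_similarity(proteomes)
        groups, _ = pk.bbh_groups(pk.bbh_edges(hits), proteomes)
        order = [p.genome_id for p in proteomes]
        links = pk.synteny_links(groups, proteomes, order, hits)
        # links only connect adjacent genomes in the order
        adjacent = set(zip(order, order[1:]))
        for a, b, ident in links:
            assert (a[0], b[0]) in adjacent
            assert 0 <= ident <= 100
        # count equals shared families per adjacent pair (single-copy here)
        for g1, g2 in adjacent:
            shared = sum(
                1
                for grp in groups
                if any(k[0] == g1 for k in grp.members)
                and any(k[0] == g2 for k in grp.members)
            )
            observed = sum(1 for a, b, _ in links if a[0] == g1 and b[0] == g2)
            assert observed == shared

    def test_unknown_genome_rejected(self, small_genomes):
        with pytest.raises(ValueError, match="not in the collection"):
            pk.synteny_links([], small_genomes.proteomes, ["nope"], [])


class TestIntergenomicClassify:
    def matrix(self, ids, entries):
        return pd.DataFrame(entries, index=ids, columns=ids, dtype=float)

    def test_rank_thresholds(self):
        sim = self.matrix(["A", "B", "C"], [[100, 96, 60], [96, 100, 60], [60, 60, 100]])
        ranks = pk.intergenomic_similarity_classify(sim)
        assert ranks.loc["A", "species"] == ranks.loc["B", "species"]
        assert ranks.loc["A", "species"] != ranks.loc["C", "species"]
        assert ranks.loc["A", "genus"] != ranks.loc["C", "genus"]
        assert ranks.loc["A", "family"] == ranks.loc["C", "family"]

    def test_single_linkage_chain(self):
        sim = self.matrix(["A", "B", "C"], [[100, 96, 80], [96, 100, 96], [80, 96, 100]])
        ranks = pk.intergenomic_similarity_classify(sim)
        assert len(set(ranks["species"])) == 1  # A-B-C chained at >= 95

    def test_nested_partitions(self):
        rng = np.random.default_rng(3)
        n = 8
        a = rng.uniform(30, 100, size=(n, n))
        sim = (a + a.T) / 2
        np.fill_diagonal(sim, 100.0)
        ids = [f"g{i}" for i in range(n)]
        ranks = pk.intergenomic_similarity_classify(pd.DataFrame(sim, index=ids, columns=ids))
        # species clusters refine genus clusters refine family clusters
        for fine, coarse in (("species", "genus"), ("genus", "family")):
            for cluster in set(ranks[fine]):
                members = ranks.index[ranks[fine] == cluster]
                assert len(set(ranks.loc[members, coarse])) == 1

    def test_asymmetric_rejected(self):
        sim = self.matrix(["A", "B"], [[100, 90], [50, 100]])
        with pytest.raises(ValueError, match="asymmetric"):
            pk.intergenomic_similarity_classify(sim)


def exhaustive_min_losses(tree, present):
    """Oracle: minimal loss count over all single-gain Dollo assignments."""
    import dendropy

    nodes = list(tree.preorder_node_iter())
    leaves = {n: frozenset(l.taxon.label for l in n.leaf_iter()) for n in nodes}
    best = None
    for gain in nodes:
        if not present <= leaves[gain]:
            continue
        below = [n for n in gain.preorder_iter()]
        internal = [n for n in below if not n.is_leaf()]
        # enumerate presence states of internal nodes below the gain
        for bits in itertools.product([0, 1], repeat=len(internal)):
            state = {n: b for n, b in zip(internal, bits)}
            for n in below:
                if n.is_leaf():
                    state[n] = 1 if n.taxon.label in present else 0
            if state.get(gain, 1) != 1:
                continue
            ok = True
            losses = 0
            for n in below:
                if n is gain:
                    continue
                parent_state = state[n.parent_node]
                if state[n] == 1 and parent_state == 0:
                    ok = False  # regain below a loss: not Dollo
                    break
                if state[n] == 0 and parent_state == 1:
                    losses += 1
            if ok and (best is None or losses < best):
                best = losses
    return best


class TestDollo:
    def test_family_everywhere_gained_at_root(self, small_genomes):
        tree = small_genomes.truth.tree_newick
        taxa = sorted(p.genome_id for p in small_genomes.proteomes)
        presence = pd.DataFrame({t: [1] for t in taxa}, index=["fam"])
        rec = pk.dollo_gain_loss(presence, tree)
        assert rec.gains["fam"] == frozenset(taxa)
        assert rec.losses["fam"] == frozenset()

    def test_single_leaf_gain_on_terminal_branch(self, small_genomes):
        tree = small_genomes.truth.tree_newick
        taxa = sorted(p.genome_id for p in small_genomes.proteomes)
        presence = pd.DataFrame(
            {t: [1 if t == taxa[0] else 0] for t in taxa}, index=["fam"]
        )
        rec = pk.dollo_gain_loss(presence, tree)
        assert rec.gains["fam"] == frozenset([taxa[0]])

    def test_three_leaf_hand_case(self):
        presence = pd.DataFrame({"A": [1], "B": [0], "C": [1]}, index=["fam"])
        rec = pk.dollo_gain_loss(presence, "((A:1,B:1):1,C:1);")
        assert rec.gains["fam"] == frozenset("ABC")
        assert rec.losses["fam"] == frozenset({frozenset("B")})

    def test_absent_family_rejected(self):
        presence = pd.DataFrame({"A": [0], "B": [0], "C": [0]}, index=["fam"])
        with pytest.raises(ValueError, match="absent"):
            pk.dollo_gain_loss(presence, "((A:1,B:1):1,C:1);")

    def test_unrooted_rejected(self):
        presence = pd.DataFrame({"A": [1], "B": [1], "C": [1]}, index=["fam"])
        with pytest.raises(ValueError, match="rooted"):
            pk.dollo_gain_loss(presence, "(A:1,B:1,C:1);")

    def test_matches_exhaustive_search_small_trees(self):
        """Loss counts equal exhaustive minimum-loss search on 5-leaf trees."""
        import dendropy
        import random as _random

        for seed in range(3):
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=5,
                rng=_random.Random(seed),
            )
            for i, leaf in enumerate(tree.leaf_node_iter()):
                leaf.taxon.label = f"t{i}"
            taxa = [f"t{i}" for i in range(5)]
            newick = tree.as_string(schema="newick", suppress_rooting=True)
            for bits in itertools.product([0, 1], repeat=5):
                if not any(bits):
                    continue
                presence = pd.DataFrame({t: [b] for t, b in zip(taxa, bits)}, index=["f"])
                rec = pk.dollo_gain_loss(presence, newick)
                oracle = exhaustive_min_losses(_as_rooted_tree(newick), frozenset(
                    t for t, b in zip(taxa, bits) if b
                ))
                assert rec.loss_count("f") == oracle

    def test_branch_tallies_aggregate(self):
        presence = pd.DataFrame(
            {"A": [1, 1], "B": [0, 1], "C": [1, 1]}, index=["f1", "f2"]
        )
        rec = pk.dollo_gain_loss(presence, "((A:1,B:1):1,C:1);")
        tallies = rec.branch_tallies()
        root_row = tallies[tallies["branch"] == "A,B,C"].iloc[0]
        assert root_row["gains"] == 2
        b_row = tallies[tallies["branch"] == "B"].iloc[0]
        assert b_row["losses"] == 1
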