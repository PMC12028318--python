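"""BBH gene families, pangenome graph, synteny, taxonomy thresholds, Dollo.

Gene families are built as connected components of the best-bidirectional-
hit (BBH) graph: for every ordered genome pair, each gene's single best hit
in the other genome (by score, then identity, then lexicographic target id)
is retained as an undirected edge when the choice is mutual and the
alignment passes the identity (>20%) and shortest-protein-coverage (>50%)
cutoffs.  On top of the families the module builds the adjacency-weighted
pangenome graph, pairwise synteny links for a display order of genomes,
single-linkage intergenomic-similarity clusters at the ICTV family / genus /
species thresholds, and Dollo gain/loss reconstructions of family
presence/absence on a rooted tree.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .genomes import Proteome
from .similarity import GeneKey, SimilarityHit

__all__ = [
    "BBHGroup",
    "bbh_edges",
    "bbh_groups",
    "PangenomeGraph",
    "pangenome_adjacency_graph",
    "synteny_links",
    "intergenomic_similarity_classify",
    "DolloReconstruction",
    "dollo_gain_loss",
    "presence_absence_matrix",
]


# ---------------------------------------------------------------------------
# BBH graph and gene families
# ---------------------------------------------------------------------------

def bbh_edges(
    hits: Iterable[SimilarityHit],
    id_cutoff: float = 20.0,
    cov_cutoff: float = 50.0,
) -> list[tuple[GeneKey, GeneKey]]:
    """Undirected best-bidirectional-hit edges between genes of different genomes.

    For each ordered genome pair (A, B) and each gene a in A, its best hit
    b in B is the hit with maximal score (ties broken by higher identity,
    then lexicographically smaller target gene id).  The edge (a, b) is
    kept iff b's best hit in A is a, identity > ``id_cutoff`` and coverage
    of the shortest protein > ``cov_cutoff``.  Intra-genome hits are
    ignored.
    """
    best: dict[tuple[GeneKey, str], SimilarityHit] = {}
    for hit in hits:
        if hit.query[0] == hit.target[0]:
            continue
        slot = (hit.query, hit.target[0])
        cur = best.get(slot)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[slot] = hit

    edges: set[tuple[GeneKey, GeneKey]] = set()
    for (query, target_genome), hit in best.items():
        if hit.identity <= id_cutoff or hit.coverage_shortest <= cov_cutoff:
            continue
        reciprocal = best.get((hit.target, query[0]))
        if reciprocal is not None and reciprocal.target == query:
            edge = tuple(sorted((query, hit.target)))
            edges.add(edge)  # type: ignore[arg-type]
    return sorted(edges)


def _hit_rank(hit: SimilarityHit) -> tuple[float, float, GeneKey]:
    # minimal rank = best: highest score, then highest identity, then
    # lexicographically smallest target id
    return (-hit.score, -hit.identity, hit.target)


@dataclass(frozen=True)
class BBHGroup:
    """One gene family: a connected component of the BBH graph."""

    group_id: str
    members: frozenset[GeneKey]
    genome_count: int
    is_core: bool  # member in every genome of the collection
    is_single_copy: bool  # exactly one member per represented genome


def bbh_groups(
    edges: Iterable[tuple[GeneKey, GeneKey]],
    proteomes: Sequence[Proteome],
) -> tuple[list[BBHGroup], dict[str, float]]:
    """Gene families as connected components, plus the persistence spectrum.

    Genes without any BBH edge become singleton families.  The spectrum
    reports the fraction of families present in >80% of genomes, in <20%,
    and in between.
    """
    graph = nx.Graph()
    all_genes = [gene.key for proteome in proteomes for gene in proteome]
    graph.add_nodes_from(all_genes)
    known = set(all_genes)
    for a, b in edges:
        if a not in known or b not in known:
            missing = a if a not in known else b
            raise ValueError(f"edge references unknown gene {missing}")
        graph.add_edge(a, b)

    n_genomes = len(proteomes)
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    groups = []
    for idx, comp in enumerate(components):
        genomes = {genome for genome, _ in comp}
        groups.append(
            BBHGroup(
                group_id=f"fam{idx:05d}",
                members=frozenset(comp),
                genome_count=len(genomes),
                is_core=len(genomes) == n_genomes,
                is_single_copy=len(comp) == len(genomes),
            )
        )
    n = len(groups)
    spectrum = {
        "frac_above_80pct": sum(g.genome_count / n_genomes > 0.8 for g in groups) / n,
        "frac_below_20pct": sum(g.genome_count / n_genomes < 0.2 for g in groups) / n,
    }
    spectrum["frac_intermediate"] = 1.0 - spectrum["frac_above_80pct"] - spectrum["frac_below_20pct"]
    return groups, spectrum


def presence_absence_matrix(
    groups: Sequence[BBHGroup], proteomes: Sequence[Proteome]
) -> pd.DataFrame:
    """Family x genome 0/1 matrix (1 = at least one member in the genome)."""
    genome_ids = [p.genome_id for p in proteomes]
    data = {
        g.group_id: [int(any(genome == gid for genome, _ in g.members)) for gid in genome_ids]
        for g in groups
    }
    return pd.DataFrame(data, index=genome_ids).T


# ---------------------------------------------------------------------------
# Pangenome adjacency graph and synteny links
# ---------------------------------------------------------------------------

@dataclass
class PangenomeGraph:
    """Gene-family adjacency graph.

    Nodes are family ids; an edge weight counts the genomes-and-positions
    in which members of the two families are direct neighbors in gene
    order.  Self-loops record tandem same-family neighbors.
    """

    graph: nx.Graph

    def edge_weight(self, a: str, b: str) -> int:
        return self.graph.edges[a, b]["weight"] if self.graph.has_edge(a, b) else 0

    def total_weight(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {"family_a": a, "family_b": b, "weight": d["weight"]}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows)

    def write_edge_list(self, path: str | Path, delimiter: str = "\t") -> None:
        self.to_edge_list().to_csv(path, sep=delimiter, index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def _gene_to_group_map(groups: Sequence[BBHGroup]) -> dict[GeneKey, str]:
    mapping: dict[GeneKey, str] = {}
    for group in groups:
        for key in group.members:
            mapping[key] = group.group_id
    return mapping


def pangenome_adjacency_graph(
    groups: Sequence[BBHGroup],
    proteomes: Sequence[Proteome],
    circular: bool = False,
) -> PangenomeGraph:
    """Adjacency-weighted pangenome graph over gene families.

    For each genome, every pair of rank-consecutive genes contributes one
    count to the edge between their families, ignoring strand.  With
    ``circular`` the last and first genes are also neighbors.  For linear
    genomes the total edge weight (self-loops included) is
    sum over genomes of (n_genes - 1).
    """
    mapping = _gene_to_group_map(groups)
    graph = nx.Graph()
    graph.add_nodes_from(g.group_id for g in groups)
    for proteome in proteomes:
        keys = [gene.key for gene in proteome]
        for key in keys:
            if key not in mapping:
                raise ValueError(f"gene {key} is not assigned to any family")
        pairs = list(zip(keys, keys[1:]))
        if circular and len(keys) > 1:
            pairs.append((keys[-1], keys[0]))
        for a, b in pairs:
            fa, fb = mapping[a], mapping[b]
            if graph.has_edge(fa, fb):
                graph.edges[fa, fb]["weight"] += 1
            else:
                graph.add_edge(fa, fb, weight=1)
    return PangenomeGraph(graph)


def synteny_links(
    groups: Sequence[BBHGroup],
    proteomes: Sequence[Proteome],
    genome_order: Sequence[str],
    hits: Iterable[SimilarityHit],
) -> list[tuple[GeneKey, GeneKey, float]]:
    """Family links between consecutive genomes of a display order.

    For each adjacent genome pair in ``genome_order`` and each family with
    members in both, one link per cross-genome member pair is emitted,
    annotated with the % identity recorded at the similarity stage (pairs
    with no recorded hit are skipped: nothing aligned to display).
    """
    known = {p.genome_id for p in proteomes}
    for gid in genome_order:
        if gid not in known:
            raise ValueError(f"genome {gid!r} not in the collection")
    identity: dict[tuple[GeneKey, GeneKey], float] = {}
    for hit in hits:
        identity[(hit.query, hit.target)] = hit.identity

    links = []
    for g1, g2 in zip(genome_order, genome_order[1:]):
        for group in groups:
            left = sorted(k for k in group.members if k[0] == g1)
            right = sorted(k for k in group.members if k[0] == g2)
            for a, b in itertools.product(left, right):
                if (a, b) in identity:
                    links.append((a, b, identity[(a, b)]))
    return links


# ---------------------------------------------------------------------------
# Intergenomic similarity thresholds (ICTV ranks)
# ---------------------------------------------------------------------------

DEFAULT_RANK_THRESHOLDS: dict[str, float] = {"family": 50.0, "genus": 70.0, "species": 95.0}


def intergenomic_similarity_classify(
    similarity: pd.DataFrame,
    thresholds: Mapping[str, float] = DEFAULT_RANK_THRESHOLDS,
) -> pd.DataFrame:
    """Single-linkage rank clusters of a genome x genome % similarity matrix.

    At each threshold t, clusters are connected components of the graph
    joining genomes with similarity >= t; clusters are therefore nested
    from species up to family.  Returns a genome-indexed frame with one
    integer cluster label column per rank.
    """
    sim = similarity.astype(float)
    if list(sim.index) != list(sim.columns):
        raise ValueError("similarity matrix must have identical row and column ids")
    arr = sim.to_numpy()
    if not np.allclose(arr, arr.T, atol=1e-6):
        raise ValueError("similarity matrix is asymmetric beyond tolerance 1e-6")
    genomes = list(sim.index)
    out = {}
    for rank, t in sorted(thresholds.items(), key=lambda kv: kv[1]):
        graph = nx.Graph()
        graph.add_nodes_from(genomes)
        for i, j in itertools.combinations(range(len(genomes)), 2):
            if arr[i, j] >= t:
                graph.add_edge(genomes[i], genomes[j])
        labels = {}
        for idx, comp in enumerate(sorted(nx.connected_components(graph), key=min)):
            for g in comp:
                labels[g] = idx
        out[rank] = [labels[g] for g in genomes]
    return pd.DataFrame(out, index=genomes)


# ---------------------------------------------------------------------------
# Dollo gain/loss
# ---------------------------------------------------------------------------

@dataclass
class DolloReconstruction:
    """Dollo parsimony reconstruction of family presence/absence.

    Each family is gained exactly once, on the branch above the most recent
    common ancestor of the genomes carrying it, and lost on the minimal set
    of branches below the gain explaining the absences.  Branches are
    identified by the set of leaf labels they subtend.
    """

    gains: dict[str, frozenset[str]]  # family -> clade of the gain branch
    losses: dict[str, frozenset[frozenset[str]]]  # family -> clades of loss branches

    def loss_count(self, family_id: str) -> int:
        return len(self.losses[family_id])

    def branch_tallies(self) -> pd.DataFrame:
        """Per-branch gain and loss totals aggregated over families."""
        counts: dict[frozenset[str], list[int]] = defaultdict(lambda: [0, 0])
        for clade in self.gains.values():
            counts[clade][0] += 1
        for clades in self.losses.values():
            for clade in clades:
                counts[clade][1] += 1
        rows = [
            {"branch": ",".join(sorted(clade)), "gains": g, "losses": l}
            for clade, (g, l) in sorted(counts.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


def _as_rooted_tree(tree: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    root_children = tree.seed_node.child_nodes()
    if len(root_children) != 2:
        raise ValueError(
            f"tree must be rooted (bifurcating root; found {len(root_children)} children)"
        )
    return tree


def dollo_gain_loss(
    presence: pd.DataFrame,
    tree: str | dendropy.Tree,
) -> DolloReconstruction:
    """Dollo gain/loss placement for a family x genome 0/1 matrix.

    Leaves of the rooted ``tree`` must match the matrix columns.  A family
    absent from every genome has no gain to place and raises.
    """
    tree = _as_rooted_tree(tree)
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    cols = set(presence.columns)
    if leaf_labels != cols:
        raise ValueError(
            f"tree leaves and matrix genomes differ: {sorted(leaf_labels ^ cols)}"
        )

    # cache subtended leaf sets
    clade: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clade[node] = frozenset([node.taxon.label])
        else:
            clade[node] = frozenset().union(*(clade[c] for c in node.child_nodes()))

    gains: dict[str, frozenset[str]] = {}
    losses: dict[str, frozenset[frozenset[str]]] = {}
    for family_id, row in presence.iterrows():
        present = frozenset(c for c in presence.columns if row[c])
        if not present:
            raise ValueError(f"family {family_id!r} absent from every genome")
        gain_node = _mrca(tree, clade, present)
        gains[family_id] = clade[gain_node]
        losses[family_id] = frozenset(_loss_branches(gain_node, clade, present))
    return DolloReconstruction(gains=gains, losses=losses)


def _mrca(
    tree: dendropy.Tree,
    clade: Mapping[dendropy.Node, frozenset[str]],
    present: frozenset[str],
) -> dendropy.Node:
    node = next(
        leaf for leaf in tree.leaf_node_iter() if leaf.taxon.label in present
    )
    while not present <= clade[node]:
        node = node.parent_node
    return node


def _loss_branches(
    gain_node: dendropy.Node,
    clade: Mapping[dendropy.Node, frozenset[str]],
    present: frozenset[str],
) -> list[frozenset[str]]:
    """Maximal subtrees below the gain with no present leaf (one loss each)."""
    out: list[frozenset[str]] = []
    stack = list(gain_node.child_nodes())
    while stack:
        node = stack.pop()
        if clade[node] & present:
            stack.extend(node.child_nodes())
        else:
            out.append(clade[node])
    return out
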