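"""Phylogeny-derived neighborhood traits and class-association tests.

Host susceptibility classes (see :mod:`phagekit.interactions`) are related
to properties of each host's local phylogenetic neighborhood: the mean
patristic distance to its k closest strains ("polymorphism") and the
fraction of those neighbors sharing a categorical trait such as biome or
sampling location ("trait specificity").  Differences of such quantities
across classes are tested with a Kruskal-Wallis test followed by pairwise
Mann-Whitney U post-hocs with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PatristicMatrix",
    "NeighborhoodProfile",
    "patristic_distance_matrix",
    "neighborhood_profile",
    "class_association_test",
    "AssociationReport",
    "read_host_metadata",
]


@dataclass
class PatristicMatrix:
    """Symmetric leaf-to-leaf path-length matrix in branch-length units."""

    taxon_ids: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        n = len(self.taxon_ids)
        if d.shape != (n, n):
            raise ValueError(f"distance grid shape {d.shape} != ({n}, {n})")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(d, d.T):
            raise ValueError("distance grid must be symmetric")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        self.distances = d

    def distance(self, a: str, b: str) -> float:
        return float(
            self.distances[self.taxon_ids.index(a), self.taxon_ids.index(b)]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.taxon_ids, columns=self.taxon_ids)


@dataclass(frozen=True)
class NeighborhoodProfile:
    """Traits of one host's k nearest strains (the focal strain excluded)."""

    host_id: str
    polymorphism: float  # mean patristic distance to the k closest strains
    trait_specificity: float  # fraction of neighbors sharing the focal trait
    neighbor_ids: tuple[str, ...]


def patristic_distance_matrix(tree: str | dendropy.Tree) -> PatristicMatrix:
    """Pairwise sums of branch lengths between leaves of a Newick tree.

    Every non-root edge must carry a branch length (none is substituted
    silently) and leaf labels must be unique.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in tree")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValueError(
                f"edge above {node.taxon.label if node.taxon else 'an internal node'} "
                "has no branch length"
            )
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return PatristicMatrix(ids, d)


def fraction_sharing_trait(focal_trait: object, neighbor_traits: Sequence[object]) -> float:
    """Default neighborhood statistic: fraction of neighbors with the focal value."""
    return sum(t == focal_trait for t in neighbor_traits) / len(neighbor_traits)


def neighborhood_profile(
    dist: PatristicMatrix,
    metadata: pd.DataFrame | Mapping[str, object],
    *,
    k: int = 6,
    trait: str | None = None,
    statistic: Callable[[object, Sequence[object]], float] = fraction_sharing_trait,
) -> list[NeighborhoodProfile]:
    """Polymorphism and trait specificity of every host's k nearest strains.

    ``metadata`` maps host id to a trait value, either directly or as a
    DataFrame indexed by host id with ``trait`` naming the column.  Ties at
    the k-th neighbor are broken toward the lexicographically smaller id,
    so the profile is deterministic and independent of taxon input order.
    The ``statistic`` is pluggable; the default is the fraction of the k
    neighbors whose trait equals the focal host's value.
    """
    n = len(dist.taxon_ids)
    if not (0 < k < n):
        raise ValueError(f"k={k} must satisfy 0 < k < {n} taxa")
    if isinstance(metadata, pd.DataFrame):
        if trait is None:
            raise ValueError("trait column name required with a DataFrame")
        traits = metadata[trait].to_dict()
    else:
        traits = dict(metadata)
    missing = [t for t in dist.taxon_ids if t not in traits]
    if missing:
        raise KeyError(f"hosts absent from metadata: {missing}")

    order = sorted(range(n), key=lambda i: dist.taxon_ids[i])
    out = []
    for i in range(n):
        ranked = sorted(
            (j for j in order if j != i),
            key=lambda j: (dist.distances[i, j], dist.taxon_ids[j]),
        )
        nearest = ranked[:k]
        ids = tuple(dist.taxon_ids[j] for j in nearest)
        poly = float(np.mean([dist.distances[i, j] for j in nearest]))
        spec = float(
            statistic(traits[dist.taxon_ids[i]], [traits[t] for t in ids])
        )
        out.append(NeighborhoodProfile(dist.taxon_ids[i], poly, spec, ids))
    return out


@dataclass
class AssociationReport:
    """Kruskal-Wallis H with pairwise Mann-Whitney post-hocs."""

    h_statistic: float
    p_value: float
    group_sizes: dict[str, int]
    pairwise: pd.DataFrame  # columns: class_a, class_b, u_statistic, p_raw, p_bh


def class_association_test(
    values: Sequence[float],
    classes: Sequence[object],
) -> AssociationReport:
    """Test whether a numeric quantity differs across >= 2 host classes.

    Runs a tie-corrected Kruskal-Wallis test over all classes, then every
    pairwise two-sided Mann-Whitney U test; post-hoc p-values are reported
    raw and Benjamini-Hochberg adjusted.
    """
    values = np.asarray(values, dtype=float)
    classes = list(classes)
    if len(values) != len(classes):
        raise ValueError("values and classes must be the same length")
    groups: dict[object, np.ndarray] = {}
    for label in dict.fromkeys(classes):  # preserve first-seen order
        groups[label] = values[[c == label for c in classes]]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty classes")
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("every class must be non-empty")

    if np.ptp(values) == 0:  # all values identical: no rank variance
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups.values())

    rows = []
    labels = list(groups)
    for a, b in itertools.combinations(labels, 2):
        u, p_raw = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"class_a": str(a), "class_b": str(b), "u_statistic": u, "p_raw": p_raw})
    pairwise = pd.DataFrame(rows)
    if not pairwise.empty:
        pairwise["p_bh"] = multipletests(pairwise["p_raw"], method="fdr_bh")[1]
    return AssociationReport(
        h_statistic=float(h),
        p_value=float(p),
        group_sizes={str(k): len(v) for k, v in groups.items()},
        pairwise=pairwise,
    )


def read_host_metadata(path: str | Path, *, delimiter: str = "\t") -> pd.DataFrame:
    """Host metadata table (host_id, clade, pGV, biome, location, ...)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    first = df.columns[0]
    if df[first].duplicated().any():
        dups = df.loc[df[first].duplicated(), first].tolist()
        raise ValueError(f"duplicate host ids in metadata: {dups}")
    return df.set_index(first)
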