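"""All-vs-all protein similarity search.

Pairwise local alignments (Smith-Waterman via Biopython's
:class:`PairwiseAligner`, BLOSUM62, gap open 11 / extend 1) between every
pair of proteins from different genomes.  Identity is defined as matched
columns over aligned columns and coverage relative to the shorter protein,
matching the downstream best-bidirectional-hit cutoffs (>20% identity,
>50% coverage of the shortest protein).

A shared-k-mer prefilter skips pairs that cannot plausibly align (two
unrelated proteins share essentially no 6-mers), which keeps the all-vs-all
tractable at collection scale without changing results for related pairs.
A loader for precomputed tabular hits (e.g. from an external search tool)
is provided for exact replication of external pipelines.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genomes import Proteome

__all__ = ["SimilarityHit", "all_vs_all_similarity", "load_similarity_table"]

GeneKey = tuple[str, str]  # (genome_id, gene_id)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYBZX")


@dataclass(frozen=True)
class SimilarityHit:
    """One directed local-alignment hit between proteins of two genomes."""

    query: GeneKey
    target: GeneKey
    identity: float  # % matched columns / aligned columns
    coverage_shortest: float  # % of the shorter protein spanned by the alignment
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if not (0.0 <= self.coverage_shortest <= 100.0):
            raise ValueError(f"coverage {self.coverage_shortest} outside [0, 100]")
        if self.query == self.target:
            raise ValueError("self-hits are not retained")


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    matrix = substitution_matrices.load("BLOSUM62")
    arr = np.array(matrix)
    # ambiguous residues contribute nothing to the score
    for sym in "XBZ":
        i = matrix.alphabet.index(sym)
        arr[i, :] = 0.0
        arr[:, i] = 0.0
    aligner.substitution_matrix = substitution_matrices.Array(
        alphabet=matrix.alphabet, dims=2, data=arr
    )
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _validate_protein(genome_id: str, gene_id: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"{genome_id}/{gene_id}: empty protein sequence")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"{genome_id}/{gene_id}: non-amino-acid symbols {sorted(bad)}")


def align_pair(
    seq_a: str, seq_b: str, aligner: Align.PairwiseAligner
) -> tuple[float, float, float] | None:
    """(identity %, coverage-of-shortest %, score) of the best local alignment.

    Returns None when no positive-scoring local alignment exists.
    """
    alignments = aligner.align(seq_a, seq_b)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    best = alignments[0]
    counts = best.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    if aligned_cols == 0:
        return None
    identity = 100.0 * counts.identities / aligned_cols
    span_a = best.coordinates[0][-1] - best.coordinates[0][0]
    span_b = best.coordinates[1][-1] - best.coordinates[1][0]
    short_len = min(len(seq_a), len(seq_b))
    coverage = 100.0 * min(span_a if len(seq_a) <= len(seq_b) else span_b, short_len) / short_len
    return identity, coverage, float(alignments.score)


def all_vs_all_similarity(
    proteomes: Sequence[Proteome],
    *,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    prefilter_k: int | None = 6,
) -> list[SimilarityHit]:
    """Local-alignment hits between every inter-genome protein pair.

    Each unordered pair is aligned once and reported in both directions
    (identity, coverage and score are symmetric).  ``prefilter_k`` sets the
    k-mer length of the shared-word prefilter; ``None`` disables it and
    aligns every pair.
    """
    aligner = _make_aligner(gap_open, gap_extend)
    entries: list[tuple[GeneKey, str]] = []
    for proteome in proteomes:
        for gene in proteome:
            _validate_protein(gene.genome_id, gene.gene_id, gene.protein)
            entries.append((gene.key, gene.protein))

    if prefilter_k is not None:
        candidate_pairs = _prefilter_pairs(entries, prefilter_k)
    else:
        candidate_pairs = {
            (i, j)
            for i, j in itertools.combinations(range(len(entries)), 2)
            if entries[i][0][0] != entries[j][0][0]
        }

    hits: list[SimilarityHit] = []
    for i, j in sorted(candidate_pairs):
        (key_a, seq_a), (key_b, seq_b) = entries[i], entries[j]
        result = align_pair(seq_a, seq_b, aligner)
        if result is None:
            continue
        identity, coverage, score = result
        hits.append(SimilarityHit(key_a, key_b, identity, coverage, score))
        hits.append(SimilarityHit(key_b, key_a, identity, coverage, score))
    return hits


def _prefilter_pairs(
    entries: list[tuple[GeneKey, str]], k: int
) -> set[tuple[int, int]]:
    """Inter-genome index pairs sharing at least one k-mer."""
    buckets: dict[str, list[int]] = defaultdict(list)
    for idx, (_, seq) in enumerate(entries):
        for kmer in _kmers(seq, k):
            buckets[kmer].append(idx)
    pairs: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for i, j in itertools.combinations(members, 2):
            if entries[i][0][0] != entries[j][0][0]:  # different genomes only
                pairs.add((i, j) if i < j else (j, i))
    return pairs


def load_similarity_table(
    path: str | Path,
    proteomes: Sequence[Proteome],
    *,
    delimiter: str = "\t",
) -> list[SimilarityHit]:
    """Load precomputed tabular hits (query, target, pident, alnlen, qlen, tlen[, bits]).

    Gene ids must be unique across the collection; genome attribution is
    recovered from ``proteomes``.  Coverage of the shortest protein is
    derived as ``alnlen / min(qlen, tlen)``; the score is the ``bits``
    column when present, else the alignment length.
    """
    gene_to_genome: dict[str, str] = {}
    for proteome in proteomes:
        for gene in proteome:
            if gene.gene_id in gene_to_genome:
                raise ValueError(
                    f"gene id {gene.gene_id!r} is not unique across genomes; "
                    "tabular hits cannot be attributed"
                )
            gene_to_genome[gene.gene_id] = gene.genome_id

    df = pd.read_csv(path, sep=delimiter)
    required = {"query", "target", "pident", "alnlen", "qlen", "tlen"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        q, t = str(row.query), str(row.target)
        if q == t:
            continue
        if q not in gene_to_genome or t not in gene_to_genome:
            unknown = q if q not in gene_to_genome else t
            raise ValueError(f"{path}: hit references unknown gene {unknown!r}")
        pident = float(row.pident)
        identity = pident * 100.0 if pident <= 1.0 else pident
        coverage = 100.0 * float(row.alnlen) / min(float(row.qlen), float(row.tlen))
        score = float(getattr(row, "bits", row.alnlen))
        hits.append(
            SimilarityHit(
                (gene_to_genome[q], q),
                (gene_to_genome[t], t),
                identity,
                min(coverage, 100.0),
                score,
            )
        )
    return hits
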