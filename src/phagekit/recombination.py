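"""Core-gene divergence, recombination mapping and association tests.

Per-family divergence is measured as the mean pairwise protein identity
over a taxon subset (by default all taxa minus a declared outgroup);
families below a threshold (default 95%) are "divergent".  Predicted
homologous-recombination segments on the concatenated codon alignment
(GFF, 1-based inclusive) are mapped onto per-gene intervals of a
coordinate map built from the reference gene order, and per-family event
counts are related to divergence and to dN/dS with a Mann-Whitney
comparison and Spearman rank correlations.
"""

from __future__ import annotations

import enum
import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FamilyAlignment",
    "GeneEvoStats",
    "family_alignment_stats",
    "GeneCoordinateMap",
    "concat_gene_coordinates",
    "BranchType",
    "RecombinationEvent",
    "parse_recombination_gff",
    "write_recombination_gff",
    "map_events_to_genes",
    "AssociationResult",
    "divergence_association",
    "read_family_alignment",
    "write_family_alignment",
]


@dataclass
class FamilyAlignment:
    """Aligned members of one gene family (proteins, optionally codons)."""

    family_id: str
    proteins: dict[str, str]
    codons: dict[str, str] | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.proteins.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.family_id}: unequal aligned protein lengths")
        if self.codons is not None:
            if set(self.codons) != set(self.proteins):
                raise ValueError(f"{self.family_id}: protein and codon taxa differ")
            clen = {len(s) for s in self.codons.values()}
            if len(clen) > 1:
                raise ValueError(f"{self.family_id}: unequal aligned codon lengths")
            if clen and lengths and next(iter(clen)) != 3 * next(iter(lengths)):
                raise ValueError(
                    f"{self.family_id}: codon alignment length must be 3x the protein length"
                )

    @property
    def aligned_length(self) -> int:
        return len(next(iter(self.proteins.values()))) if self.proteins else 0

    @property
    def codon_length(self) -> int:
        if self.codons is None:
            raise ValueError(f"{self.family_id}: no codon alignment")
        return len(next(iter(self.codons.values())))


@dataclass
class GeneEvoStats:
    """Per-family evolutionary summary used by the association tests."""

    family_id: str
    mean_pairwise_identity: float  # %
    is_divergent: bool
    recomb_event_count: int = 0
    dnds: float = math.nan

    def __post_init__(self) -> None:
        if self.recomb_event_count < 0:
            raise ValueError("recomb_event_count must be >= 0")


def pairwise_identity(seq_a: str, seq_b: str) -> float | None:
    """% identical columns among columns where both sequences are non-gap.

    None when the pair shares no mutually non-gap column.
    """
    both = [(a, b) for a, b in zip(seq_a, seq_b) if a != "-" and b != "-"]
    if not both:
        return None
    matches = sum(a == b for a, b in both)
    return 100.0 * matches / len(both)


def family_alignment_stats(
    aln: FamilyAlignment,
    taxa: Sequence[str] | None = None,
    divergence_threshold: float = 95.0,
) -> GeneEvoStats:
    """Mean pairwise identity of a family over a taxon subset.

    The mean runs over all unordered pairs; pairs with zero mutually
    non-gap columns are excluded with a warning.  ``is_divergent`` is True
    when the mean falls below ``divergence_threshold``.
    """
    subset = list(taxa) if taxa is not None else sorted(aln.proteins)
    missing = [t for t in subset if t not in aln.proteins]
    if missing:
        raise KeyError(f"{aln.family_id}: taxa not in alignment: {missing}")
    if len(subset) < 2:
        raise ValueError(f"{aln.family_id}: need at least 2 taxa")
    identities = []
    for a, b in itertools.combinations(subset, 2):
        ident = pairwise_identity(aln.proteins[a], aln.proteins[b])
        if ident is None:
            warnings.warn(
                f"{aln.family_id}: pair ({a}, {b}) has no mutually non-gap column; excluded"
            )
        else:
            identities.append(ident)
    if not identities:
        raise ValueError(f"{aln.family_id}: every pair was gap-disjoint")
    mean_ident = float(np.mean(identities))
    return GeneEvoStats(
        family_id=aln.family_id,
        mean_pairwise_identity=mean_ident,
        is_divergent=mean_ident < divergence_threshold,
    )


# ---------------------------------------------------------------------------
# Concatenated-alignment coordinates
# ---------------------------------------------------------------------------

@dataclass
class GeneCoordinateMap:
    """Per-family [start, end) column intervals on the concatenated alignment."""

    family_ids: list[str]
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.family_ids) != len(self.intervals):
            raise ValueError("family_ids and intervals length mismatch")
        cursor = 0
        for fam, (start, end) in zip(self.family_ids, self.intervals):
            if start != cursor or end <= start:
                raise ValueError(
                    f"intervals must be contiguous and non-empty (family {fam!r})"
                )
            cursor = end

    @property
    def total_length(self) -> int:
        return self.intervals[-1][1] if self.intervals else 0

    def interval(self, family_id: str) -> tuple[int, int]:
        return self.intervals[self.family_ids.index(family_id)]


def concat_gene_coordinates(
    families: Sequence[tuple[str, int]],
) -> GeneCoordinateMap:
    """Coordinate map from (family_id, codon-alignment length) in reference order."""
    ids, intervals = [], []
    cursor = 0
    for family_id, length in families:
        if length <= 0 or length % 3 != 0:
            raise ValueError(
                f"family {family_id!r}: length {length} must be a positive multiple of 3"
            )
        ids.append(family_id)
        intervals.append((cursor, cursor + length))
        cursor += length
    return GeneCoordinateMap(ids, intervals)


# ---------------------------------------------------------------------------
# Recombination events
# ---------------------------------------------------------------------------

class BranchType(enum.Enum):
    INTERNAL = "internal"
    TERMINAL = "terminal"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class RecombinationEvent:
    """One predicted recombination segment, 0-based half-open columns."""

    start: int
    end: int
    branch_type: BranchType = BranchType.UNKNOWN
    affected_taxa: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


def gff_to_internal(start: int, end: int) -> tuple[int, int]:
    """GFF 1-based inclusive -> 0-based half-open."""
    return start - 1, end


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> GFF 1-based inclusive."""
    return start + 1, end


def parse_recombination_gff(path: str | Path) -> list[RecombinationEvent]:
    """Parse a recombination-predictions GFF (Gubbins dialect).

    Coordinates are on the concatenated alignment, 1-based inclusive, and
    are converted to the internal 0-based half-open convention.  The
    ``taxa`` attribute (when present) gives the affected leaves; the
    branch type is inferred from it (several taxa -> internal branch, one
    -> terminal, absent -> unknown).
    """
    path = Path(path)
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end or start < 1:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}..{end}")
            taxa = frozenset()
            if len(fields) >= 9:
                attrs = _parse_gff_attributes(fields[8])
                if "taxa" in attrs:
                    taxa = frozenset(attrs["taxa"].split())
            if len(taxa) > 1:
                branch_type = BranchType.INTERNAL
            elif len(taxa) == 1:
                branch_type = BranchType.TERMINAL
            else:
                branch_type = BranchType.UNKNOWN
            s0, e0 = gff_to_internal(start, end)
            events.append(RecombinationEvent(s0, e0, branch_type, taxa))
    return events


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        key, value = item.split("=", 1)
        attrs[key.strip()] = value.strip().strip('"')
    return attrs


def write_recombination_gff(
    events: Iterable[RecombinationEvent], path: str | Path, source: str = "phagekit"
) -> None:
    """Emit events in the same GFF dialect the parser reads (round-trip exact)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ev in events:
            start, end = internal_to_gff(ev.start, ev.end)
            attrs = f'taxa="{" ".join(sorted(ev.affected_taxa))}";' if ev.affected_taxa else ""
            fh.write(
                "\t".join(
                    ["SEQUENCE", source, "recombination", str(start), str(end), ".", ".", ".", attrs]
                )
                + "\n"
            )


def map_events_to_genes(
    events: Sequence[RecombinationEvent],
    coords: GeneCoordinateMap,
) -> tuple[pd.Series, int]:
    """Per-family event counts by >= 1-column interval overlap.

    One event may overlap (and increment) several families.  Returns the
    counts as a family-indexed Series plus the number of families with at
    least one event.  Events outside [0, total_length) raise.
    """
    tree = IntervalTree()
    for family_id, (start, end) in zip(coords.family_ids, coords.intervals):
        tree[start:end] = family_id
    counts = pd.Series(0, index=coords.family_ids, dtype=int)
    total = coords.total_length
    for ev in events:
        if ev.start < 0 or ev.end > total:
            raise ValueError(
                f"event [{ev.start}, {ev.end}) outside the alignment [0, {total})"
            )
        for hit in tree.overlap(ev.start, ev.end):
            counts[hit.data] += 1
    return counts, int((counts > 0).sum())


# ---------------------------------------------------------------------------
# Divergence / recombination / dN/dS association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Divergence vs recombination vs dN/dS association report."""

    mw_u: float  # recomb counts, divergent vs non-divergent families
    mw_p: float
    spearman_identity_recomb: tuple[float, float]  # (rho, p)
    spearman_identity_dnds: tuple[float, float]
    p_bh: dict[str, float]
    n_divergent: int
    n_non_divergent: int
    warnings: list[str] = field(default_factory=list)


def divergence_association(stats_list: Sequence[GeneEvoStats]) -> AssociationResult:
    """Association of core-gene divergence with recombination and with dN/dS.

    (i) two-sided Mann-Whitney U comparing recombination event counts
    between divergent and non-divergent families; (ii) Spearman rank
    correlations of mean pairwise identity against event counts and
    against dN/dS.  P-values are reported raw and Benjamini-Hochberg
    adjusted.  Families with undefined dN/dS are excluded from that
    correlation only.
    """
    if len(stats_list) < 5:
        raise ValueError("need at least 5 families with complete fields")
    notes: list[str] = []
    identity = np.array([s.mean_pairwise_identity for s in stats_list])
    counts = np.array([s.recomb_event_count for s in stats_list], dtype=float)
    divergent = np.array([s.is_divergent for s in stats_list])

    if divergent.all() or not divergent.any():
        notes.append("one divergence group is empty; class comparison skipped")
        mw_u, mw_p = math.nan, math.nan
    elif np.ptp(counts) == 0:
        mw_u, mw_p = float(divergent.sum() * (~divergent).sum()) / 2.0, 1.0
    else:
        mw_u, mw_p = stats.mannwhitneyu(
            counts[divergent], counts[~divergent], alternative="two-sided"
        )

    rho_rec, p_rec = _spearman_or_flag(identity, counts, "recomb_event_count", notes)

    dnds = np.array([s.dnds for s in stats_list], dtype=float)
    usable = ~np.isnan(dnds)
    if usable.sum() >= 3:
        rho_dnds, p_dnds = _spearman_or_flag(
            identity[usable], dnds[usable], "dnds", notes
        )
    else:
        notes.append("fewer than 3 families with defined dN/dS; correlation skipped")
        rho_dnds, p_dnds = math.nan, math.nan

    raw = {"mw_recomb": mw_p, "spearman_recomb": p_rec, "spearman_dnds": p_dnds}
    keys = [k for k, v in raw.items() if not math.isnan(v)]
    adjusted = dict.fromkeys(raw, math.nan)
    if keys:
        adj = multipletests([raw[k] for k in keys], method="fdr_bh")[1]
        adjusted.update(dict(zip(keys, adj)))

    return AssociationResult(
        mw_u=float(mw_u),
        mw_p=float(mw_p),
        spearman_identity_recomb=(float(rho_rec), float(p_rec)),
        spearman_identity_dnds=(float(rho_dnds), float(p_dnds)),
        p_bh=adjusted,
        n_divergent=int(divergent.sum()),
        n_non_divergent=int((~divergent).sum()),
        warnings=notes,
    )


def _spearman_or_flag(
    x: np.ndarray, y: np.ndarray, label: str, notes: list[str]
) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        notes.append(f"{label} (or identity) is constant; correlation undefined")
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Alignment I/O (FASTA)
# ---------------------------------------------------------------------------

def read_family_alignment(
    protein_fasta: str | Path | None,
    codon_fasta: str | Path | None = None,
    family_id: str | None = None,
) -> FamilyAlignment:
    """Family alignment from aligned FASTA file(s).

    When only a codon FASTA is given, the protein alignment is derived by
    codon translation (gap codons become gap columns).
    """
    from Bio import SeqIO
    from Bio.Seq import Seq

    if protein_fasta is None and codon_fasta is None:
        raise ValueError("need at least one of protein_fasta / codon_fasta")
    codons = None
    if codon_fasta is not None:
        with open(codon_fasta) as fh:
            codons = {r.id: str(r.seq).upper() for r in SeqIO.parse(fh, "fasta")}
    if protein_fasta is not None:
        with open(protein_fasta) as fh:
            proteins = {r.id: str(r.seq).upper() for r in SeqIO.parse(fh, "fasta")}
    else:
        proteins = {}
        for name, seq in codons.items():  # type: ignore[union-attr]
            aa = []
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                aa.append("-" if "-" in codon else str(Seq(codon).translate()))
            proteins[name] = "".join(aa)
    fid = family_id or (Path(codon_fasta or protein_fasta).stem)
    return FamilyAlignment(fid, proteins, codons)


def write_family_alignment(aln: FamilyAlignment, codon_fasta: str | Path) -> None:
    if aln.codons is None:
        raise ValueError(f"{aln.family_id}: no codon alignment to write")
    with open(codon_fasta, "w") as fh:
        for name in sorted(aln.codons):
            fh.write(f">{name}\n{aln.codons[name]}\n")
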