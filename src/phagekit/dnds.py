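"""Alignment-wide counting dN/dS (Nei-Gojobori 1986 with Jukes-Cantor).

An explicit counting-method estimator for codon alignments: gap-rich codon
columns are trimmed, synonymous and nonsynonymous sites and differences
are counted for every unordered sequence pair (averaging over all minimal
mutational pathways between differing codons), pooled, and converted to
distances with the Jukes-Cantor correction.  The ratio is flagged
undefined when no synonymous change is observed (dS = 0).

Site counting follows the standard conventions: each codon contributes
exactly 3 sites, single-step neighbors that are stop codons count as
nonsynonymous, and pathway steps are compared through the translation
(a step between two stop codons counts as synonymous).  A parser for
external per-family dN/dS tables (e.g. from a codon-model fit) is also
provided; the counting estimator is a stand-in, not a codon model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio.Data import CodonTable

__all__ = ["DnDsResult", "counting_dnds", "load_dnds_table"]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = ("A", "T", "C", "G")
GAP_CODON = "---"


def _translate(codon: str) -> str | None:
    """Amino acid of a codon; None for stop codons."""
    return _TABLE.forward_table.get(codon)


@dataclass(frozen=True)
class DnDsResult:
    dn: float
    ds: float
    dnds: float  # NaN when undefined
    n_codons_used: int
    undefined_reason: str | None = None

    @property
    def is_defined(self) -> bool:
        return self.undefined_reason is None


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon, summing to 3."""
    aa = _translate(codon)
    if aa is None:
        raise ValueError(f"in-frame stop codon {codon}")
    syn = nonsyn = 0
    for pos, base in enumerate(codon):
        for other in _BASES:
            if other == base:
                continue
            neighbor = codon[:pos] + other + codon[pos + 1 :]
            if _translate(neighbor) == aa:
                syn += 1
            else:
                nonsyn += 1  # includes mutations to stop codons
    total = syn + nonsyn
    return 3.0 * syn / total, 3.0 * nonsyn / total


def _codon_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over minimal pathways."""
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn = nonsyn = 0.0
    n_paths = math.factorial(len(diff_pos))
    for order in itertools.permutations(diff_pos):
        current = codon1
        for pos in order:
            step = current[:pos] + codon2[pos] + current[pos + 1 :]
            if _translate(current) == _translate(step):
                syn += 1.0 / n_paths
            else:
                nonsyn += 1.0 / n_paths
            current = step
    return syn, nonsyn


def _trim_gap_columns(
    codons: Mapping[str, list[str]], gap_col_threshold: float
) -> list[int]:
    """Indices of codon columns whose gap fraction is below the threshold."""
    n_seq = len(codons)
    n_col = len(next(iter(codons.values())))
    kept = []
    for col in range(n_col):
        gaps = sum(1 for seq in codons.values() if "-" in seq[col])
        if 100.0 * gaps / n_seq < gap_col_threshold:
            kept.append(col)
    return kept


def counting_dnds(
    codon_sequences: Mapping[str, str],
    gap_col_threshold: float = 20.0,
) -> DnDsResult:
    """Single alignment-wide dN/dS of a codon alignment by the counting method.

    ``codon_sequences`` maps taxon to an aligned in-frame nucleotide
    sequence (length a multiple of 3; gaps as ``-``).  Codon columns with
    >= ``gap_col_threshold`` % gapped codons are removed before counting.
    Sites and differences are pooled over all unordered pairs; in-frame
    stop codons raise, naming the sequence and codon position.
    """
    if len(codon_sequences) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in codon_sequences.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    (length,) = lengths
    if length % 3 != 0:
        raise ValueError(f"aligned length {length} is not a multiple of 3")

    codons = {
        name: [seq[i : i + 3].upper() for i in range(0, length, 3)]
        for name, seq in codon_sequences.items()
    }
    for name, seq_codons in codons.items():
        for pos, codon in enumerate(seq_codons):
            if "-" not in codon and _translate(codon) is None:
                raise ValueError(
                    f"in-frame stop codon {codon} in sequence {name!r} at codon {pos + 1}"
                )

    kept = _trim_gap_columns(codons, gap_col_threshold)

    total_s_sites = total_n_sites = 0.0
    total_s_diff = total_n_diff = 0.0
    n_pairs = 0
    for name1, name2 in itertools.combinations(sorted(codons), 2):
        s_sites = [0.0, 0.0]
        n_sites = [0.0, 0.0]
        s_diff = n_diff = 0.0
        for col in kept:
            c1, c2 = codons[name1][col], codons[name2][col]
            if "-" in c1 or "-" in c2:
                continue
            for k, c in enumerate((c1, c2)):
                s, n = _codon_sites(c)
                s_sites[k] += s
                n_sites[k] += n
            ds_, dn_ = _codon_differences(c1, c2)
            s_diff += ds_
            n_diff += dn_
        total_s_sites += (s_sites[0] + s_sites[1]) / 2.0
        total_n_sites += (n_sites[0] + n_sites[1]) / 2.0
        total_s_diff += s_diff
        total_n_diff += n_diff
        n_pairs += 1

    if total_s_sites == 0 or total_n_sites == 0:
        return DnDsResult(
            math.nan, math.nan, math.nan, len(kept), "no usable codon columns"
        )
    ps = total_s_diff / total_s_sites
    pn = total_n_diff / total_n_sites
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    if math.isnan(ds) or math.isnan(dn):
        return DnDsResult(dn, ds, math.nan, len(kept), "proportion too large for JC correction")
    if ds == 0.0:
        reason = None if dn == 0.0 else "dS = 0"
        return DnDsResult(dn, ds, math.nan, len(kept), reason or "dN = dS = 0")
    return DnDsResult(dn, ds, dn / ds, len(kept))


def _jukes_cantor(p: float) -> float:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def load_dnds_table(
    path: str | Path, *, delimiter: str = "\t"
) -> dict[str, float]:
    """Per-family dN/dS values from an external estimator (family_id, dnds)."""
    df = pd.read_csv(path, sep=delimiter)
    required = {"family_id", "dnds"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    if df["family_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate family ids")
    return dict(zip(df["family_id"].astype(str), df["dnds"].astype(float)))
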