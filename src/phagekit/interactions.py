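"""Cross-infection matrix scoring.

A phage collection assayed against a panel of bacterial hosts yields a
phage x host grid of titers (PFU/ml) plus categorical non-infection
outcomes.  This module reads such grids and scores them two ways:

* per-phage specialization via the Paired Difference Index (PDI), which
  contrasts the highest log10 titer a phage achieves on any host with the
  titers it achieves on every other host;
* per-host susceptibility, defined as ``1 - PDI`` computed host-wise, with
  a deterministic three-class partition (resistant / slightly susceptible /
  susceptible).

Non-infection cells (resistant, resistant-but-impaired, not assessed) can
either be floored at the detection limit (log-score 0) or dropped from the
sum entirely; both conventions are first-class policies.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "EntryState",
    "TiterEntry",
    "TiterMatrix",
    "NullHandling",
    "ScoringPolicy",
    "Axis",
    "HostClass",
    "SpecificityResult",
    "SusceptibilityResult",
    "read_titer_matrix",
    "write_titer_matrix",
    "pdi_from_entries",
    "compute_pdi",
    "susceptibility_scores",
    "classify_hosts",
]


class EntryState(enum.Enum):
    """Outcome category of one phage x host assay cell."""

    TITER = "titer"
    RESISTANT = "resistant"
    IMPAIRED = "impaired"  # clearing zone but no viable progeny
    NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class TiterEntry:
    """One assay cell: either a positive titer or a categorical state."""

    state: EntryState
    value: float | None = None

    def __post_init__(self) -> None:
        if self.state is EntryState.TITER:
            if self.value is None or not (self.value > 0):
                raise ValueError(
                    f"TITER entries need a strictly positive PFU/ml value, got {self.value!r}"
                )
        elif self.value is not None:
            raise ValueError(f"state {self.state.name} must not carry a titer value")

    @property
    def is_infection(self) -> bool:
        return self.state is EntryState.TITER


@dataclass
class TiterMatrix:
    """Phage x host grid of :class:`TiterEntry` (phages = rows)."""

    phage_ids: list[str]
    host_ids: list[str]
    entries: list[list[TiterEntry]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.phage_ids)) != len(self.phage_ids):
            raise ValueError("duplicate phage ids")
        if len(set(self.host_ids)) != len(self.host_ids):
            raise ValueError("duplicate host ids")
        if len(self.entries) != len(self.phage_ids):
            raise ValueError("row count does not match number of phage ids")
        for row in self.entries:
            if len(row) != len(self.host_ids):
                raise ValueError("column count does not match number of host ids")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.phage_ids), len(self.host_ids))

    def entry(self, phage_id: str, host_id: str) -> TiterEntry:
        return self.entries[self.phage_ids.index(phage_id)][self.host_ids.index(host_id)]

    def row(self, phage_id: str) -> list[TiterEntry]:
        return list(self.entries[self.phage_ids.index(phage_id)])

    def column(self, host_id: str) -> list[TiterEntry]:
        j = self.host_ids.index(host_id)
        return [row[j] for row in self.entries]

    def to_dataframe(self, tokens: Mapping[EntryState, str] | None = None) -> pd.DataFrame:
        """Plain ordered-matrix export: numeric titers, tokens elsewhere."""
        tokens = tokens or DEFAULT_STATE_TOKENS
        data = [
            [e.value if e.is_infection else tokens[e.state] for e in row]
            for row in self.entries
        ]
        return pd.DataFrame(data, index=self.phage_ids, columns=self.host_ids)


class NullHandling(enum.Enum):
    """How non-infection cells enter a PDI sum."""

    FLOOR = "floor"  # scored at the detection limit (log-score 0 by default)
    DROP = "drop"  # excluded from both the sum and the denominator


@dataclass(frozen=True)
class ScoringPolicy:
    """Conventions for turning an assay row into log-titer scores.

    ``floor_value`` is the detection limit in PFU/ml; titers are clamped to
    it from below.  With ``subtract_floor`` (default) scores are log titers
    relative to the detection limit, so non-infections score exactly 0;
    without it, scores are absolute log10 titers and a non-infection keeps
    the nonzero share ``log10(floor_value)`` under normalization (relevant
    when the assay's detection limit is above 1 PFU/ml).  With
    ``normalize`` on, scores are divided by the row maximum so the PDI is
    bounded in [0, 1].  The log base is fixed at 10 (titers are reported as
    powers of ten).
    """

    null_handling: NullHandling = NullHandling.FLOOR
    normalize: bool = True
    floor_value: float = 1.0
    subtract_floor: bool = True

    log_base: int = field(default=10, init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.floor_value > 0:
            raise ValueError("floor_value must be > 0")


class Axis(enum.Enum):
    PHAGE = "phage"
    HOST = "host"


class HostClass(enum.Enum):
    RESISTANT = "resistant"
    SLIGHTLY_SUSCEPTIBLE = "slightly_susceptible"
    SUSCEPTIBLE = "susceptible"


@dataclass(frozen=True)
class SpecificityResult:
    entity_id: str
    pdi: float  # NaN when undefined; see undefined_reason
    n_counterparts_used: int
    undefined_reason: str | None = None

    @property
    def is_defined(self) -> bool:
        return self.undefined_reason is None


@dataclass(frozen=True)
class SusceptibilityResult:
    host_id: str
    score: float
    cls: HostClass | None = None
    n_counterparts_used: int = 0
    undefined_reason: str | None = None

    @property
    def is_defined(self) -> bool:
        return self.undefined_reason is None


DEFAULT_STATE_TOKENS: dict[EntryState, str] = {
    EntryState.RESISTANT: "R",
    EntryState.IMPAIRED: "I",
    EntryState.NOT_ASSESSED: "NA",
}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_titer_matrix(
    path: str | Path,
    *,
    delimiter: str = "\t",
    tokens: Mapping[str, EntryState] | None = None,
    phages_as_rows: bool = True,
    zero_as_resistant: bool = False,
    provenance: str | None = None,
) -> TiterMatrix:
    """Read a delimited phage x host titer table.

    The first row holds host ids and the first column phage ids (swap the
    axes with ``phages_as_rows=False``).  Cells are positive PFU/ml numbers
    or categorical tokens (default ``R`` resistant, ``I`` impaired, ``NA``
    not assessed).  ``zero_as_resistant`` maps a numeric 0 to the resistant
    state instead of rejecting it.
    """
    token_map = {k.upper(): v for k, v in (tokens or _invert(DEFAULT_STATE_TOKENS)).items()}
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delimiter) if r]
    if len(rows) < 2:
        raise ValueError(f"{path}: need a header row and at least one data row")
    header = [c.strip() for c in rows[0][1:]]
    width = len(rows[0])
    row_ids: list[str] = []
    entries: list[list[TiterEntry]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(row)} fields, expected {width})"
            )
        row_ids.append(row[0].strip())
        entries.append(
            [
                _parse_cell(cell.strip(), token_map, zero_as_resistant, path, lineno)
                for cell in row[1:]
            ]
        )
    if not phages_as_rows:
        entries = [list(col) for col in zip(*entries)]
        row_ids, header = header, row_ids
    return TiterMatrix(
        phage_ids=row_ids,
        host_ids=header,
        entries=entries,
        provenance=provenance if provenance is not None else str(path),
    )


def _invert(d: Mapping[EntryState, str]) -> dict[str, EntryState]:
    return {v: k for k, v in d.items()}


def _parse_cell(
    cell: str,
    token_map: Mapping[str, EntryState],
    zero_as_resistant: bool,
    path: Path,
    lineno: int,
) -> TiterEntry:
    upper = cell.upper()
    if upper in token_map:
        return TiterEntry(state=token_map[upper])
    try:
        value = float(cell)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: unrecognized cell {cell!r}") from exc
    if value == 0 and zero_as_resistant:
        return TiterEntry(state=EntryState.RESISTANT)
    if value <= 0:
        raise ValueError(f"{path}:{lineno}: non-positive titer {cell!r}")
    return TiterEntry(state=EntryState.TITER, value=value)


def write_titer_matrix(
    matrix: TiterMatrix,
    path: str | Path,
    *,
    delimiter: str = "\t",
    tokens: Mapping[EntryState, str] | None = None,
) -> None:
    matrix.to_dataframe(tokens).to_csv(path, sep=delimiter)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _entry_scores(
    entries: Sequence[TiterEntry], policy: ScoringPolicy
) -> tuple[list[float], int]:
    """Log10 scores of a row under a policy; returns (scores, n_used).

    Scores are log10 titers relative to the detection limit,
    ``log10(value / floor_value)`` clamped at 0, so a non-infection (FLOOR
    policy) and a titer at the detection limit both score 0.  Under DROP
    only positive-titer cells contribute.
    """
    floor_log = math.log10(policy.floor_value)
    offset = floor_log if policy.subtract_floor else 0.0
    scores: list[float] = []
    for e in entries:
        if e.is_infection:
            scores.append(max(max(math.log10(e.value), floor_log) - offset, 0.0))
        elif policy.null_handling is NullHandling.FLOOR:
            scores.append(max(floor_log - offset, 0.0))
    return scores, len(scores)


def pdi_from_entries(
    entries: Sequence[TiterEntry], policy: ScoringPolicy = ScoringPolicy()
) -> tuple[float, int, str | None]:
    """PDI of one row of assay cells.

    Returns ``(pdi, n_counterparts_used, undefined_reason)``.  The PDI is
    the mean, over all non-maximal positions, of the difference between the
    highest log-titer score and each other score:

        PDI = sum_{i=2..N} (P_1 - P_i) / (N - 1)

    with scores P sorted in descending order.  Under ``normalize`` the
    scores are first divided by the row maximum, bounding the PDI in
    [0, 1].  A row with no positive titer at all is maximally specialized
    by convention (PDI = 1, zero counterparts used).
    """
    n_infections = sum(e.is_infection for e in entries)
    if n_infections == 0:
        return 1.0, 0, None
    scores, n_used = _entry_scores(entries, policy)
    if n_used < 2:
        return math.nan, n_used, f"only {n_used} usable counterpart(s) under DROP"
    top = max(scores)
    if policy.normalize:
        if top <= 0:
            # every assessed titer sits at the detection limit: no contrast
            return 0.0, n_used, None
        scores = [s / top for s in scores]
        top = 1.0
    pdi = sum(top - s for s in scores) / (n_used - 1)
    return pdi, n_used, None


def compute_pdi(
    matrix: TiterMatrix,
    axis: Axis = Axis.PHAGE,
    policy: ScoringPolicy = ScoringPolicy(),
) -> list[SpecificityResult]:
    """Per-phage (or per-host) Paired Difference Index.

    Requires at least two counterparts on the chosen axis.  Entities whose
    PDI is undefined under the DROP policy (fewer than two positive titers)
    are flagged via ``undefined_reason`` rather than silently NaN.
    """
    if axis is Axis.PHAGE:
        ids, rows = matrix.phage_ids, matrix.entries
    else:
        ids = matrix.host_ids
        rows = [[r[j] for r in matrix.entries] for j in range(len(matrix.host_ids))]
    if rows and len(rows[0]) < 2:
        raise ValueError(f"need at least 2 counterparts on axis {axis.name}")
    out = []
    for entity_id, row in zip(ids, rows):
        pdi, n_used, reason = pdi_from_entries(row, policy)
        out.append(SpecificityResult(entity_id, pdi, n_used, reason))
    return out


def susceptibility_scores(
    matrix: TiterMatrix, policy: ScoringPolicy = ScoringPolicy()
) -> list[SusceptibilityResult]:
    """Host susceptibility scores, ``1 - PDI_host``.

    A host never productively infected scores exactly 0 (the resistant
    class); a host exploited identically by every phage scores 1.
    """
    out = []
    for res in compute_pdi(matrix, Axis.HOST, policy):
        if not res.is_defined:
            out.append(
                SusceptibilityResult(
                    res.entity_id,
                    math.nan,
                    None,
                    res.n_counterparts_used,
                    res.undefined_reason,
                )
            )
        else:
            out.append(
                SusceptibilityResult(
                    res.entity_id, 1.0 - res.pdi, None, res.n_counterparts_used
                )
            )
    return out


def classify_host_score(score: float) -> HostClass:
    """Three-class partition of a susceptibility score.

    0 -> resistant; (0, 0.5) -> slightly susceptible; >= 0.5 -> susceptible
    (boundary inclusive).
    """
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"susceptibility score {score} outside [0, 1]")
    if score == 0.0:
        return HostClass.RESISTANT
    if score < 0.5:
        return HostClass.SLIGHTLY_SUSCEPTIBLE
    return HostClass.SUSCEPTIBLE


def classify_hosts(
    results: Iterable[SusceptibilityResult],
) -> list[SusceptibilityResult]:
    """Fill the class field of susceptibility results (undefined stay None)."""
    out = []
    for res in results:
        if not res.is_defined:
            out.append(res)
        else:
            out.append(replace(res, cls=classify_host_score(res.score)))
    return out


def results_to_dataframe(
    results: Iterable[SpecificityResult | SusceptibilityResult],
) -> pd.DataFrame:
    """Tabular export of scoring results (one row per entity)."""
    rows = []
    for r in results:
        if isinstance(r, SpecificityResult):
            rows.append(
                {
                    "entity_id": r.entity_id,
                    "pdi": r.pdi,
                    "n_counterparts_used": r.n_counterparts_used,
                    "undefined_reason": r.undefined_reason,
                }
            )
        else:
            rows.append(
                {
                    "entity_id": r.host_id,
                    "score": r.score,
                    "class": r.cls.value if r.cls else None,
                    "n_counterparts_used": r.n_counterparts_used,
                    "undefined_reason": r.undefined_reason,
                }
            )
    return pd.DataFrame(rows)
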