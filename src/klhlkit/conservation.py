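"""Per-column conservation statistics, consensus, penalties, bimodal positions.

A column's *rank* is the frequency of its most common residue among non-gap
rows.  Ranks are binned into conservation classes: ultraconservative at 66% or
higher, conservative in [50%, 66%), weakly conserved in [33%, 50%), and
excluded below 33%.  Each interval is closed at its lower bound, which keeps
the classes disjoint.

Penalties quantify divergence of one sequence from the consensus (or a named
reference row) over a selected column set: every mismatch is charged the
within-column frequency of the target residue, so losing a highly conserved
residue costs more than losing a variable one.  A gap in the scored row counts
as a mismatch; the ``X`` ambiguity residue never matches any target.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GAP, Alignment

logger = logging.getLogger(__name__)

CLASS_ULTRA = "ultra"
CLASS_CONSERVATIVE = "conservative"
CLASS_WEAK = "weak"
CLASS_EXCLUDED = "excluded"

#: Lower bounds of (weak, conservative, ultra) rank classes.
DEFAULT_CLASS_BOUNDS = (0.33, 0.50, 0.66)


def conservation_class(
    rank: float, bounds: tuple[float, float, float] = DEFAULT_CLASS_BOUNDS
) -> str:
    """Conservation class of a rank in [0, 1]; intervals closed at the lower bound."""
    if not 0.0 <= rank <= 1.0:
        raise ValueError(f"rank {rank} outside [0, 1]")
    weak, conservative, ultra = bounds
    if rank >= ultra:
        return CLASS_ULTRA
    if rank >= conservative:
        return CLASS_CONSERVATIVE
    if rank >= weak:
        return CLASS_WEAK
    return CLASS_EXCLUDED


@dataclass
class ColumnProfile:
    """Residue statistics of one alignment column (1-based index)."""

    column: int
    counts: dict[str, int]
    gap_count: int
    n_rows: int
    top_residue: str | None
    rank: float
    klass: str

    def frequency(self, residue: str) -> float:
        """Frequency of a residue among non-gap rows (0 for all-gap columns)."""
        non_gap = self.n_rows - self.gap_count
        if non_gap == 0:
            return 0.0
        return self.counts.get(residue, 0) / non_gap


def column_profile(
    alignment: Alignment,
    column: int,
    *,
    bounds: tuple[float, float, float] = DEFAULT_CLASS_BOUNDS,
    all_rows_denominator: bool = False,
) -> ColumnProfile:
    """Profile one column: residue counts, top residue, rank, class.

    Frequencies are computed over non-gap rows (set ``all_rows_denominator``
    to include gaps in the denominator).  ``X`` is counted in the denominator
    but never eligible as the top residue.  An all-gap column has rank 0 and
    class ``excluded``.
    """
    col = alignment.column(column)
    counts = Counter(c for c in col if c != GAP)
    gap_count = len(col) - sum(counts.values())
    denom = len(col) if all_rows_denominator else len(col) - gap_count
    candidates = {r: n for r, n in counts.items() if r != "X"}
    if denom == 0 or not candidates:
        return ColumnProfile(column, dict(counts), gap_count, len(col), None, 0.0,
                             CLASS_EXCLUDED)
    top = min(candidates, key=lambda r: (-candidates[r], r))
    rank = candidates[top] / denom
    return ColumnProfile(
        column, dict(counts), gap_count, len(col), top, rank,
        conservation_class(rank, bounds),
    )


def consensus(alignment: Alignment, columns: Sequence[int]) -> dict[int, str | None]:
    """Most frequent non-gap residue per selected column (1-based indices).

    Ties are broken alphabetically (logged); all-gap columns yield ``None``.
    """
    out: dict[int, str | None] = {}
    for c in columns:
        prof = column_profile(alignment, c)
        if prof.top_residue is not None:
            top_n = prof.counts[prof.top_residue]
            tied = [r for r, n in prof.counts.items() if n == top_n and r != "X"]
            if len(tied) > 1:
                logger.info(
                    "column %d: consensus tie between %s resolved alphabetically",
                    c, sorted(tied),
                )
        out[c] = prof.top_residue
    return out


@dataclass
class PenaltyEntry:
    """Divergence of one row from the consensus or a reference row."""

    seq_id: str
    mode: str
    penalty: float
    n_mismatched: int
    n_columns_scored: int


def penalty_score(
    alignment: Alignment,
    seq_id: str,
    columns: Sequence[int],
    mode: str = "consensus",
) -> PenaltyEntry:
    """Frequency-weighted mismatch penalty of one row over selected columns.

    ``mode`` is ``"consensus"`` or ``"reference:<row id>"``.  For each selected
    column the target residue is the column consensus (or the reference row's
    residue); a mismatch adds that target residue's within-column frequency.
    Columns where the target is undefined (all-gap column, or a gapped
    reference) are skipped and excluded from ``n_columns_scored``.
    """
    row = alignment.row(seq_id)
    ref_row = None
    if mode.startswith("reference:"):
        ref_row = alignment.row(mode.split(":", 1)[1])
    elif mode != "consensus":
        raise ValueError(f"unknown penalty mode {mode!r}")

    penalty = 0.0
    n_mismatch = 0
    n_scored = 0
    for c in columns:
        prof = column_profile(alignment, c)
        if ref_row is not None:
            target = ref_row[c - 1]
            if target == GAP:
                continue
        else:
            target = prof.top_residue
            if target is None:
                continue
        n_scored += 1
        observed = row[c - 1]
        if observed != target or observed == "X":
            penalty += prof.frequency(target)
            n_mismatch += 1
    return PenaltyEntry(seq_id, mode, penalty, n_mismatch, n_scored)


def penalty_report(
    alignment: Alignment,
    columns: Sequence[int],
    reference_id: str | None = None,
) -> pd.DataFrame:
    """Penalty table for every row, vs consensus and optionally vs a reference."""
    rows = []
    for sid in alignment.ids:
        entry = penalty_score(alignment, sid, columns, "consensus")
        rec = {
            "seq_id": sid,
            "penalty_vs_consensus": entry.penalty,
            "mismatches_vs_consensus": entry.n_mismatched,
        }
        if reference_id is not None:
            ref = penalty_score(alignment, sid, columns, f"reference:{reference_id}")
            rec["penalty_vs_reference"] = ref.penalty
            rec["mismatches_vs_reference"] = ref.n_mismatched
        rows.append(rec)
    return pd.DataFrame(rows)


def bimodal_positions(
    alignment: Alignment,
    clades: Mapping[str, Iterable[str]],
    theta: float = 0.8,
) -> list[tuple[int, str, str, str, str]]:
    """Columns where two clades each fix a different residue.

    Reports ``(column, residue_1, clade_1, residue_2, clade_2)`` for every
    column and clade pair where residue 1 has within-clade frequency >= theta
    in clade 1 and a different residue 2 has frequency >= theta in clade 2.
    Within-clade frequencies count gaps in the denominator, so a mostly-gapped
    clade cannot qualify.  Since theta > 0.5, at most one residue per clade
    can qualify at a column.
    """
    if not 0.5 < theta <= 1.0:
        raise ValueError("theta must be in (0.5, 1]")
    clade_rows = {name: [alignment.row(i) for i in ids] for name, ids in clades.items()}
    covered = {i for ids in clades.values() for i in ids}
    missing = set(alignment.ids) - covered
    if missing:
        raise ValueError(f"clade partition does not cover rows: {sorted(missing)}")
    names = sorted(clade_rows)
    out: list[tuple[int, str, str, str, str]] = []
    for c in range(1, alignment.n_cols + 1):
        dominant: dict[str, str] = {}
        for name in names:
            rows = clade_rows[name]
            counts = Counter(r[c - 1] for r in rows)
            counts.pop(GAP, None)
            counts.pop("X", None)
            if not counts:
                continue
            res, n = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            if n / len(rows) >= theta:
                dominant[name] = res
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if a in dominant and b in dominant and dominant[a] != dominant[b]:
                    out.append((c, dominant[a], a, dominant[b], b))
    return out
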