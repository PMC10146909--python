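"""The "cysteine code": clade-level cysteine conservation, basic flanks, motifs.

The cysteine code of a redox-sensor protein is the pattern of its cysteine
positions together with the residues that surround them.  This module builds a
per-reference-cysteine report: for each cysteine of a named reference row the
alignment column, domain label, and conservation at three levels (the
reference ortholog group, the reference's clade, and the whole family) are
tabulated, along with whether the cysteine carries a basic residue (H/K/R)
within a sequence window — basic flanks lower the thiol pKa and mark the
cysteine as more susceptible to regulatory modification.  Cysteine columns
conserved in the family but absent from the reference are reported in a
separate section.

Conservation labels are threshold-based: a group is scored ``NotAlignable`` if
too few of its rows are aligned at the column, otherwise the presence fraction
p of the residue (gaps count as absence) maps to ``Yes`` (p >= 0.9),
``Partially`` (0.5 <= p < 0.9) or ``No``.  The thresholds are exposed, and
presence fractions are always printed so any re-thresholding is transparent.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GAP, Alignment, ProteinRecord

BASIC_RESIDUES = frozenset("HKR")

LABEL_YES = "Yes"
LABEL_PARTIALLY = "Partially"
LABEL_NO = "No"
LABEL_NOT_ALIGNABLE = "NotAlignable"


class PositionMap:
    """Bidirectional map between reference residue numbers and alignment columns.

    Covers exactly the reference row's non-gap columns; both directions are
    strictly increasing and 1-based.
    """

    def __init__(self, ref_row: str):
        self._pos_to_col: dict[int, int] = {}
        self._col_to_pos: dict[int, int] = {}
        pos = 0
        for col, c in enumerate(ref_row, start=1):
            if c != GAP:
                pos += 1
                self._pos_to_col[pos] = col
                self._col_to_pos[col] = pos
        self.n_positions = pos

    def column_of(self, position: int) -> int:
        try:
            return self._pos_to_col[position]
        except KeyError:
            raise KeyError(f"reference position {position} out of range") from None

    def position_of(self, column: int) -> int | None:
        """Reference position at a column, or None where the reference is gapped."""
        return self._col_to_pos.get(column)

    def items(self) -> Iterable[tuple[int, int]]:
        return self._pos_to_col.items()


def map_reference_positions(alignment: Alignment, reference_id: str) -> PositionMap:
    """PositionMap for a named reference row of an alignment."""
    return PositionMap(alignment.row(reference_id))


def classify_group_conservation(
    alignment: Alignment,
    column: int,
    group_ids: Sequence[str],
    residue: str = "C",
    yes_threshold: float = 0.9,
    partial_threshold: float = 0.5,
    alignable_threshold: float = 0.5,
) -> tuple[str, float, float]:
    """Conservation label of a residue in a group at one column.

    Returns ``(label, presence_fraction, non_gap_fraction)``.  The group is
    ``NotAlignable`` if its non-gap fraction at the column is below
    ``alignable_threshold``; otherwise the presence fraction (gaps counting as
    absence) is thresholded into Yes / Partially / No.
    """
    if not group_ids:
        raise ValueError("group must be non-empty")
    col = [alignment.row(i)[column - 1] for i in group_ids]
    n = len(col)
    non_gap = sum(1 for c in col if c != GAP) / n
    presence = sum(1 for c in col if c == residue) / n
    if non_gap < alignable_threshold:
        return LABEL_NOT_ALIGNABLE, presence, non_gap
    if presence >= yes_threshold:
        return LABEL_YES, presence, non_gap
    if presence >= partial_threshold:
        return LABEL_PARTIALLY, presence, non_gap
    return LABEL_NO, presence, non_gap


@dataclass
class FlankHit:
    """A cysteine with at least one basic residue within the sequence window."""

    position: int
    flanking: tuple[tuple[int, str], ...]  # (position, residue) of basic neighbors


def cysteine_positions(seq: str) -> list[int]:
    """1-based positions of every cysteine in an ungapped sequence."""
    return [i for i, c in enumerate(seq, start=1) if c == "C"]


def basic_flank_scan(record: ProteinRecord | str, window: int = 1) -> list[FlankHit]:
    """Cysteines flanked by a basic residue (H, K or R) within ±window.

    Every cysteine of the sequence is examined; windows are truncated at the
    sequence boundaries.  Only flagged cysteines are returned, sorted by
    position.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = record.seq if isinstance(record, ProteinRecord) else record
    hits: list[FlankHit] = []
    for pos in cysteine_positions(seq):
        lo = max(1, pos - window)
        hi = min(len(seq), pos + window)
        basics = tuple(
            (p, seq[p - 1])
            for p in range(lo, hi + 1)
            if p != pos and seq[p - 1] in BASIC_RESIDUES
        )
        if basics:
            hits.append(FlankHit(pos, basics))
    return hits


# --- motif scanning --------------------------------------------------------

#: Residue classes usable inside motif patterns.
RESIDUE_CLASSES = {
    "basic": frozenset("HKR"),
    "large_hydrophobic": frozenset("LIVMF"),
}


@dataclass(frozen=True)
class MotifPattern:
    """A short motif over exact residues, wildcards, and residue classes.

    Patterns are written with uppercase letters for exact residues, a
    lowercase ``x`` for a wildcard, and bracketed sets for residue classes,
    e.g. ``"KRR"``, ``"YxxGG"``, ``"[LIVMF]xE"``.  The ambiguity residue ``X``
    in a sequence matches only wildcards.
    """

    name: str
    tokens: tuple[frozenset | None, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) < 2:
            raise ValueError("pattern length must be >= 2")

    def __len__(self) -> int:
        return len(self.tokens)

    @classmethod
    def parse(cls, name: str, pattern: str) -> "MotifPattern":
        tokens: list[frozenset | None] = []
        for tok in re.findall(r"\[[A-Z]+\]|[A-Zx]", pattern):
            if tok == "x":
                tokens.append(None)
            elif tok.startswith("["):
                tokens.append(frozenset(tok[1:-1]))
            else:
                tokens.append(frozenset(tok))
        joined = "".join(
            "x" if t is None else (next(iter(t)) if len(t) == 1 else f"[{''.join(sorted(t))}]")
            for t in tokens
        )
        if joined != pattern:
            raise ValueError(f"cannot parse motif pattern {pattern!r}")
        return cls(name, tuple(tokens))


#: Built-in motifs of the Kelch-like family analysis: the arginine-triad mimic
#: KRR, the propeller-blade YxxGG and double-glycine motifs, and the
#: Cullin-interacting phi-x-E motif (phi = large hydrophobic).
BUILTIN_MOTIFS = {
    "KRR": MotifPattern.parse("KRR", "KRR"),
    "YxxGG": MotifPattern.parse("YxxGG", "YxxGG"),
    "GG": MotifPattern.parse("GG", "GG"),
    "phi-xE": MotifPattern.parse("phi-xE", "[FILMV]xE"),
}


def motif_scan(record: ProteinRecord | str, pattern: MotifPattern) -> list[tuple[int, int]]:
    """All (possibly overlapping) matches as 1-based (start, end) pairs."""
    seq = record.seq if isinstance(record, ProteinRecord) else record
    k = len(pattern)
    out: list[tuple[int, int]] = []
    for s in range(len(seq) - k + 1):
        for tok, c in zip(pattern.tokens, seq[s:s + k]):
            if tok is not None and c not in tok:
                break
        else:
            out.append((s + 1, s + k))
    return out


def motif_scan_alignment(
    alignment: Alignment,
    row_id: str,
    pattern: MotifPattern,
    position_map: PositionMap | None = None,
) -> list[dict]:
    """Scan a row's ungapped sequence; optionally report reference numbering.

    Each match dict carries the match coordinates in the row's own residue
    numbering and, when a reference PositionMap is given, the reference
    positions equivalent to the match start/end columns (None where the
    reference is gapped there).
    """
    row = alignment.row(row_id)
    own_map = PositionMap(row)
    seq = row.replace(GAP, "")
    matches = []
    for start, end in motif_scan(seq, pattern):
        entry: dict = {"row_id": row_id, "motif": pattern.name,
                       "start": start, "end": end}
        if position_map is not None:
            entry["ref_start"] = position_map.position_of(own_map.column_of(start))
            entry["ref_end"] = position_map.position_of(own_map.column_of(end))
        matches.append(entry)
    return matches


# --- domain labelling ------------------------------------------------------

#: Approximate domain intervals of the human reference protein (1-based,
#: inclusive), following the Pfam-derived BTB boundary (67-178) and the
#: conventional region definitions around it.  Users studying another
#: reference should supply their own table.
KEAP1_DOMAINS: tuple[tuple[str, int, int], ...] = (
    ("NTR", 1, 66),
    ("BTB", 67, 178),
    ("BACK", 179, 270),
    ("IVR", 271, 326),
    ("Kelch1", 327, 358),
    ("Kelch2", 359, 412),
    ("Kelch3", 413, 460),
    ("Kelch4", 461, 505),
    ("Kelch5", 506, 552),
    ("Kelch6", 553, 597),
    ("CTR", 598, 9999),
)


def domain_label(position: int, domains: Sequence[tuple[str, int, int]]) -> str:
    """Label of the first domain interval containing a reference position."""
    for name, start, end in domains:
        if start <= position <= end:
            return name
    return "-"


# --- the report ------------------------------------------------------------

@dataclass
class CysteineRecord:
    """Report row for one reference cysteine."""

    position: int
    column: int
    domain: str
    in_reference_group: str
    in_clade: str
    in_family: str
    p_reference_group: float
    p_clade: float
    p_family: float
    basic_flank: bool
    flanking: tuple[tuple[int, str], ...]
    studied: str = ""


def build_cysteine_report(
    alignment: Alignment,
    reference_id: str,
    clades: Mapping[str, Sequence[str]],
    domains: Sequence[tuple[str, int, int]] = KEAP1_DOMAINS,
    reference_group: Sequence[str] | None = None,
    window: int = 1,
    yes_threshold: float = 0.9,
    partial_threshold: float = 0.5,
    alignable_threshold: float = 0.5,
    annotations: Mapping[int, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-reference-cysteine conservation report plus the missing-column section.

    Parameters
    ----------
    alignment : Alignment
        Family alignment containing the reference row.
    reference_id : str
        Row whose cysteines are reported; report positions use its numbering.
    clades : mapping of clade name -> row ids
        Must cover every alignment row; the clade containing the reference
        provides the clade-level classification.
    reference_group : sequence of str, optional
        The reference's ortholog group (defaults to the reference row alone).
    annotations : mapping of reference position -> str, optional
        Literature metadata (e.g. a "+" for experimentally studied residues);
        copied into the ``studied`` column, never computed.

    Returns
    -------
    (main, missing)
        ``main`` has one row per reference cysteine.  ``missing`` lists
        alignment columns whose cysteine is conserved (Yes/Partially) at the
        family level or in some clade while the reference residue there is not
        a cysteine — the family cysteines the reference lost.
    """
    covered = {i for ids in clades.values() for i in ids}
    missing_rows = set(alignment.ids) - covered
    if missing_rows:
        raise ValueError(f"clade partition does not cover rows: {sorted(missing_rows)}")
    if reference_group is None:
        reference_group = [reference_id]
    ref_clade = next(
        (name for name, ids in clades.items() if reference_id in ids), None
    )
    if ref_clade is None:
        raise ValueError(f"reference {reference_id!r} not assigned to any clade")

    pmap = map_reference_positions(alignment, reference_id)
    ref_seq = alignment.degapped(reference_id)
    flank_by_pos = {h.position: h for h in basic_flank_scan(ref_seq, window)}
    annotations = dict(annotations or {})
    thresholds = dict(
        yes_threshold=yes_threshold,
        partial_threshold=partial_threshold,
        alignable_threshold=alignable_threshold,
    )

    family_ids = sorted(alignment.ids)
    records: list[CysteineRecord] = []
    for pos in cysteine_positions(ref_seq):
        col = pmap.column_of(pos)
        g_label, g_p, _ = classify_group_conservation(
            alignment, col, sorted(reference_group), "C", **thresholds
        )
        c_label, c_p, _ = classify_group_conservation(
            alignment, col, sorted(clades[ref_clade]), "C", **thresholds
        )
        f_label, f_p, _ = classify_group_conservation(
            alignment, col, family_ids, "C", **thresholds
        )
        hit = flank_by_pos.get(pos)
        records.append(
            CysteineRecord(
                position=pos,
                column=col,
                domain=domain_label(pos, domains),
                in_reference_group=g_label,
                in_clade=c_label,
                in_family=f_label,
                p_reference_group=g_p,
                p_clade=c_p,
                p_family=f_p,
                basic_flank=hit is not None,
                flanking=hit.flanking if hit else (),
                studied=annotations.get(pos, ""),
            )
        )

    main = pd.DataFrame(
        [
            {
                "position": r.position,
                "column": r.column,
                "domain": r.domain,
                "conserved_in_reference_group": r.in_reference_group,
                "conserved_in_clade": r.in_clade,
                "conserved_in_family": r.in_family,
                "presence_reference_group": r.p_reference_group,
                "presence_clade": r.p_clade,
                "presence_family": r.p_family,
                "basic_flank": r.basic_flank,
                "flanking_basics": ";".join(f"{res}{p}" for p, res in r.flanking),
                "studied": r.studied,
            }
            for r in records
        ],
        columns=[
            "position", "column", "domain", "conserved_in_reference_group",
            "conserved_in_clade", "conserved_in_family",
            "presence_reference_group", "presence_clade", "presence_family",
            "basic_flank", "flanking_basics", "studied",
        ],
    )

    # family/clade cysteine columns the reference lost
    ref_row = alignment.row(reference_id)
    missing: list[dict] = []
    clade_names = sorted(clades)
    for col in range(1, alignment.n_cols + 1):
        if ref_row[col - 1] == "C":
            continue
        f_label, f_p, _ = classify_group_conservation(
            alignment, col, family_ids, "C", **thresholds
        )
        clade_hits = []
        for name in clade_names:
            lab, p, _ = classify_group_conservation(
                alignment, col, sorted(clades[name]), "C", **thresholds
            )
            if lab in (LABEL_YES, LABEL_PARTIALLY):
                clade_hits.append(f"{name}:{lab}")
        if f_label in (LABEL_YES, LABEL_PARTIALLY) or clade_hits:
            pos = pmap.position_of(col)
            missing.append(
                {
                    "column": col,
                    "reference_position": pos if pos is not None else "",
                    "reference_residue": ref_row[col - 1],
                    "family_label": f_label,
                    "presence_family": f_p,
                    "clades_conserved": ";".join(clade_hits),
                }
            )
    missing_df = pd.DataFrame(
        missing,
        columns=["column", "reference_position", "reference_residue",
                 "family_label", "presence_family", "clades_conserved"],
    )
    return main, missing_df


def cysteine_spacing(seq: str) -> list[int]:
    """Successive spacings (in residues) between cysteines of a sequence."""
    pos = cysteine_positions(seq)
    return [b - a for a, b in zip(pos, pos[1:])]


def cysteine_spacing_histogram(seq: str) -> dict[int, int]:
    """Histogram of cysteine spacings (exploratory; no periodicity is asserted)."""
    return dict(sorted(Counter(cysteine_spacing(seq)).items()))
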