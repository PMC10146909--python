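"""Sequence, alignment, and domain-table I/O plus the shared data model.

Coordinates are 1-based and inclusive throughout the public API (matching the
residue numbering used for the human reference protein, e.g. C151); conversion
to 0-based indices happens only at numpy array boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetically.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residues accepted in sequences (X = unknown/ambiguous; never matches a consensus).
SEQUENCE_ALPHABET = set(AMINO_ACIDS) | {"X"}
GAP = "-"

# Non-standard one-letter codes mapped to X on input.
_NONSTANDARD = {"B", "Z", "U", "O", "J"}


def clean_sequence(seq: str, *, record_id: str = "?", allow_gaps: bool = False) -> str:
    """Normalise a raw sequence string.

    Uppercases, strips ``*`` (stop), maps non-standard residues (B, Z, U, O, J)
    to ``X`` with a logged warning, and normalises gap characters ``.`` to
    ``-`` when ``allow_gaps`` is set.  Unrecognised characters raise.
    """
    out = []
    warned: set[str] = set()
    for c in seq.upper():
        if c == "*":
            continue
        if c in _NONSTANDARD:
            if c not in warned:
                logger.warning("record %s: non-standard residue %s mapped to X", record_id, c)
                warned.add(c)
            c = "X"
        if c in (".", "-"):
            if not allow_gaps:
                raise ValueError(f"record {record_id}: gap character in ungapped sequence")
            c = GAP
        elif c not in SEQUENCE_ALPHABET:
            raise ValueError(f"record {record_id}: invalid residue {c!r}")
        out.append(c)
    return "".join(out)


@dataclass
class ProteinRecord:
    """A protein sequence with 1-based residue numbering."""

    id: str
    seq: str
    gene: str = ""
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.seq):
            raise IndexError(f"position {position} outside 1..{len(self.seq)}")
        return self.seq[position - 1]


class Alignment:
    """A gapped sequence matrix with named rows.

    Rows must have identical length; degapping any row reproduces the
    underlying protein sequence exactly.
    """

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        if len(ids) == 0:
            raise ValueError("alignment must contain at least one row")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self.ids: list[str] = list(ids)
        self._rows: dict[str, str] = dict(zip(self.ids, rows))
        self.n_cols: int = len(rows[0])
        self._matrix: np.ndarray | None = None

    @classmethod
    def from_records(cls, records: Iterable[ProteinRecord]) -> "Alignment":
        recs = list(records)
        return cls([r.id for r in recs], [r.seq for r in recs])

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def matrix(self) -> np.ndarray:
        """Residue matrix of shape (n_rows, n_cols), dtype '<U1'."""
        if self._matrix is None:
            self._matrix = np.array([list(self._rows[i]) for i in self.ids])
        return self._matrix

    def row(self, row_id: str) -> str:
        try:
            return self._rows[row_id]
        except KeyError:
            raise KeyError(f"unknown row id {row_id!r}") from None

    def degapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def column(self, column: int) -> str:
        """Column residues (1-based column index)."""
        if not 1 <= column <= self.n_cols:
            raise IndexError(f"column {column} outside 1..{self.n_cols}")
        j = column - 1
        return "".join(self._rows[i][j] for i in self.ids)

    def subset_rows(self, row_ids: Sequence[str]) -> "Alignment":
        return Alignment(list(row_ids), [self.row(i) for i in row_ids])

    def with_rows(self, rows: dict[str, str]) -> "Alignment":
        """A copy with some rows replaced (same ids and width)."""
        return Alignment(self.ids, [rows.get(i, self._rows[i]) for i in self.ids])


@dataclass(frozen=True)
class DomainHit:
    """A scored domain interval on a protein (1-based inclusive coordinates)."""

    protein_id: str
    domain: str
    e_value: float
    start: int
    end: int
    source_name: str = ""

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError(f"{self.protein_id}: e-value must be > 0")
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"{self.protein_id}: invalid coordinates {self.start}..{self.end}"
            )


def canonical_domain(name: str) -> str:
    """Map a domain/profile name to one of BTB, BACK, Kelch, other."""
    low = name.lower()
    if "kelch" in low or "pf01344" in low:
        return "Kelch"
    if "back" in low or "pf07707" in low:
        return "BACK"
    if "btb" in low or "pf00651" in low:
        return "BTB"
    return "other"


def read_fasta(path: str | Path, *, allow_gaps: bool = False) -> list[ProteinRecord]:
    """Read a FASTA file into protein records.

    The header token before the first whitespace becomes the id; sequences are
    uppercased and ``*`` is stripped.  Duplicate ids and empty files raise.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = clean_sequence(str(rec.seq), record_id=rec.id, allow_gaps=allow_gaps)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, seq=seq, description=desc))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_alignment(path: str | Path) -> Alignment:
    """Read a gapped FASTA alignment ('.' and '-' both accepted as gaps)."""
    records = read_fasta(path, allow_gaps=True)
    return Alignment.from_records(records)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    write_fasta(
        [ProteinRecord(id=i, seq=alignment.row(i)) for i in alignment.ids], path
    )


# --- domain tables ---------------------------------------------------------

_DIALECTS = ("tsv", "hmmer-domtbl")

_TSV_HEADER_TOKENS = {"protein_id", "protein", "id"}


def read_domain_table(path: str | Path, dialect: str = "tsv") -> list[DomainHit]:
    """Read per-protein domain hits.

    Two dialects are supported:

    ``tsv``
        Five whitespace/tab-separated columns: protein_id, domain, e_value,
        start, end.  A header line and ``#`` comments are skipped.
    ``hmmer-domtbl``
        HMMER3 ``--domtblout`` as produced by *hmmscan* (target = domain
        profile, query = protein); the per-domain independent e-value and
        alignment coordinates are used.

    Coordinates are kept 1-based inclusive.  Malformed numeric fields raise
    with the offending line number.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if dialect == "tsv":
                if lineno == 1 and fields and fields[0].lower() in _TSV_HEADER_TOKENS:
                    continue
                if len(fields) < 5:
                    raise ValueError(f"{path} line {lineno}: expected 5 columns")
                pid, name, e_str, s_str, t_str = fields[:5]
            else:
                if len(fields) < 19:
                    raise ValueError(f"{path} line {lineno}: truncated domtblout row")
                name, pid = fields[0], fields[3]
                e_str, s_str, t_str = fields[12], fields[17], fields[18]
            try:
                e_value = float(e_str)
                start, end = int(s_str), int(t_str)
            except ValueError:
                raise ValueError(
                    f"{path} line {lineno}: unparsable numeric field"
                ) from None
            try:
                hits.append(
                    DomainHit(
                        protein_id=pid,
                        domain=canonical_domain(name),
                        e_value=e_value,
                        start=start,
                        end=end,
                        source_name=name,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from None
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain\te_value\tstart\tend\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.domain}\t{h.e_value:g}\t{h.start}\t{h.end}\n")
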