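"""Domain-architecture family selection and isoform deduplication.

Membership in the Kelch-like (KLHL) family is defined by domain architecture:
a protein qualifies if it carries a BTB domain, a BACK domain, and at least
one Kelch repeat, each at or below a configurable e-value threshold.  The
default thresholds apply the loose 0.1 architecture-check cutoff to all three
domains; Kelch hits are counted individually without overlap merging, since
profile searches routinely detect only a subset of the six propeller blades.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .io_formats import DomainHit, ProteinRecord


@dataclass(frozen=True)
class ArchitectureRule:
    """E-value thresholds defining the required BTB + BACK + Kelch architecture."""

    btb_max_evalue: float = 0.1
    back_max_evalue: float = 0.1
    kelch_max_evalue: float = 0.1
    min_kelch_hits: int = 1

    def __post_init__(self) -> None:
        for v in (self.btb_max_evalue, self.back_max_evalue, self.kelch_max_evalue):
            if v <= 0:
                raise ValueError("e-value thresholds must be > 0")
        if self.min_kelch_hits < 0:
            raise ValueError("min_kelch_hits must be >= 0")


def filter_by_architecture(
    hits: Iterable[DomainHit],
    rule: ArchitectureRule = ArchitectureRule(),
    protein_ids: Sequence[str] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Partition proteins into accepted ids and per-protein rejection reasons.

    Parameters
    ----------
    hits : iterable of DomainHit
        All domain hits, any order.
    rule : ArchitectureRule
        Thresholds; defaults are the loose architecture-check values.
    protein_ids : sequence of str, optional
        The full protein universe.  Proteins without any hit are rejected with
        reason "missing BTB".  Defaults to the proteins present in ``hits``.

    Returns
    -------
    (accepted, rejections)
        ``accepted`` is sorted for determinism; ``rejections`` maps each
        rejected id to the first missing requirement (checked in the order
        BTB, BACK, Kelch).
    """
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        by_protein[h.protein_id].append(h)
    universe = set(protein_ids) if protein_ids is not None else set(by_protein)

    accepted: list[str] = []
    rejections: dict[str, str] = {}
    for pid in sorted(universe):
        phits = by_protein.get(pid, [])
        if not any(h.domain == "BTB" and h.e_value <= rule.btb_max_evalue for h in phits):
            rejections[pid] = "missing BTB"
            continue
        if not any(h.domain == "BACK" and h.e_value <= rule.back_max_evalue for h in phits):
            rejections[pid] = "missing BACK"
            continue
        n_kelch = sum(
            1 for h in phits if h.domain == "Kelch" and h.e_value <= rule.kelch_max_evalue
        )
        if n_kelch < rule.min_kelch_hits:
            if n_kelch == 0:
                rejections[pid] = "missing Kelch"
            else:
                rejections[pid] = (
                    f"only {n_kelch} of {rule.min_kelch_hits} required Kelch hits"
                )
            continue
        accepted.append(pid)
    return accepted, rejections


def deduplicate_isoforms(
    records: Iterable[ProteinRecord],
    gene_key: Callable[[ProteinRecord], str] | None = None,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Keep one isoform per gene: the longest sequence, ties to smallest id.

    ``gene_key`` extracts the grouping key; by default the record's ``gene``
    field is used, falling back to the id for records without a gene label
    (which therefore form singleton groups).

    Returns the kept records (sorted by id, so the result is independent of
    input order) and a mapping of dropped id -> kept id.
    """
    if gene_key is None:
        gene_key = lambda r: r.gene or r.id  # noqa: E731
    groups: dict[str, list[ProteinRecord]] = defaultdict(list)
    for rec in records:
        groups[gene_key(rec)].append(rec)
    kept: list[ProteinRecord] = []
    dropped: dict[str, str] = {}
    for _, members in groups.items():
        winner = min(members, key=lambda r: (-len(r.seq), r.id))
        kept.append(winner)
        for m in members:
            if m.id != winner.id:
                dropped[m.id] = winner.id
    kept.sort(key=lambda r: r.id)
    return kept, dropped
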