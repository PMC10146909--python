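"""Clade-structured protein-family simulator with planted ground truth.

Families are simulated under the same embedded JTT substitution model used for
distance estimation: a star-of-clades tree (one long branch per clade, short
branches to the leaves) is evolved column by column, and the generator then
*plants* the features the analysis modules are meant to recover — columns of
prescribed conservation class, cysteine columns conserved at the family,
clade, or reference-ortholog level with prescribed presence fractions, basic
flanking residues next to chosen cysteines, and sequence motifs in chosen
rows.  There is no indel process, so the true alignment is the simulated
matrix itself; gaps are injected afterwards with :func:`corrupt_alignment`.

To keep the planted truth exact rather than approximate, the background is
scrubbed around the plan: simulated cysteines are replaced everywhere except
planted columns (cysteines occur only where the plan puts them), basic
residues are removed from the flanking window of planted cysteine columns
unless a flank is planted there, and presence fractions are realised as exact
row counts.  Classification truth is computed from the realised matrix at
generation time, so recovery tests compare against what was actually emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import substitution
from .cyscode import BUILTIN_MOTIFS, MotifPattern, LABEL_YES, LABEL_PARTIALLY, LABEL_NO
from .io_formats import Alignment, ProteinRecord, write_fasta

_AA = substitution.AA_ORDER
_C_IDX = _AA.index("C")
_BASIC_IDX = [_AA.index(r) for r in "HKR"]


@dataclass(frozen=True)
class PlantedCysteine:
    """A cysteine column planted for a scope of rows at a presence fraction.

    ``scope`` is ``"family"``, ``"clade:<name>"``, or ``"reference"`` (the
    reference ortholog group).
    """

    column: int
    scope: str
    presence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence <= 1.0:
            raise ValueError("presence must be in [0, 1]")


@dataclass(frozen=True)
class PlantedFlank:
    """A basic residue planted next to a planted cysteine column."""

    cys_column: int
    offset: int = 1
    residue: str = "K"


@dataclass(frozen=True)
class PlantedMotif:
    """A motif written into chosen rows at a start column.

    ``rows`` is ``"all"``, ``"clade:<name>"``, ``"reference"``, or an explicit
    tuple of row ids; ``motif`` names a built-in pattern or is a pattern
    string.
    """

    motif: str
    rows: str | tuple[str, ...] = "all"
    column: int = 1


def _default_cysteine_plan() -> tuple[PlantedCysteine, ...]:
    return (
        PlantedCysteine(40, "family", 1.0),        # family-wide conserved
        PlantedCysteine(80, "clade:clade1", 1.0),  # clade-specific
        PlantedCysteine(120, "reference", 1.0),    # reference-group only
        PlantedCysteine(160, "clade:clade2", 0.7),  # partially conserved, other clade
        PlantedCysteine(200, "family", 0.7),       # partially conserved family-wide
    )


def _default_flank_plan() -> tuple[PlantedFlank, ...]:
    return (PlantedFlank(120, 1, "K"),)


def _default_motif_plan() -> tuple[PlantedMotif, ...]:
    return (
        PlantedMotif("KRR", "clade:clade2", 250),
        PlantedMotif("phi-xE", "all", 260),
    )


@dataclass
class FamilyConfig:
    """Simulation parameters; defaults give a 5-clade, 40-taxon family."""

    n_clades: int = 5
    taxa_per_clade: int = 8
    length: int = 300
    inter_clade_branch: float = 0.8
    intra_clade_branch: float = 0.05
    frac_ultra: float = 0.10
    frac_conservative: float = 0.10
    frac_weak: float = 0.10
    reference_group_size: int = 3
    flank_window: int = 1
    planted_cysteines: tuple[PlantedCysteine, ...] = field(
        default_factory=_default_cysteine_plan
    )
    planted_flanks: tuple[PlantedFlank, ...] = field(default_factory=_default_flank_plan)
    planted_motifs: tuple[PlantedMotif, ...] = field(default_factory=_default_motif_plan)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_ultra + self.frac_conservative + self.frac_weak > 1.0:
            raise ValueError("class fractions must sum to <= 1")
        if self.n_clades < 1 or self.taxa_per_clade < 1 or self.length < 1:
            raise ValueError("n_clades, taxa_per_clade and length must be >= 1")
        if not 1 <= self.reference_group_size <= self.taxa_per_clade:
            raise ValueError("reference_group_size must fit within a clade")


#: Presence fraction used when planting columns of each conservation class;
#: values sit well inside the class intervals (0.66/0.50/0.33 boundaries).
CLASS_PRESENCE = {"ultra": 0.90, "conservative": 0.58, "weak": 0.41}


@dataclass(frozen=True)
class CysteineTruth:
    """Realised classification of one planted cysteine column."""

    column: int
    scope: str
    presence_target: float
    rows_with_c: tuple[str, ...]
    label_reference_group: str
    label_reference_clade: str
    label_family: str
    labels_by_clade: dict[str, str]
    flank_planted: bool


@dataclass
class FamilyTruth:
    """Everything the generator knows about the emitted family."""

    newick: str
    clades: dict[str, tuple[str, ...]]
    reference_id: str
    reference_group: tuple[str, ...]
    column_classes: dict[int, str]
    cysteines: tuple[CysteineTruth, ...]
    motifs: tuple[tuple[str, str, int], ...]  # (row_id, motif name, start column)
    seed: int


def _label(p: float, yes: float = 0.9, partial: float = 0.5) -> str:
    if p >= yes:
        return LABEL_YES
    if p >= partial:
        return LABEL_PARTIALLY
    return LABEL_NO


def _evolve_child(parent: np.ndarray, branch: float, rng: np.random.Generator,
                  cum_cache: dict[float, np.ndarray]) -> np.ndarray:
    """Sample child states under JTT conditioned on never visiting cysteine.

    The background is kept cysteine-free so cysteines occur only where the
    plan puts them; the transition kernel is renormalised over the remaining
    19 states.
    """
    if branch not in cum_cache:
        p = substitution.transition_matrix(branch).copy()
        p[:, _C_IDX] = 0.0
        p /= p.sum(axis=1, keepdims=True)
        cum_cache[branch] = p.cumsum(axis=1)
    cum = cum_cache[branch]
    u = rng.random(parent.size)
    return (u[:, None] > cum[parent]).sum(axis=1).astype(np.int64)


def _draw(rng: np.random.Generator, size: int, exclude: set[int]) -> np.ndarray:
    """Draw residues from the JTT equilibrium, excluding some indices."""
    w = substitution.JTT_FREQS.copy()
    for i in exclude:
        w[i] = 0.0
    w /= w.sum()
    return rng.choice(20, size=size, p=w)


def _resolve_pattern(name: str) -> MotifPattern:
    if name in BUILTIN_MOTIFS:
        return BUILTIN_MOTIFS[name]
    return MotifPattern.parse(name, name)


def generate_family(config: FamilyConfig) -> tuple[list[ProteinRecord], Alignment, FamilyTruth]:
    """Simulate a family and return (records, true alignment, truth).

    Deterministic given ``config.seed``.  Raises on an infeasible plan
    (planted features overlapping in the same columns).
    """
    rng = np.random.default_rng(config.seed)
    L = config.length
    clade_names = [f"clade{i + 1}" for i in range(config.n_clades)]
    clades = {
        name: tuple(
            f"{name}_t{j + 1:02d}" for j in range(config.taxa_per_clade)
        )
        for name in clade_names
    }
    taxa = [t for name in clade_names for t in clades[name]]
    reference_group = clades[clade_names[0]][: config.reference_group_size]
    reference_id = reference_group[0]

    # --- feasibility: planted features must occupy disjoint columns --------
    used: dict[int, str] = {}

    def _reserve(col: int, what: str) -> None:
        if not 1 <= col <= L:
            raise ValueError(f"planted column {col} outside 1..{L}")
        if col in used:
            raise ValueError(
                f"infeasible plan: column {col} claimed by both {used[col]} and {what}"
            )
        used[col] = what

    for pc in config.planted_cysteines:
        for c in range(pc.column - config.flank_window, pc.column + config.flank_window + 1):
            if 1 <= c <= L:
                _reserve(c, f"cysteine@{pc.column}")
    cys_columns = {pc.column for pc in config.planted_cysteines}
    for fl in config.planted_flanks:
        if fl.cys_column not in cys_columns:
            raise ValueError(f"flank at column {fl.cys_column} has no planted cysteine")
        if abs(fl.offset) > config.flank_window or fl.offset == 0:
            raise ValueError("flank offset must be within the window and non-zero")
        if fl.residue not in "HKR":
            raise ValueError("flank residue must be basic (H, K or R)")
    motif_spans: list[tuple[PlantedMotif, MotifPattern]] = []
    for pm in config.planted_motifs:
        pat = _resolve_pattern(pm.motif)
        for c in range(pm.column, pm.column + len(pat)):
            _reserve(c, f"motif@{pm.column}")
        motif_spans.append((pm, pat))

    # --- simulate down the star-of-clades tree -----------------------------
    cum_cache: dict[float, np.ndarray] = {}
    root = _draw(rng, L, {_C_IDX})
    matrix = np.empty((len(taxa), L), dtype=np.int64)
    row_index = {t: i for i, t in enumerate(taxa)}
    for name in clade_names:
        ancestor = _evolve_child(root, config.inter_clade_branch, rng, cum_cache)
        for t in clades[name]:
            matrix[row_index[t]] = _evolve_child(
                ancestor, config.intra_clade_branch, rng, cum_cache
            )

    # --- planted conservation-class columns --------------------------------
    free_cols = [c for c in range(1, L + 1) if c not in used]
    n_rows = len(taxa)
    counts = {
        "ultra": round(config.frac_ultra * L),
        "conservative": round(config.frac_conservative * L),
        "weak": round(config.frac_weak * L),
    }
    n_class = sum(counts.values())
    if n_class > len(free_cols):
        raise ValueError("infeasible plan: not enough free columns for class plan")
    chosen = rng.choice(len(free_cols), size=n_class, replace=False)
    chosen_cols = [free_cols[i] for i in sorted(chosen.tolist())]
    column_classes: dict[int, str] = {}
    pool = list(chosen_cols)
    rng.shuffle(pool)
    it = iter(pool)
    for klass, n in counts.items():
        for _ in range(n):
            column_classes[next(it)] = klass
    # planted class columns get an i.i.d. background (no clade correlation),
    # so the top residue and its realised frequency are the planted ones
    for col, klass in sorted(column_classes.items()):
        j = col - 1
        target = int(_draw(rng, 1, {_C_IDX})[0])
        k = round(CLASS_PRESENCE[klass] * n_rows)
        matrix[:, j] = _draw(rng, n_rows, {_C_IDX, target})
        rows = rng.choice(n_rows, size=k, replace=False)
        matrix[rows, j] = target

    # --- planted cysteines -------------------------------------------------
    def _scope_rows(scope: str) -> tuple[str, ...]:
        if scope == "family":
            return tuple(taxa)
        if scope == "reference":
            return reference_group
        if scope.startswith("clade:"):
            name = scope.split(":", 1)[1]
            if name not in clades:
                raise ValueError(f"unknown clade in scope {scope!r}")
            return clades[name]
        raise ValueError(f"unknown scope {scope!r}")

    flank_by_col: dict[int, list[PlantedFlank]] = {}
    for fl in config.planted_flanks:
        flank_by_col.setdefault(fl.cys_column, []).append(fl)

    cys_truth: list[CysteineTruth] = []
    for pc in sorted(config.planted_cysteines, key=lambda p: p.column):
        j = pc.column - 1
        scope = _scope_rows(pc.scope)
        k = round(pc.presence * len(scope))
        picked = sorted(
            rng.choice(len(scope), size=k, replace=False).tolist()
        )
        rows_with_c = tuple(scope[i] for i in picked)
        # with full presence the whole scope carries C, reference included
        for t in rows_with_c:
            matrix[row_index[t], j] = _C_IDX
        # scrub basic residues in the flank window, then plant flanks
        for off in range(-config.flank_window, config.flank_window + 1):
            col = pc.column + off
            if off == 0 or not 1 <= col <= L:
                continue
            col_j = col - 1
            basic = np.isin(matrix[:, col_j], _BASIC_IDX)
            if basic.any():
                matrix[basic, col_j] = _draw(
                    rng, int(basic.sum()), {_C_IDX, *_BASIC_IDX}
                )
        for fl in flank_by_col.get(pc.column, []):
            col_j = pc.column + fl.offset - 1
            for t in rows_with_c:
                matrix[row_index[t], col_j] = _AA.index(fl.residue)

        def _p(group: tuple[str, ...]) -> float:
            return sum(1 for t in group if t in rows_with_c) / len(group)

        cys_truth.append(
            CysteineTruth(
                column=pc.column,
                scope=pc.scope,
                presence_target=pc.presence,
                rows_with_c=rows_with_c,
                label_reference_group=_label(_p(reference_group)),
                label_reference_clade=_label(_p(clades[clade_names[0]])),
                label_family=_label(_p(tuple(taxa))),
                labels_by_clade={n: _label(_p(clades[n])) for n in clade_names},
                flank_planted=pc.column in flank_by_col,
            )
        )

    # --- planted motifs ----------------------------------------------------
    motif_truth: list[tuple[str, str, int]] = []
    for pm, pat in motif_spans:
        if isinstance(pm.rows, tuple):
            target_rows = pm.rows
        elif pm.rows == "all":
            target_rows = tuple(taxa)
        else:
            target_rows = _scope_rows(pm.rows)
        residues = []
        for tok in pat.tokens:
            if tok is None:
                residues.append(int(_draw(rng, 1, {_C_IDX})[0]))
            elif len(tok) == 1:
                residues.append(_AA.index(next(iter(tok))))
            else:
                residues.append(_AA.index(rng.choice(sorted(tok))))
        for t in target_rows:
            matrix[row_index[t], pm.column - 1: pm.column - 1 + len(pat)] = residues
            motif_truth.append((t, pat.name, pm.column))

    # --- emit --------------------------------------------------------------
    rows = ["".join(_AA[i] for i in matrix[row_index[t]]) for t in taxa]
    records = [
        ProteinRecord(id=t, seq=row, gene=t, species=name)
        for name in clade_names
        for t, row in ((t, rows[row_index[t]]) for t in clades[name])
    ]
    alignment = Alignment(taxa, rows)
    newick = (
        "("
        + ",".join(
            "("
            + ",".join(f"{t}:{config.intra_clade_branch}" for t in clades[name])
            + f"):{config.inter_clade_branch}"
            for name in clade_names
        )
        + ");"
    )
    truth = FamilyTruth(
        newick=newick,
        clades=clades,
        reference_id=reference_id,
        reference_group=reference_group,
        column_classes=column_classes,
        cysteines=tuple(cys_truth),
        motifs=tuple(motif_truth),
        seed=config.seed,
    )
    return records, alignment, truth


def corrupt_alignment(
    alignment: Alignment,
    gap_fraction: float,
    seed: int,
    row_ids: list[str] | None = None,
    columns: tuple[int, int] | None = None,
) -> tuple[Alignment, list[tuple[str, int]]]:
    """Inject random gap runs into (a region of) an alignment.

    ``gap_fraction`` is the target fraction of gapped cells within the region
    (``row_ids`` x the inclusive 1-based column range ``columns``; defaults:
    all rows, all columns).  Gaps are placed as runs with geometric lengths
    (mean ~4).  Deterministic given the seed; returns the gapped alignment and
    the sorted list of (row id, column) cells that were gapped.
    """
    if not 0.0 <= gap_fraction < 1.0:
        raise ValueError("gap_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = row_ids if row_ids is not None else list(alignment.ids)
    lo, hi = columns if columns is not None else (1, alignment.n_cols)
    if not 1 <= lo <= hi <= alignment.n_cols:
        raise ValueError("invalid column range")
    width = hi - lo + 1
    n_target = round(gap_fraction * len(rows) * width)
    gapped: set[tuple[str, int]] = set()
    guard = 0
    while len(gapped) < n_target and guard < 100_000:
        guard += 1
        rid = rows[int(rng.integers(0, len(rows)))]
        start = int(rng.integers(lo, hi + 1))
        run = 1 + int(rng.geometric(0.25))
        for c in range(start, min(start + run, hi + 1)):
            if len(gapped) >= n_target:
                break
            gapped.add((rid, c))
    new_rows: dict[str, str] = {}
    for rid in rows:
        chars = list(alignment.row(rid))
        for c in range(lo, hi + 1):
            if (rid, c) in gapped:
                chars[c - 1] = "-"
        new_rows[rid] = "".join(chars)
    return alignment.with_rows(new_rows), sorted(gapped)


def write_family(
    records: list[ProteinRecord],
    alignment: Alignment,
    truth: FamilyTruth,
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Write FASTA, true alignment, true tree, clade table and truth TSVs."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": prefix.with_suffix(".fasta"),
        "alignment": Path(f"{prefix}.aln.fasta"),
        "newick": prefix.with_suffix(".nwk"),
        "clades": Path(f"{prefix}.clades.tsv"),
        "cysteines": Path(f"{prefix}.cysteines.tsv"),
        "columns": Path(f"{prefix}.columns.tsv"),
        "motifs": Path(f"{prefix}.motifs.tsv"),
    }
    write_fasta(records, paths["fasta"])
    write_fasta(
        [ProteinRecord(id=i, seq=alignment.row(i)) for i in alignment.ids],
        paths["alignment"],
    )
    paths["newick"].write_text(truth.newick + "\n")
    with open(paths["clades"], "w") as fh:
        fh.write("row_id\tclade\n")
        for name, ids in truth.clades.items():
            for t in ids:
                fh.write(f"{t}\t{name}\n")
    with open(paths["cysteines"], "w") as fh:
        fh.write(
            "column\tscope\tpresence_target\tlabel_reference_group\t"
            "label_reference_clade\tlabel_family\tflank_planted\trows_with_c\n"
        )
        for ct in truth.cysteines:
            fh.write(
                f"{ct.column}\t{ct.scope}\t{ct.presence_target}\t"
                f"{ct.label_reference_group}\t{ct.label_reference_clade}\t"
                f"{ct.label_family}\t{ct.flank_planted}\t"
                f"{';'.join(ct.rows_with_c)}\n"
            )
    with open(paths["columns"], "w") as fh:
        fh.write("column\tclass\n")
        for col, klass in sorted(truth.column_classes.items()):
            fh.write(f"{col}\t{klass}\n")
    with open(paths["motifs"], "w") as fh:
        fh.write("row_id\tmotif\tstart_column\n")
        for rid, name, col in truth.motifs:
            fh.write(f"{rid}\t{name}\t{col}\n")
    return paths
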