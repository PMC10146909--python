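"""End-to-end orchestration: filter -> tree -> conservation -> cysteine code.

The pipeline composes the analysis stages on user-supplied files and writes
all reports as tab-separated UTF-8 with a JSON manifest (thresholds, seed,
output checksums).  Re-running with the same inputs, configuration and seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
from skbio import TreeNode

from . import __version__
from .conservation import bimodal_positions, column_profile, penalty_report
from .cyscode import (
    BUILTIN_MOTIFS,
    KEAP1_DOMAINS,
    build_cysteine_report,
    cysteine_spacing_histogram,
    map_reference_positions,
    motif_scan_alignment,
)
from .family_select import ArchitectureRule, filter_by_architecture
from .io_formats import (
    read_alignment,
    read_domain_table,
    read_fasta,
    write_fasta,
)
from .phylo import (
    BlockSelection,
    bootstrap_support,
    select_conserved_blocks,
    write_newick,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds of a full run.

    ``alignment`` is required.  ``clades`` may be a TSV (row_id, clade); when
    absent the tree is cut into ``n_clades`` groups at its longest internal
    edges.
    """

    alignment: str
    out_dir: str
    reference_id: str | None = None
    seqs: str | None = None
    hits: str | None = None
    hits_dialect: str = "tsv"
    clades: str | None = None
    domains: str | None = None
    annotations: str | None = None
    skip_tree: bool = False
    n_clades: int = 5
    # architecture thresholds (loose architecture-check defaults)
    btb_evalue: float = 0.1
    back_evalue: float = 0.1
    kelch_evalue: float = 0.1
    min_kelch: int = 1
    # block selection
    auto_blocks: bool = True
    min_rank: float = 0.5
    max_gap_fraction: float = 0.2
    min_block_len: int = 3
    # tree
    bootstrap_reps: int = 100
    # conservation / cysteine code
    theta: float = 0.8
    yes_threshold: float = 0.9
    partial_threshold: float = 0.5
    alignable_threshold: float = 0.5
    flank_window: int = 1
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def clades_from_tree(tree: TreeNode, k: int) -> dict[str, tuple[str, ...]]:
    """Cut a tree into ``k`` leaf groups at its longest internal edges.

    The ``k - 1`` longest internal edges are removed; each resulting connected
    component of leaves becomes a clade.  Clades are named ``clade1..k`` in
    order of their lexicographically smallest member.
    """
    internals = [n for n in tree.non_tips(include_self=False) if n.length is not None]
    internals.sort(key=lambda n: -n.length)
    cuts = set(id(n) for n in internals[: max(k - 1, 0)])

    groups: dict[int, list[str]] = {}
    for tip in tree.tips():
        anchor = 0
        node = tip.parent
        while node is not None:
            if id(node) in cuts:
                anchor = id(node)
                break
            node = node.parent
        groups.setdefault(anchor, []).append(tip.name)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    return {f"clade{i + 1}": tuple(sorted(g)) for i, g in enumerate(ordered)}


def read_clades_tsv(path: str | Path) -> dict[str, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["clade"]), []).append(str(row["row_id"]))
    return {k: tuple(v) for k, v in out.items()}


def read_domains_tsv(path: str | Path) -> tuple[tuple[str, int, int], ...]:
    df = pd.read_csv(path, sep="\t")
    return tuple(
        (str(r["domain"]), int(r["start"]), int(r["end"])) for _, r in df.iterrows()
    )


def read_annotations_tsv(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path, sep="\t")
    return {int(r["position"]): str(r["studied"]) for _, r in df.iterrows()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def _stage(name: str):
        logger.info("stage %s", name)

    # --- family selection (optional) --------------------------------------
    if config.hits is not None:
        _stage("filter")
        hits = read_domain_table(config.hits, config.hits_dialect)
        rule = ArchitectureRule(
            btb_max_evalue=config.btb_evalue,
            back_max_evalue=config.back_evalue,
            kelch_max_evalue=config.kelch_evalue,
            min_kelch_hits=config.min_kelch,
        )
        protein_ids = None
        if config.seqs is not None:
            protein_ids = [r.id for r in read_fasta(config.seqs)]
        accepted, rejections = filter_by_architecture(hits, rule, protein_ids)
        rej_path = out / "rejections.tsv"
        with open(rej_path, "w") as fh:
            fh.write("protein_id\treason\n")
            for pid in sorted(rejections):
                fh.write(f"{pid}\t{rejections[pid]}\n")
        outputs["rejections"] = rej_path
        if config.seqs is not None:
            keep = [r for r in read_fasta(config.seqs) if r.id in set(accepted)]
            acc_path = out / "accepted.fasta"
            write_fasta(keep, acc_path)
            outputs["accepted"] = acc_path

    # --- alignment and blocks ---------------------------------------------
    _stage("alignment")
    alignment = read_alignment(config.alignment)
    reference_id = config.reference_id or alignment.ids[0]

    if config.auto_blocks:
        blocks = select_conserved_blocks(
            alignment, config.min_rank, config.max_gap_fraction, config.min_block_len
        )
        if len(blocks) == 0:
            blocks = BlockSelection(tuple(range(1, alignment.n_cols + 1)))
    else:
        blocks = BlockSelection(tuple(range(1, alignment.n_cols + 1)))

    # --- tree --------------------------------------------------------------
    clades: dict[str, tuple[str, ...]] | None = None
    if config.clades is not None:
        clades = read_clades_tsv(config.clades)
    if not config.skip_tree:
        _stage("tree")
        tree, n_eff, n_skipped = bootstrap_support(
            alignment, list(blocks), n_reps=config.bootstrap_reps, seed=config.seed
        )
        tree_path = out / "tree.nwk"
        write_newick(tree, tree_path)
        outputs["tree"] = tree_path
        if clades is None:
            clades = clades_from_tree(tree, config.n_clades)
    if clades is None:
        raise ValueError("clade assignments required when the tree stage is skipped")
    clades_path = out / "clades.tsv"
    with open(clades_path, "w") as fh:
        fh.write("row_id\tclade\n")
        for name in sorted(clades):
            for rid in clades[name]:
                fh.write(f"{rid}\t{name}\n")
    outputs["clades"] = clades_path

    # --- conservation -------------------------------------------------------
    _stage("conservation")
    profiles = pd.DataFrame(
        [
            {
                "column": p.column,
                "top_residue": p.top_residue or "",
                "rank": round(p.rank, 6),
                "class": p.klass,
                "gap_count": p.gap_count,
                "selected": p.column in set(blocks),
            }
            for p in (
                column_profile(alignment, c) for c in range(1, alignment.n_cols + 1)
            )
        ]
    )
    prof_path = out / "profiles.tsv"
    profiles.to_csv(prof_path, sep="\t", index=False)
    outputs["profiles"] = prof_path

    penalties = penalty_report(alignment, list(blocks), reference_id=reference_id)
    pen_path = out / "penalties.tsv"
    penalties.to_csv(pen_path, sep="\t", index=False, float_format="%.6f")
    outputs["penalties"] = pen_path

    bimodal = bimodal_positions(alignment, clades, theta=config.theta)
    bim_path = out / "bimodal.tsv"
    with open(bim_path, "w") as fh:
        fh.write("column\tresidue_1\tclade_1\tresidue_2\tclade_2\n")
        for row in bimodal:
            fh.write("\t".join(str(x) for x in row) + "\n")
    outputs["bimodal"] = bim_path

    # --- cysteine code ------------------------------------------------------
    _stage("cyscode")
    domains = (
        read_domains_tsv(config.domains) if config.domains is not None else KEAP1_DOMAINS
    )
    annotations = (
        read_annotations_tsv(config.annotations) if config.annotations else None
    )
    main, missing = build_cysteine_report(
        alignment,
        reference_id,
        clades,
        domains=domains,
        window=config.flank_window,
        yes_threshold=config.yes_threshold,
        partial_threshold=config.partial_threshold,
        alignable_threshold=config.alignable_threshold,
        annotations=annotations,
    )
    cys_path = out / "cysteine_report.tsv"
    main.to_csv(cys_path, sep="\t", index=False, float_format="%.6f")
    outputs["cysteine_report"] = cys_path
    miss_path = out / "cysteine_missing.tsv"
    missing.to_csv(miss_path, sep="\t", index=False, float_format="%.6f")
    outputs["cysteine_missing"] = miss_path

    pmap = map_reference_positions(alignment, reference_id)
    motif_rows = []
    for name, pattern in BUILTIN_MOTIFS.items():
        for rid in alignment.ids:
            motif_rows.extend(motif_scan_alignment(alignment, rid, pattern, pmap))
    motifs_df = pd.DataFrame(
        motif_rows, columns=["row_id", "motif", "start", "end", "ref_start", "ref_end"]
    )
    motif_path = out / "motifs.tsv"
    motifs_df.to_csv(motif_path, sep="\t", index=False)
    outputs["motifs"] = motif_path

    spacing = cysteine_spacing_histogram(alignment.degapped(reference_id))
    spacing_path = out / "cysteine_spacing.tsv"
    with open(spacing_path, "w") as fh:
        fh.write("spacing\tcount\n")
        for k, v in spacing.items():
            fh.write(f"{k}\t{v}\n")
    outputs["cysteine_spacing"] = spacing_path

    # --- manifest -----------------------------------------------------------
    manifest = {
        "package": "klhlkit",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_rows": alignment.n_rows,
        "n_cols": alignment.n_cols,
        "n_selected_columns": len(blocks),
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
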