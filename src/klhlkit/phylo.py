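"""Neighbor-joining phylogeny with JTT maximum-likelihood distances.

Pairwise distances are ML estimates under the embedded JTT model (uniform
rates across sites, pairwise deletion of columns with a gap or ``X`` in either
row).  Trees are built with the Saitou–Nei neighbor-joining agglomeration and
carry bootstrap support computed by resampling the selected columns with
replacement.  Trees are scikit-bio :class:`~skbio.tree.TreeNode` objects, so
they interoperate with the wider ecosystem; Newick is the on-disk format, with
supports stored as internal node labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from . import substitution
from .conservation import column_profile
from .io_formats import Alignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockSelection:
    """An ordered set of selected alignment columns (1-based, strictly increasing)."""

    columns: tuple[int, ...]

    def __post_init__(self) -> None:
        cols = self.columns
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("columns must be strictly increasing")
        if cols and cols[0] < 1:
            raise ValueError("columns are 1-based")

    def __len__(self) -> int:
        return len(self.columns)

    def __iter__(self):
        return iter(self.columns)


def _encode_rows(alignment: Alignment, columns: Sequence[int] | None) -> dict[str, np.ndarray]:
    if columns is not None:
        idx = np.asarray(list(columns), dtype=np.int64) - 1
    else:
        idx = np.arange(alignment.n_cols)
    return {i: substitution.encode(alignment.row(i))[idx] for i in alignment.ids}


def jtt_distance(
    row_a: str,
    row_b: str,
    columns: Sequence[int] | None = None,
    t_max: float = 10.0,
) -> float:
    """ML JTT distance between two gapped rows (expected substitutions/site).

    Columns with a gap or ``X`` in either row are excluded (pairwise
    deletion).  Raises ``ValueError("no shared sites")`` if nothing remains.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have identical length")
    a = substitution.encode(row_a)
    b = substitution.encode(row_b)
    if columns is not None:
        idx = np.asarray(list(columns), dtype=np.int64) - 1
        a, b = a[idx], b[idx]
    counts = substitution.pair_counts(a, b)
    return substitution.ml_distance(counts, t_max=t_max)


def jtt_distance_matrix(
    alignment: Alignment,
    columns: Sequence[int] | None = None,
    t_max: float = 10.0,
) -> DistanceMatrix:
    """Symmetric matrix of pairwise ML JTT distances over selected columns."""
    enc = _encode_rows(alignment, columns)
    ids = alignment.ids
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            counts = substitution.pair_counts(enc[ids[i]], enc[ids[j]])
            try:
                d[i, j] = d[j, i] = substitution.ml_distance(counts, t_max=t_max)
            except ValueError:
                raise ValueError(
                    f"no shared sites between {ids[i]} and {ids[j]}"
                ) from None
    return DistanceMatrix(d, ids)


# --- neighbor joining ------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix | tuple[Sequence[str], np.ndarray]) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Accepts a scikit-bio DistanceMatrix (or ``(ids, array)``; the array must
    be symmetric with zero diagonal).  Negative branch-length estimates are
    clamped to zero.  Ties in the Q criterion are broken by the
    lexicographically smallest pair of cluster keys (a cluster's key is its
    smallest leaf name), which makes the result independent of input order.
    The returned tree is the conventional unrooted representation: a root with
    three children for >= 3 taxa, two children (half the distance each) for 2.
    """
    if isinstance(dm, DistanceMatrix):
        ids, d = list(dm.ids), dm.data.astype(float).copy()
    else:
        ids, d = list(dm[0]), np.asarray(dm[1], dtype=float).copy()
        if d.shape[0] != d.shape[1] or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    keys: list[str] = list(ids)

    if n == 2:
        for node in nodes:
            node.length = d[0, 1] / 2.0
        root = TreeNode(children=nodes)
        return root

    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        q = np.minimum(q, q.T)  # enforce exact symmetry against round-off
        q[np.tril_indices(r)] = np.inf
        qmin = q.min()
        ties = np.argwhere(q <= qmin)
        best = min(
            (tuple(sorted((keys[active[i]], keys[active[j]]))), i, j)
            for i, j in ties
        )
        _, ai, aj = best
        i_glob, j_glob = active[ai], active[aj]
        dij = d[i_glob, j_glob]
        vi = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2 * (r - 2))
        vj = dij - vi
        child_i, child_j = nodes[i_glob], nodes[j_glob]
        child_i.length = max(vi, 0.0)
        child_j.length = max(vj, 0.0)
        new_node = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining clusters
        new_d = np.zeros(len(d) + 1)
        for ak in active:
            if ak in (i_glob, j_glob):
                continue
            new_d[ak] = 0.5 * (d[i_glob, ak] + d[j_glob, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_d[:-1]
        d[:-1, -1] = new_d[:-1]
        nodes.append(new_node)
        keys.append(min(keys[i_glob], keys[j_glob]))
        active = [a for a in active if a not in (i_glob, j_glob)] + [len(d) - 1]

    # join the final three clusters at the (unrooted) root
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(length, 0.0)
    order = sorted(((keys[a], a), (keys[b], b), (keys[c], c)))
    return TreeNode(children=[nodes[idx] for _, idx in order])


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree as normalised leaf sets.

    Each internal edge splits the taxa in two; the side *not* containing the
    lexicographically smallest taxon represents the bipartition, so the set is
    rooting-invariant.
    """
    taxa = frozenset(t.name for t in tree.tips())
    anchor = min(taxa)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            parts.add(side)
    return parts


def bootstrap_support(
    alignment: Alignment,
    columns: Sequence[int],
    n_reps: int = 100,
    seed: int = 0,
    t_max: float = 10.0,
) -> tuple[TreeNode, int, int]:
    """NJ tree with bootstrap supports on internal nodes.

    The selected columns are resampled with replacement ``n_reps`` times; each
    replicate's distances and NJ tree are recomputed, and each internal node
    of the point-estimate tree receives the percentage of replicates containing
    its bipartition (attribute ``support``, 0-100).  Replicates in which some
    pair has no comparable sites are skipped and counted; the effective
    denominator is returned.

    Returns ``(tree, n_effective, n_skipped)``.  Identical seeds give
    identical output.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cols = np.asarray(list(columns), dtype=np.int64)
    if cols.size == 0:
        raise ValueError("no columns selected")
    rng = np.random.default_rng(seed)

    point_tree = neighbor_joining(jtt_distance_matrix(alignment, cols, t_max=t_max))
    taxa = frozenset(alignment.ids)
    anchor = min(taxa)

    counts: dict[frozenset[str], int] = {}
    n_skipped = 0
    for _ in range(n_reps):
        sampled = cols[rng.integers(0, cols.size, size=cols.size)]
        try:
            rep_dm = jtt_distance_matrix(alignment, sampled, t_max=t_max)
        except ValueError as exc:
            logger.warning("bootstrap replicate skipped: %s", exc)
            n_skipped += 1
            continue
        for part in bipartitions(neighbor_joining(rep_dm)):
            counts[part] = counts.get(part, 0) + 1
    n_eff = n_reps - n_skipped
    if n_eff == 0:
        raise ValueError("all bootstrap replicates were skipped")

    for node in point_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        node.support = round(100.0 * counts.get(side, 0) / n_eff)
    return point_tree, n_eff, n_skipped


def select_conserved_blocks(
    alignment: Alignment,
    min_rank: float = 0.5,
    max_gap_fraction: float = 0.2,
    min_block_len: int = 3,
) -> BlockSelection:
    """Automated stand-in for manual conserved-block selection.

    Keeps columns whose gap fraction is at most ``max_gap_fraction`` and whose
    top-residue rank is at least ``min_rank``, then drops runs of qualifying
    columns shorter than ``min_block_len``.  Deterministic; may return an
    empty selection.
    """
    qualifying = []
    for c in range(1, alignment.n_cols + 1):
        prof = column_profile(alignment, c)
        gap_frac = prof.gap_count / prof.n_rows
        qualifying.append(gap_frac <= max_gap_fraction and prof.rank >= min_rank)
    selected: list[int] = []
    run: list[int] = []
    for c, ok in enumerate(qualifying, start=1):
        if ok:
            run.append(c)
        else:
            if len(run) >= min_block_len:
                selected.extend(run)
            run = []
    if len(run) >= min_block_len:
        selected.extend(run)
    return BlockSelection(tuple(selected))


# --- Newick I/O ------------------------------------------------------------

def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write Newick with integer supports as internal node labels."""
    out = tree.copy()
    for node in out.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is not None:
            node.name = str(int(support))
    out.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    """Read Newick; numeric internal labels are interpreted as supports."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.non_tips(include_self=False):
        if node.name is not None:
            try:
                node.support = int(float(node.name))
            except ValueError:
                pass
    return tree
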