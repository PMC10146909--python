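import numpy as np
import pytest

from klhlkit.io_formats import Alignment
from klhlkit.synthetic_data import FamilyConfig, generate_family


@pytest.fixture(scope="session")
def default_family():
    """One simulated 5-clade / 40-taxon family reused across test modules."""
    config = FamilyConfig(seed=1)
    records, alignment, truth = generate_family(config)
    return records, alignment, truth


@pytest.fixture()
def toy_alignment():
    """4 rows x 6 columns with known column statistics.

    Columns (1-based): 1 "AAAA", 2 "AAAB", 3 "AABB", 4 "AAA-", 5 "ABCD",
    6 "----".
    """
    rows = [
        "AAAAA-",
        "AAAAB-",
        "AABAC-",
        "ABB-D-",
    ]
    return Alignment(["r1", "r2", "r3", "r4"], rows)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random binary tree and its exact leaf-to-leaf path-length matrix.

    Independent of the package's tree code: clusters are joined in random
    order and path lengths are accumulated per leaf, so additivity holds by
    construction.
    """
    taxa = [f"T{i}" for i in range(n_taxa)]
    # each cluster: (leaf set, dict leaf -> distance to cluster root)
    clusters = [({t}, {t: 0.0}) for t in taxa]
    joins = []
    d = {t: {} for t in taxa}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (leaves_i, depth_i) = clusters[i]
        (leaves_j, depth_j) = clusters[j]
        bi = float(rng.uniform(0.05, 0.5))
        bj = float(rng.uniform(0.05, 0.5))
        for a in leaves_i:
            for b in leaves_j:
                dist = depth_i[a] + bi + depth_j[b] + bj
                d[a][b] = dist
                d[b][a] = dist
        merged = leaves_i | leaves_j
        depth = {a: depth_i[a] + bi for a in leaves_i}
        depth.update({b: depth_j[b] + bj for b in leaves_j})
        joins.append((frozenset(leaves_i), frozenset(leaves_j)))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, depth))
    mat = np.zeros((n_taxa, n_taxa))
    for a_idx, a in enumerate(taxa):
        for b_idx, b in enumerate(taxa):
            if a != b:
                mat[a_idx, b_idx] = d[a][b]
    # non-trivial bipartitions implied by the joins
    all_leaves = frozenset(taxa)
    parts = set()
    anchor = min(taxa)
    for side_a, side_b in joins:
        for side in (side_a, side_b):
            norm = all_leaves - side if anchor in side else side
            if 2 <= len(norm) <= n_taxa - 2:
                parts.add(norm)
    return taxa, mat, parts
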