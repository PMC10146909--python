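import numpy as np
import pytest
from scipy.linalg import expm
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from klhlkit import substitution
from klhlkit.io_formats import Alignment
from klhlkit.phylo import (
    BlockSelection,
    bipartitions,
    bootstrap_support,
    jtt_distance,
    neighbor_joining,
    read_newick,
    select_conserved_blocks,
    write_newick,
)

from conftest import random_additive_tree

AA = substitution.AA_ORDER


# --- independent grid-search oracle for the ML distance --------------------

def grid_ml_distance(row_a: str, row_b: str, step: float = 1e-4) -> float:
    """Brute-force grid maximisation of the per-site JTT log-likelihood.

    Uses scipy's expm directly and a per-site sum (no count matrix, no
    eigendecomposition), so it shares no code path with the implementation.
    A coarse pass brackets the optimum, then the stated fine grid is applied
    inside the bracket.
    """
    q = substitution.JTT_RATE_MATRIX
    pi = substitution.JTT_FREQS
    pairs = [
        (AA.index(a), AA.index(b))
        for a, b in zip(row_a, row_b)
        if a in AA and b in AA
    ]

    def ll(t):
        p = expm(q * t)
        return sum(np.log(pi[i] * p[i, j]) for i, j in pairs)

    coarse = np.arange(step, 5.0, 0.01)
    t0 = coarse[int(np.argmax([ll(t) for t in coarse]))]
    fine = np.arange(max(step, t0 - 0.02), t0 + 0.02, step)
    return float(fine[int(np.argmax([ll(t) for t in fine]))])


def _mutated_pair(rng, length=100, n_diff=10):
    base = "".join(rng.choice(list(AA), size=length))
    sites = rng.choice(length, size=n_diff, replace=False)
    other = list(base)
    for s in sites:
        choices = [a for a in AA if a != base[s]]
        other[s] = choices[int(rng.integers(len(choices)))]
    return base, "".join(other)


def test_jtt_distance_identical_rows_is_zero():
    assert jtt_distance("ACDEF" * 10, "ACDEF" * 10) == 0.0


def test_jtt_distance_matches_grid_search_oracle():
    rng = np.random.default_rng(42)
    a, b = _mutated_pair(rng, length=100, n_diff=10)
    assert jtt_distance(a, b) == pytest.approx(grid_ml_distance(a, b), abs=1e-3)


def test_jtt_distance_symmetric():
    rng = np.random.default_rng(7)
    a, b = _mutated_pair(rng, length=80, n_diff=25)
    assert jtt_distance(a, b) == pytest.approx(jtt_distance(b, a), abs=1e-9)


def test_jtt_distance_monotone_in_nested_difference_sets():
    rng = np.random.default_rng(11)
    base = "".join(rng.choice(list(AA), size=120))
    prev = 0.0
    other = list(base)
    sites = rng.choice(120, size=40, replace=False)
    for k in (5, 10, 20, 40):
        for s in sites[:k]:
            if other[s] == base[s]:
                other[s] = [a for a in AA if a != base[s]][0]
        d = jtt_distance(base, "".join(other))
        assert d >= prev - 1e-9
        prev = d


def test_jtt_distance_pairwise_deletion_and_no_shared_sites():
    # gap/X columns are excluded: distance equals the gap-free pair
    assert jtt_distance("AC-DX", "ACWDY") == jtt_distance("ACD", "ACD")
    with pytest.raises(ValueError, match="no shared sites"):
        jtt_distance("--A", "AX-")


def test_jtt_distance_saturation_warns_and_caps():
    # maximally divergent short pair: optimum runs into the bound
    a = "ACDEFGHIKL" * 2
    b = "LKIHGFEDCA" * 2
    with pytest.warns(UserWarning, match="saturated"):
        d = jtt_distance(a, b, t_max=2.0)
    assert d == 2.0


def test_nj_two_taxa_single_edge():
    tree = neighbor_joining(DistanceMatrix([[0, 0.3], [0.3, 0]], ["A", "B"]))
    dist = tree.find("A").distance(tree.find("B"))
    assert dist == pytest.approx(0.3)


def test_nj_three_taxa_closed_form():
    d = DistanceMatrix([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]], list("ABC"))
    tree = neighbor_joining(d)
    # b_A = (d_AB + d_AC - d_BC)/2 etc.
    assert tree.find("A").length == pytest.approx(0.1)
    assert tree.find("B").length == pytest.approx(0.3)
    assert tree.find("C").length == pytest.approx(0.5)


def test_nj_four_taxa_recovers_generating_tree():
    # tree ((A:0.1,B:0.3):0.1,(C:0.2,D:0.2)) -> additive distances
    ids = list("ABCD")
    d = np.array(
        [
            [0.0, 0.4, 0.4, 0.4],
            [0.4, 0.0, 0.6, 0.6],
            [0.4, 0.6, 0.0, 0.4],
            [0.4, 0.6, 0.4, 0.0],
        ]
    )
    tree = neighbor_joining(DistanceMatrix(d, ids))
    assert frozenset("AB") in bipartitions(tree) or frozenset("CD") in bipartitions(tree)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                    d[i, j], abs=1e-10
                )


@pytest.mark.parametrize("n_taxa", [5, 8, 12])
def test_nj_exact_on_random_additive_matrices(n_taxa):
    rng = np.random.default_rng(100 + n_taxa)
    for _ in range(3):
        taxa, mat, true_parts = random_additive_tree(n_taxa, rng)
        tree = neighbor_joining(DistanceMatrix(mat, taxa))
        assert bipartitions(tree) == true_parts
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                        mat[i, j], abs=1e-10
                    )


def test_nj_topology_agrees_with_skbio_reference():
    rng = np.random.default_rng(5)
    taxa, mat, _ = random_additive_tree(7, rng)
    mat = mat + rng.uniform(0, 0.01, size=mat.shape)
    mat = 0.5 * (mat + mat.T)
    np.fill_diagonal(mat, 0.0)
    dm = DistanceMatrix(mat, taxa)
    ours = bipartitions(neighbor_joining(dm))
    reference = bipartitions(skbio_nj(dm))
    assert ours == reference


def test_nj_rejects_asymmetric_input():
    with pytest.raises(ValueError):
        neighbor_joining((["A", "B", "C"], np.array([[0, 1, 2], [1, 0, 3], [2.5, 3, 0]])))


def test_nj_deterministic_under_relabelled_order():
    rng = np.random.default_rng(3)
    taxa, mat, _ = random_additive_tree(6, rng)
    dm = DistanceMatrix(mat, taxa)
    perm = list(reversed(range(len(taxa))))
    dm2 = DistanceMatrix(mat[np.ix_(perm, perm)], [taxa[i] for i in perm])
    assert bipartitions(neighbor_joining(dm)) == bipartitions(neighbor_joining(dm2))


# --- conserved block selection ---------------------------------------------

def test_blocks_fully_conserved_alignment_selects_all():
    aln = Alignment(["a", "b"], ["AAAA", "AAAA"])
    assert list(select_conserved_blocks(aln, 0.9, 0.2, 1)) == [1, 2, 3, 4]


def test_blocks_all_gap_column_never_selected():
    aln = Alignment(["a", "b"], ["A-A", "A-A"])
    assert list(select_conserved_blocks(aln, 0.9, 0.2, 1)) == [1, 3]


def test_blocks_short_runs_dropped():
    # qualifying columns 2,3,4 (run of 3) and 7 (run of 1)
    aln = Alignment(["a", "b"], ["AAAAAAAAAA", "BAAABBABBB"])
    assert list(select_conserved_blocks(aln, 0.9, 0.2, 3)) == [2, 3, 4]


def test_block_selection_requires_increasing_columns():
    with pytest.raises(ValueError):
        BlockSelection((3, 2))


# --- bootstrap --------------------------------------------------------------

def _two_clade_alignment():
    # two 3-taxon clades differing at half the columns
    length = 60
    a_row = "A" * length
    b_row = "C" * (length // 2) + "A" * (length - length // 2)
    rows = {
        "a1": a_row, "a2": a_row, "a3": a_row,
        "b1": b_row, "b2": b_row, "b3": b_row,
    }
    return Alignment(list(rows), list(rows.values()))


def test_bootstrap_planted_clade_gets_high_support():
    aln = _two_clade_alignment()
    tree, n_eff, n_skipped = bootstrap_support(
        aln, list(range(1, 61)), n_reps=100, seed=0
    )
    assert n_skipped == 0 and n_eff == 100
    supports = {
        frozenset(t.name for t in node.tips()): node.support
        for node in tree.non_tips(include_self=False)
    }
    clade_support = max(
        s for part, s in supports.items()
        if part in (frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2", "b3"}))
    )
    assert clade_support >= 95


def test_bootstrap_single_replicate_supports_are_0_or_100():
    aln = _two_clade_alignment()
    tree, _, _ = bootstrap_support(aln, list(range(1, 61)), n_reps=1, seed=1)
    for node in tree.non_tips(include_self=False):
        assert node.support in (0, 100)


def test_bootstrap_same_seed_identical_supports():
    aln = _two_clade_alignment()
    t1, _, _ = bootstrap_support(aln, list(range(1, 61)), n_reps=20, seed=9)
    t2, _, _ = bootstrap_support(aln, list(range(1, 61)), n_reps=20, seed=9)
    s1 = sorted(n.support for n in t1.non_tips(include_self=False))
    s2 = sorted(n.support for n in t2.non_tips(include_self=False))
    assert s1 == s2


def test_newick_round_trip_preserves_lengths_and_supports(tmp_path):
    aln = _two_clade_alignment()
    tree, _, _ = bootstrap_support(aln, list(range(1, 61)), n_reps=10, seed=2)
    p = tmp_path / "t.nwk"
    write_newick(tree, p)
    back = read_newick(p)
    assert bipartitions(back) == bipartitions(tree)
    for a in ("a1", "b3"):
        for b in ("a2", "b1"):
            assert back.find(a).distance(back.find(b)) == pytest.approx(
                tree.find(a).distance(tree.find(b)), abs=1e-9
            )
    orig = {
        frozenset(t.name for t in n.tips()): n.support
        for n in tree.non_tips(include_self=False)
    }
    readback = {
        frozenset(t.name for t in n.tips()): getattr(n, "support", None)
        for n in back.non_tips(include_self=False)
    }
    for part, s in readback.items():
        if s is not None:
            assert orig[part] == s
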