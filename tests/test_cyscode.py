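import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from klhlkit.cyscode import (
    BUILTIN_MOTIFS,
    KEAP1_DOMAINS,
    LABEL_NO,
    LABEL_NOT_ALIGNABLE,
    LABEL_PARTIALLY,
    LABEL_YES,
    MotifPattern,
    basic_flank_scan,
    build_cysteine_report,
    classify_group_conservation,
    cysteine_spacing_histogram,
    domain_label,
    map_reference_positions,
    motif_scan,
    motif_scan_alignment,
)
from klhlkit.io_formats import Alignment

AA = "ACDEFGHIKLMNPQRSTVWY"


# --- position map -----------------------------------------------------------

def test_position_map_with_gaps():
    aln = Alignment(["ref", "o"], ["A-CD", "AACD"])
    pmap = map_reference_positions(aln, "ref")
    assert dict(pmap.items()) == {1: 1, 2: 3, 3: 4}
    assert pmap.position_of(2) is None


def test_position_map_gap_free_identity():
    aln = Alignment(["ref"], ["ACDE"])
    pmap = map_reference_positions(aln, "ref")
    assert dict(pmap.items()) == {1: 1, 2: 2, 3: 3, 4: 4}


def test_position_map_round_trip():
    aln = Alignment(["ref", "o"], ["MK--VC-D", "MKAAVCAD"])
    pmap = map_reference_positions(aln, "ref")
    for pos in range(1, pmap.n_positions + 1):
        assert pmap.position_of(pmap.column_of(pos)) == pos


def test_position_map_unknown_reference():
    aln = Alignment(["a"], ["AC"])
    with pytest.raises(KeyError):
        map_reference_positions(aln, "nope")


# --- group conservation -----------------------------------------------------

def _col_alignment(column: str) -> Alignment:
    ids = [f"r{i}" for i in range(len(column))]
    return Alignment(ids, list(column))


def test_classify_all_cysteine_is_yes():
    aln = _col_alignment("C" * 10)
    label, p, _ = classify_group_conservation(aln, 1, aln.ids)
    assert (label, p) == (LABEL_YES, 1.0)


@pytest.mark.parametrize(
    "column,expected,p_expected",
    [
        ("C" * 9 + "A", LABEL_YES, 0.9),
        ("C" * 7 + "AAA", LABEL_PARTIALLY, 0.7),
        ("C" * 4 + "A" * 6, LABEL_NO, 0.4),
        ("C" * 2 + "-" * 8, LABEL_NOT_ALIGNABLE, 0.2),
    ],
)
def test_classify_threshold_bins(column, expected, p_expected):
    aln = _col_alignment(column)
    label, p, _ = classify_group_conservation(aln, 1, aln.ids)
    assert label == expected
    assert p == pytest.approx(p_expected)


def test_classify_gaps_count_as_absence():
    aln = _col_alignment("CCCCC----C")  # 6 C, 4 gaps: alignable, p = 0.6
    label, p, non_gap = classify_group_conservation(aln, 1, aln.ids)
    assert label == LABEL_PARTIALLY
    assert p == pytest.approx(0.6)
    assert non_gap == pytest.approx(0.6)


def test_classify_monotone_in_presence():
    order = {LABEL_NO: 0, LABEL_PARTIALLY: 1, LABEL_YES: 2}
    prev = -1
    for n_c in range(0, 11):
        aln = _col_alignment("C" * n_c + "A" * (10 - n_c))
        label, _, _ = classify_group_conservation(aln, 1, aln.ids)
        assert order[label] >= prev
        prev = order[label]


def test_classify_empty_group_rejected():
    aln = _col_alignment("CC")
    with pytest.raises(ValueError):
        classify_group_conservation(aln, 1, [])


# --- basic flanks -----------------------------------------------------------

def test_flank_scan_flags_adjacent_lysine():
    hits = basic_flank_scan("ACK", window=1)
    assert [(h.position, h.flanking) for h in hits] == [(2, ((3, "K"),))]


def test_flank_scan_no_basic_neighbors():
    assert basic_flank_scan("ACA", window=1) == []


def test_flank_scan_truncates_at_boundaries():
    hits = basic_flank_scan("CR", window=3)
    assert hits[0].position == 1
    assert hits[0].flanking == ((2, "R"),)


def test_flank_scan_window_validation():
    with pytest.raises(ValueError):
        basic_flank_scan("ACA", window=0)


@settings(max_examples=60, deadline=None)
@given(
    st.text(alphabet=AA, min_size=1, max_size=60),
    st.integers(min_value=1, max_value=4),
)
def test_flank_scan_window_monotonicity(seq, window):
    small = {h.position for h in basic_flank_scan(seq, window)}
    large = {h.position for h in basic_flank_scan(seq, window + 1)}
    assert small <= large


# --- motifs ------------------------------------------------------------------

def test_motif_scan_krr_single_match():
    assert motif_scan("AKRRA", BUILTIN_MOTIFS["KRR"]) == [(2, 4)]


def test_motif_scan_overlapping_matches():
    assert motif_scan("GGG", BUILTIN_MOTIFS["GG"]) == [(1, 2), (2, 3)]


def test_motif_scan_phi_xe_class_token():
    # phi = large hydrophobic; x = any; then E (the M-S-E arrangement)
    assert motif_scan("AMSEA", BUILTIN_MOTIFS["phi-xE"]) == [(2, 4)]
    assert motif_scan("AGSEA", BUILTIN_MOTIFS["phi-xE"]) == []


def test_motif_x_residue_matches_only_wildcards():
    assert motif_scan("KXR", BUILTIN_MOTIFS["KRR"]) == []
    assert motif_scan("YXAGG", BUILTIN_MOTIFS["YxxGG"]) == [(1, 5)]


def test_motif_pattern_parse_and_validation():
    pat = MotifPattern.parse("test", "[HKR]xG")
    assert motif_scan("AHAGA", pat) == [(2, 4)]
    with pytest.raises(ValueError):
        MotifPattern.parse("short", "K")
    with pytest.raises(ValueError):
        MotifPattern.parse("bad", "K?R")


def test_motif_scan_alignment_reports_reference_numbering():
    # the match sits at row positions 2-4 but reference positions 3-5
    aln = Alignment(["ref", "row"], ["AAKRR", "-AKRR"])
    pmap = map_reference_positions(aln, "ref")
    (m,) = motif_scan_alignment(aln, "row", BUILTIN_MOTIFS["KRR"], pmap)
    assert (m["start"], m["end"]) == (2, 4)
    assert (m["ref_start"], m["ref_end"]) == (3, 5)


# --- domain labels -----------------------------------------------------------

def test_domain_label_uses_pfam_btb_boundaries():
    assert domain_label(151, KEAP1_DOMAINS) == "BTB"
    assert domain_label(67, KEAP1_DOMAINS) == "BTB"
    assert domain_label(66, KEAP1_DOMAINS) == "NTR"
    assert domain_label(583, KEAP1_DOMAINS) == "Kelch6"


# --- the report --------------------------------------------------------------

def test_report_matches_planted_truth(default_family):
    _, alignment, truth = default_family
    clades = {k: list(v) for k, v in truth.clades.items()}
    main, missing = build_cysteine_report(
        alignment, truth.reference_id, clades,
        reference_group=truth.reference_group,
    )
    ref_row = alignment.row(truth.reference_id)
    expected_main = {
        ct.column: ct for ct in truth.cysteines
        if truth.reference_id in ct.rows_with_c
    }
    assert set(main["position"]) == set(expected_main)  # no gaps: position == column
    for _, row in main.iterrows():
        ct = expected_main[row["column"]]
        assert row["conserved_in_reference_group"] == ct.label_reference_group
        assert row["conserved_in_clade"] == ct.label_reference_clade
        assert row["conserved_in_family"] == ct.label_family
        assert bool(row["basic_flank"]) == ct.flank_planted
    # every planted column the reference lost shows up in the missing section
    lost = {
        ct.column for ct in truth.cysteines
        if truth.reference_id not in ct.rows_with_c
    }
    assert lost <= set(missing["column"])


def test_report_invariant_to_row_order(default_family):
    _, alignment, truth = default_family
    clades = {k: list(v) for k, v in truth.clades.items()}
    main1, miss1 = build_cysteine_report(
        alignment, truth.reference_id, clades, reference_group=truth.reference_group
    )
    reordered = alignment.subset_rows(sorted(alignment.ids, reverse=True))
    main2, miss2 = build_cysteine_report(
        reordered, truth.reference_id, clades, reference_group=truth.reference_group
    )
    assert main1.equals(main2)
    assert miss1.equals(miss2)


def test_report_reference_without_cysteines_is_empty():
    aln = Alignment(["ref", "o1", "o2"], ["AAA", "ACA", "ACA"])
    main, missing = build_cysteine_report(
        aln, "ref", {"c1": ["ref", "o1", "o2"]},
    )
    assert len(main) == 0
    # the column where the others have C is partially conserved family-wide
    assert list(missing["column"]) == [2]


def test_report_degenerate_single_clade_partition():
    aln = Alignment(["ref", "o1"], ["ACA", "ACA"])
    main, _ = build_cysteine_report(
        aln, "ref", {"all": ["ref", "o1"]}, reference_group=["ref", "o1"]
    )
    (row,) = main.to_dict("records")
    assert row["conserved_in_clade"] == row["conserved_in_family"]
    assert row["conserved_in_reference_group"] == row["conserved_in_family"]


def test_report_requires_covering_partition():
    aln = Alignment(["ref", "o1"], ["ACA", "ACA"])
    with pytest.raises(ValueError, match="cover"):
        build_cysteine_report(aln, "ref", {"c1": ["ref"]})


def test_spacing_histogram_counts_gaps_between_cysteines():
    assert cysteine_spacing_histogram("CAACAAAC") == {3: 1, 4: 1}
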