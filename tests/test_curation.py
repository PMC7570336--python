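"""Outlier screening, consensus/subtype construction and site detection."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from barcauth import curation
from barcauth.curation import (
    build_consensus,
    detect_subtypes,
    filter_outliers,
    find_discriminating_sites,
    pairwise_identity,
    read_panel_table,
    scan_hotspots,
)
from barcauth.errors import DataError
from barcauth.iupac import contains
from barcauth.seqio import MultipleAlignment, SequenceRecord
from barcauth import synthetic


def _recs(seqs, species="Hypericum perforatum"):
    return [SequenceRecord(f"r{i}", s, species=species) for i, s in enumerate(seqs, 1)]


# ---------------------------------------------------------------------------
# outlier filtering


def test_identical_sequences_all_kept():
    kept, dropped = filter_outliers(_recs(["ACGTACGTAC"] * 5))
    assert len(kept) == 5 and not dropped


def test_singleton_outlier_discarded():
    core = "ACGTACGTACGTACGTACGT"  # 20 nt
    outlier = "ACGTTCGTACGAACGTACCT"  # 3 substitutions -> 85% to core
    # oracle: exhaustive pairwise identity matrix
    records = _recs([core, core, core, core, outlier])
    for a, b in itertools.combinations(records[:4], 2):
        assert pairwise_identity(a.sequence, b.sequence) == 1.0
    assert pairwise_identity(core, outlier) < 0.95
    kept, dropped = filter_outliers(records)
    assert [r.id for r in dropped] == ["r5"]
    assert len(kept) == 4


def test_two_distant_sequences_both_kept():
    a = "ACGTACGTACGTACGTACGT"
    b = "ACGTTCGTACGAACGTACCT"
    assert pairwise_identity(a, b) < 0.95
    kept, dropped = filter_outliers(_recs([a, b]))
    assert len(kept) == 2 and not dropped


def test_filter_outliers_idempotent():
    core = "ACGTACGTACGTACGTACGT"
    outlier = "TTTTACGTACGAACGAACCT"
    kept, _ = filter_outliers(_recs([core, core, core, outlier]))
    kept2, dropped2 = filter_outliers(kept)
    assert [r.id for r in kept2] == [r.id for r in kept] and not dropped2


def test_filter_outliers_empty_input_errors():
    with pytest.raises(DataError):
        filter_outliers([])


# ---------------------------------------------------------------------------
# consensus


@pytest.mark.parametrize(
    "rows,floor,expected",
    [
        (["ACGT", "ACGT"], 0.25, "ACGT"),
        (["ACGT", "ACGA"], 0.25, "ACGW"),
        (["ACGT", "ACGA", "ACGA", "ACGA"], 0.3, "ACGA"),
    ],
)
def test_consensus_frequency_rule(rows, floor, expected):
    assert build_consensus(rows, floor).consensus == expected


def test_consensus_majority_gap_column_dropped():
    cons = build_consensus(["A-GT", "A-GT", "ACGT"], 0.25)
    assert cons.consensus == "AGT"
    assert cons.dropped_columns == [2]


def test_consensus_polymorphic_columns_are_one_based():
    cons = build_consensus(["ACGT", "ACGA"], 0.25)
    assert cons.polymorphic_columns == [4]


@given(st.lists(st.text(alphabet="ACGT", min_size=6, max_size=6), min_size=1, max_size=8))
@settings(derandomize=True, max_examples=60)
def test_consensus_at_zero_floor_contains_every_row(rows):
    cons = build_consensus(rows, ambiguity_floor=0.0).consensus
    for row in rows:
        for code, base in zip(cons, row):
            assert contains(code, base)


# ---------------------------------------------------------------------------
# subtypes


def test_identical_rows_one_subtype():
    subs = detect_subtypes(_recs(["ACGTACGTAC"] * 10), link_identity=0.95)
    assert len(subs) == 1 and subs[0].subtype_label == "I"


def test_planted_templates_recovered_and_order_invariant():
    cfg = synthetic.SimConfig(seed=11, noise_rate=0.0)
    sim = synthetic.generate_panel(cfg)
    rows = sim.alignment.rows_for_species("Hypericum perforatum")
    subs = detect_subtypes(rows, link_identity=0.995)
    templates = sorted(sim.truth.subtype_templates["Hypericum perforatum"].values())
    assert sorted(c.consensus for c in subs) == templates
    shuffled = list(reversed(rows))
    subs2 = detect_subtypes(shuffled, link_identity=0.995)
    assert [(c.subtype_label, c.consensus) for c in subs] == [
        (c.subtype_label, c.consensus) for c in subs2
    ]


def test_disconnected_rows_two_subtypes():
    subs = detect_subtypes(_recs(["AAAAAAAAAA", "TTTTTTTTTT"]), link_identity=0.9)
    assert len(subs) == 2


# ---------------------------------------------------------------------------
# discriminating sites


def _aln(rows_by_species):
    records = []
    for sp, rows in rows_by_species.items():
        for i, s in enumerate(rows, 1):
            records.append(SequenceRecord(f"{sp[:3]}{i}", s, species=sp))
    return MultipleAlignment(records, "toy")


def test_invariant_alignment_empty_report():
    aln = _aln({"tgt": ["AAAA"], "sp2": ["AAAA"], "sp3": ["AAAA"]})
    report = find_discriminating_sites(aln, "tgt")
    assert report.unique_sites == [] and report.pairwise_sites == {}


def test_unique_site_by_brute_force_column_scan():
    aln = _aln({"tgt": ["AAAA"], "sp2": ["AGAA"], "sp3": ["ATAA"]})
    report = find_discriminating_sites(aln, "tgt")
    assert report.unique_sites == [2]
    assert report.pairwise_sites[("sp2", "tgt")] == [2]


def test_column_where_target_subtypes_disagree_excluded():
    aln = _aln({"tgt": ["AAAA", "AGAA"], "sp2": ["ACAA"]})
    report = find_discriminating_sites(aln, "tgt")
    assert 2 not in report.unique_sites


def test_target_absent_errors():
    aln = _aln({"sp2": ["ACGT"]})
    with pytest.raises(DataError):
        find_discriminating_sites(aln, "tgt")


def test_pairwise_but_not_unique_site():
    # column 2 separates tgt from adu but a third species shares the tgt state
    aln = _aln({"tgt": ["AAAA"], "adu": ["AGAA"], "oth": ["AAAA"]})
    report = find_discriminating_sites(aln, "tgt")
    assert 2 not in report.unique_sites
    assert report.pairwise_sites[("adu", "tgt")] == [2]


def test_unique_sites_within_pairwise_union_on_generated_panel():
    sim = synthetic.generate_panel(synthetic.SimConfig(seed=5, noise_rate=0.0))
    target = "Hypericum perforatum"
    report = find_discriminating_sites(sim.alignment, target)
    union = set()
    for (a, b), cols in report.pairwise_sites.items():
        if target in (a, b):
            union |= set(cols)
    assert set(report.unique_sites) <= union


# ---------------------------------------------------------------------------
# hotspots


def test_invariant_alignment_all_zero_scores():
    aln = _aln({"a": ["ACGTACGTACGT"], "b": ["ACGTACGTACGT"]})
    assert all(h.score == 0 for h in scan_hotspots(aln, window=4))


def test_hotspot_window_finds_packed_variation():
    a = ["A"] * 30
    b = list(a)
    for col in (10, 12, 14, 16, 18):  # 1-based 11..19
        b[col] = "G"
    aln = _aln({"x": ["".join(a)], "y": ["".join(b)]})
    hits = scan_hotspots(aln, window=10)
    best = max(hits, key=lambda h: h.score)
    # exhaustive scoring oracle: best window must overlap the packed region
    assert best.start <= 19 and best.end >= 11
    assert best.flagged


def test_window_larger_than_alignment_errors():
    aln = _aln({"a": ["ACGT"]})
    with pytest.raises(DataError):
        scan_hotspots(aln, window=10)
    with pytest.raises(DataError):
        scan_hotspots(aln, window=0)


# ---------------------------------------------------------------------------
# panel metadata


def test_packaged_panel_table_loads():
    panel = synthetic.load_panel_metadata()
    assert len(panel) == 20
    by_name = {p.name: p for p in panel}
    target = by_name["Hypericum perforatum"]
    assert target.section == "Hypericum" and target.meseguer_clade == "E"
    mac = by_name["Hypericum maculatum"]
    assert {"REL", "ADULT"} <= set(mac.flags)
    assert sum("ADULT" in p.flags for p in panel) == 11
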