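"""Ranking, library assembly, construct design, design-matrix arithmetic."""

import pytest

from cwgtscreen.library_design import (
    Candidate,
    Construct,
    SelectionConfig,
    assemble_library,
    design_constructs,
    enumerate_design,
    format_label,
    parse_label,
    rank_bin,
)
from cwgtscreen.seqfeatures import FeatureSummary, Segment, annotate, molecular_weight
from cwgtscreen.seqio import ProteinRecord


def features(n_sequons=0, n_cys=0, tm=None, tail=None, mw=40.0):
    return FeatureSummary(
        sequon_positions=tuple(range(1, n_sequons + 1)),
        cysteine_count=n_cys,
        tm_segments=(Segment(*tm, "TM"),) if tm else (),
        disordered_cterm=Segment(*tail, "DISORDER") if tail else None,
        expected_mw=mw,
    )


def candidate(pid, n_sequons, n_cys, evidence=True, organism="org", bin_index=1):
    return Candidate(
        protein=ProteinRecord(id=pid, residues="M" * 50, organism=organism),
        features=features(n_sequons, n_cys),
        evidence=evidence,
        bin=bin_index,
    )


# --- Label grammar ------------------------------------------------------------

@pytest.mark.parametrize(
    "deletions,label",
    [
        ((), "full-length"),
        (((1, 50),), "Δ1–50"),
        (((1, 91), (393, 457)), "Δ1–91 and Δ393–457"),
    ],
)
def test_label_grammar_round_trip(deletions, label):
    assert format_label(deletions) == label
    assert parse_label(label) == deletions


def test_parse_label_accepts_ascii_hyphen():
    assert parse_label("Δ1-50") == ((1, 50),)


def test_parse_label_rejects_garbage():
    with pytest.raises(ValueError):
        parse_label("delta 1 to 50")


# --- Construct invariants -----------------------------------------------------

def test_construct_rejects_unsorted_or_overlapping_deletions():
    with pytest.raises(ValueError):
        Construct(parent_id="p", deletions=((10, 20), (15, 30)))
    with pytest.raises(ValueError):
        Construct(parent_id="p", deletions=((30, 40), (1, 5)))


def test_retained_residues_applies_deletions():
    parent = ProteinRecord(id="p", residues="ABCDEFGHIK".replace("B", "W"))
    construct = Construct(parent_id="p", deletions=((1, 3), (8, 10)))
    assert construct.retained_residues(parent) == parent.residues[3:7]


def test_retained_residues_full_span_error():
    parent = ProteinRecord(id="p", residues="MKVLI")
    with pytest.raises(ValueError, match="entire"):
        Construct(parent_id="p", deletions=((1, 5),)).retained_residues(parent)


# --- rank_bin -----------------------------------------------------------------

def test_rank_bin_sorts_by_sequons_then_cysteines():
    cands = [
        candidate("a", 0, 3),
        candidate("b", 1, 1),
        candidate("c", 0, 2),
    ]
    assert [c.protein.id for c in rank_bin(cands)] == ["c", "a", "b"]


def test_rank_bin_drops_no_evidence():
    cands = [candidate("a", 0, 0, evidence=False), candidate("b", 5, 9)]
    assert [c.protein.id for c in rank_bin(cands)] == ["b"]


def test_rank_bin_id_tie_break_stable():
    cands = [candidate(pid, 1, 1) for pid in ("z", "m", "a")]
    ranked = rank_bin(cands)
    assert [c.protein.id for c in ranked] == ["a", "m", "z"]
    assert rank_bin(ranked) == ranked


def test_rank_bin_single_candidate():
    cands = [candidate("only", 2, 2)]
    assert rank_bin(cands) == cands


# --- assemble_library ---------------------------------------------------------

def test_assemble_selects_one_per_bin():
    bins = {"a": 1, "b": 2}
    cands = [
        candidate("a", 0, 0, bin_index=1, organism="o1"),
        candidate("b", 0, 0, bin_index=2, organism="o2"),
    ]
    selection = assemble_library(bins, cands)
    assert [c.protein.id for c in selection.selected] == ["a", "b"]
    assert selection.empty_bins == ()


def test_assemble_prefers_unrepresented_organism():
    bins = {"a": 1, "b": 1, "c": 1}
    cands = [
        candidate("a", 0, 0, bin_index=1, organism="maize"),
        candidate("b", 0, 1, bin_index=1, organism="maize"),
        candidate("c", 2, 5, bin_index=1, organism="soy"),
    ]
    selection = assemble_library(bins, cands, per_bin=2)
    assert [c.protein.id for c in selection.selected] == ["a", "c"]


def test_assemble_reports_empty_bins():
    bins = {"a": 1, "b": 2}
    cands = [
        candidate("a", 0, 0, bin_index=1),
        candidate("b", 0, 0, bin_index=2, evidence=False),
    ]
    selection = assemble_library(bins, cands)
    assert [c.protein.id for c in selection.selected] == ["a"]
    assert selection.empty_bins == (2,)


def test_assemble_never_selects_without_evidence():
    bins = {"a": 1}
    cands = [candidate("a", 0, 0, evidence=False)]
    selection = assemble_library(bins, cands)
    assert selection.selected == ()


# --- design_constructs --------------------------------------------------------

def _protein(length=500):
    return ProteinRecord(id="p", residues="MKVLIANSTW" * (length // 10))


def test_design_no_tm_no_tail_full_length_only():
    constructs = design_constructs(_protein(), features())
    assert [c.label for c in constructs] == ["full-length"]


def test_design_n_terminal_truncation():
    constructs = design_constructs(_protein(), features(tm=(7, 29)))
    assert [c.label for c in constructs] == ["full-length", "Δ1–29"]


def test_design_tm_beyond_window_ignored():
    constructs = design_constructs(_protein(), features(tm=(70, 91)))
    assert [c.label for c in constructs] == ["full-length"]


def test_design_tm_and_disordered_tail():
    constructs = design_constructs(
        _protein(), features(tm=(20, 41), tail=(393, 457))
    )
    assert [c.label for c in constructs] == [
        "full-length", "Δ1–41", "Δ1–41 and Δ393–457",
    ]


def test_design_stalk_offset_moves_junction():
    constructs = design_constructs(_protein(), features(tm=(7, 29)), stalk_offset=5)
    assert [c.label for c in constructs] == ["full-length", "Δ1–34"]


def test_design_expected_mw_matches_retained_residues():
    protein = _protein()
    tag = 3000.0
    for construct in design_constructs(
        protein, features(tm=(7, 29), tail=(393, 457)), tag_mass=tag
    ):
        retained = construct.retained_residues(protein)
        expected = molecular_weight(
            ProteinRecord(id="r", residues=retained), tag_mass=tag
        )
        assert construct.expected_mw == pytest.approx(expected, abs=1e-6)


def test_design_consistent_with_annotation():
    # planted type II anchor: predictor output feeds design directly
    seq = "DD" + "LIVF" * 7 + "D" * 200 + "W" * 100
    protein = ProteinRecord(id="p", residues=seq)
    constructs = design_constructs(protein, annotate(protein))
    labels = [c.label for c in constructs]
    assert labels[0] == "full-length"
    assert len(labels) == 2 and labels[1].startswith("Δ1–")


# --- enumerate_design ---------------------------------------------------------

def test_enumerate_published_test_screen_size():
    constructs = [Construct(parent_id=f"c{i}") for i in range(38)]
    points = enumerate_design(
        constructs,
        ["pET55dest", "pET32dest", "pET22dest"],
        ["none", "TF", "KJE", "ELS", "KJE+ELS", "TF+KJE"],
    )
    assert len(points) == 38 * 3 * 6 == 684


def test_enumerate_published_crop_screen_size():
    constructs = [Construct(parent_id=f"c{i}") for i in range(69)]
    points = enumerate_design(constructs, ["pET55dest", "pET22dest"], ["none"])
    assert len(points) == 138


def test_enumerate_order_and_ids_deterministic():
    points = enumerate_design(
        [Construct(parent_id="c1"), Construct(parent_id="c2")], ["v1", "v2"], ["h"]
    )
    assert [p.sample_id for p in points] == ["S0001", "S0002", "S0003", "S0004"]
    assert [(p.construct.parent_id, p.vector) for p in points] == [
        ("c1", "v1"), ("c1", "v2"), ("c2", "v1"), ("c2", "v2"),
    ]


def test_enumerate_single_cell():
    assert len(enumerate_design([Construct(parent_id="c")], ["v"], ["h"])) == 1


def test_enumerate_empty_panel_error():
    with pytest.raises(ValueError):
        enumerate_design([], ["v"], ["h"])
    with pytest.raises(ValueError):
        enumerate_design([Construct(parent_id="c")], [], ["h"])


# --- SelectionConfig ----------------------------------------------------------

def test_config_defaults_are_screen_operating_point():
    config = SelectionConfig()
    assert config.min_identity == 0.40
    assert (config.min_len_ratio, config.max_len_ratio) == (0.85, 1.15)
    assert config.k_bins == 10
    assert config.mw_tolerance == 0.15
    assert (config.purity_cutoff, config.conc_cutoff) == (27.0, 70.0)
    assert config.codon_fold == 5.0


def test_config_yaml_round_trip(tmp_path):
    config = SelectionConfig(k_bins=7, tag_mass=3000.0)
    path = tmp_path / "config.yaml"
    config.to_yaml(path)
    assert SelectionConfig.from_yaml(path) == config


def test_config_rejects_unknown_keys(tmp_path):
    path = tmp_path / "config.yaml"
    path.write_text("bogus_knob: 3\n")
    with pytest.raises(ValueError, match="bogus_knob"):
        SelectionConfig.from_yaml(path)


def test_config_rejects_bad_window():
    with pytest.raises(ValueError):
        SelectionConfig(min_len_ratio=1.2, max_len_ratio=0.9)
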