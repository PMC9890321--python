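"""Annotation hierarchy, TextGrid round trips, and labeling rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocalcomb.annotation_io import (
    AnnotationSet,
    VocalUnit,
    assign_call_group,
    assign_position_category,
    derive_sequences,
    gap_statistics,
    group_into_combinations,
    read_textgrid,
    relabel_segments,
    simplify_call_label,
    write_textgrid,
)
from vocalcomb.errors import FormatError, HierarchyError, LabelError, OrderingError


def assert_units_equal(a: AnnotationSet, b: AnnotationSet, tol: float = 1e-6):
    for lv in ("segment", "call", "combination"):
        ua, ub = a.units[lv], b.units[lv]
        assert len(ua) == len(ub), lv
        for x, y in zip(ua, ub):
            assert x.label == y.label
            assert math.isclose(x.start, y.start, abs_tol=tol)
            assert math.isclose(x.end, y.end, abs_tol=tol)


class TestTextGridRoundTrip:
    def test_write_read_identity(self, tiny_annotation, tmp_path):
        path = tmp_path / "rt.TextGrid"
        write_textgrid(tiny_annotation, path)
        back = read_textgrid(path, tiny_annotation.meta)
        assert_units_equal(tiny_annotation, back)

    def test_counts_preserved(self, tiny_annotation, tmp_path):
        path = tmp_path / "rt.TextGrid"
        write_textgrid(tiny_annotation, path)
        back = read_textgrid(path, tiny_annotation.meta)
        assert len(back.units["segment"]) == 4
        assert len(back.units["call"]) == 2
        assert len(back.units["combination"]) == 1

    def test_missing_tier_is_hierarchy_error(self, tiny_annotation, tmp_path, meta):
        path = tmp_path / "named.TextGrid"
        write_textgrid(tiny_annotation, path, tier_names={"segment": "phones"})
        with pytest.raises(HierarchyError):
            read_textgrid(path, meta)
        # and readable again when the alias is declared
        back = read_textgrid(path, meta, tier_names={"segment": "phones"})
        assert len(back.units["segment"]) == 4

    def test_refuses_overlapping_segments(self, meta, tmp_path):
        segs = [
            VocalUnit(0.1, 0.5, "DS", "segment"),
            VocalUnit(0.3, 0.7, "SH", "segment"),
        ]
        ann = AnnotationSet(meta=meta, units={"segment": segs, "call": [], "combination": []})
        with pytest.raises((OrderingError, HierarchyError)):
            write_textgrid(ann, tmp_path / "bad.TextGrid")

    def test_empty_annotation_round_trips(self, meta, tmp_path):
        ann = AnnotationSet(meta=meta)
        path = write_textgrid(ann, tmp_path / "empty.TextGrid")
        back = read_textgrid(path, meta)
        assert all(not back.units[lv] for lv in back.units)

    def test_malformed_interval_is_format_error(self, tmp_path, meta):
        bad = tmp_path / "bad.TextGrid"
        bad.write_text(
            'File type = "ooTextFile"\nObject class = "TextGrid"\n\n'
            "xmin = 0\nxmax = 1\ntiers? <exists>\nsize = 1\nitem []:\n"
            "    item [1]:\n"
            '        class = "IntervalTier"\n        name = "segment"\n'
            "        xmin = 0\n        xmax = 1\n        intervals: size = 1\n"
            "        intervals [1]:\n            xmin = 0.5\n            xmax = 0.2\n"
            '            text = "DS"\n'
        )
        with pytest.raises(FormatError):
            read_textgrid(bad, meta)

    def test_small_overlap_is_repaired_by_truncation(self, tmp_path, meta):
        """Boundaries intersecting by <= 1 ms are placed where the
        intersection ceases (earlier unit truncated)."""
        ann = AnnotationSet(meta=meta, units={
            "segment": [VocalUnit(0.1, 0.3, "DS", "segment"),
                        VocalUnit(0.3, 0.5, "SH", "segment")],
            "call": [VocalUnit(0.1, 0.5, "c", "call")],
            "combination": [],
        })
        path = write_textgrid(ann, tmp_path / "ok.TextGrid")
        # hand-edit the written grid so DS runs 0.0005 s into SH
        text = path.read_text().replace("xmax = 0.300000", "xmax = 0.300500", 1)
        path.write_text(text)
        back = read_textgrid(path, meta)
        seg = back.units["segment"]
        assert seg[0].end == pytest.approx(0.3, abs=1e-9)
        assert seg[1].start == pytest.approx(0.3, abs=1e-9)


class TestRelabeling:
    @pytest.mark.parametrize(
        "orig,expected", [("HL", "LH"), ("US", "SH"), ("DS", "DS")]
    )
    def test_default_mapping(self, meta, orig, expected):
        ann = AnnotationSet(meta=meta, units={
            "segment": [VocalUnit(0.1, 0.2, orig, "segment")],
            "call": [], "combination": [],
        })
        out = relabel_segments(ann)
        assert out.units["segment"][0].label == expected

    def test_strict_mode_rejects_unknown(self, meta):
        ann = AnnotationSet(meta=meta, units={
            "segment": [VocalUnit(0.1, 0.2, "XX", "segment")],
            "call": [], "combination": [],
        })
        with pytest.raises(LabelError):
            relabel_segments(ann, {"HL": "LH"}, strict=True)


def _calls(times):
    return [VocalUnit(a, b, f"c{i}", "call") for i, (a, b) in enumerate(times)]


class TestGroupIntoCombinations:
    def test_all_gaps_below_threshold_one_combination(self):
        calls = _calls([(0.0, 1.0), (1.1, 2.0), (2.3, 3.0)])  # gaps 0.1, 0.3
        combos = group_into_combinations(calls, threshold=0.5, tolerance=0.0)
        assert len(combos) == 1
        assert combos[0].start == 0.0 and combos[0].end == 3.0

    def test_large_gap_splits_and_single_call_dropped(self):
        calls = _calls([(0.0, 1.0), (1.1, 2.0), (3.2, 4.0)])  # gaps 0.1, 1.2
        combos = group_into_combinations(calls, threshold=0.5, tolerance=0.0)
        assert len(combos) == 1
        assert combos[0].end == 2.0  # third call is discrete

    def test_tolerance_admits_slight_deviation(self):
        # a 0.61 s gap is still joined under threshold 0.5 + tolerance 0.15
        calls = _calls([(0.0, 1.0), (1.61, 2.0)])
        assert len(group_into_combinations(calls, 0.5, 0.15)) == 1
        assert len(group_into_combinations(calls, 0.5, 0.0)) == 0

    def test_single_call_yields_nothing(self):
        assert group_into_combinations(_calls([(0.0, 1.0)])) == []

    def test_unsorted_input_rejected(self):
        calls = [VocalUnit(1.0, 2.0, "b", "call"), VocalUnit(0.0, 0.5, "a", "call")]
        with pytest.raises(OrderingError):
            group_into_combinations(calls)


class TestSequencesAndGaps:
    def test_segment_sequences_per_call(self, tiny_annotation):
        assert derive_sequences(tiny_annotation, "segment") == [
            ["NL", "DS"], ["LH", "DS"],
        ]

    def test_call_group_sequences_per_combination(self, tiny_annotation):
        assert derive_sequences(tiny_annotation, "call") == [
            ["other", "LH-containing"],
        ]

    def test_orphan_segment_raises(self, meta):
        ann = AnnotationSet(meta=meta, units={
            "segment": [VocalUnit(5.0, 5.2, "DS", "segment")],
            "call": [VocalUnit(0.0, 1.0, "c", "call")],
            "combination": [],
        })
        with pytest.raises(HierarchyError):
            derive_sequences(ann, "segment")

    def test_between_segment_gaps(self, tiny_annotation):
        gs = gap_statistics([tiny_annotation], "between-segment")
        assert gs.gaps == pytest.approx([0.02, 0.02])
        assert gs.mean == pytest.approx(0.02) and gs.max == pytest.approx(0.02)

    def test_between_call_gaps_within_combination_only(self, tiny_annotation):
        gs = gap_statistics([tiny_annotation], "between-call")
        assert gs.gaps == pytest.approx([0.3])

    def test_abutting_units_have_zero_gap(self, meta):
        ann = AnnotationSet(meta=meta, units={
            "segment": [VocalUnit(0.1, 0.2, "DS", "segment"),
                        VocalUnit(0.2, 0.3, "SH", "segment")],
            "call": [VocalUnit(0.1, 0.3, "c", "call")],
            "combination": [],
        })
        gs = gap_statistics([ann], "between-segment")
        assert gs.gaps == [0.0]


class TestCallLabels:
    @pytest.mark.parametrize("labels,expected", [
        (["SH", "SH", "SH", "LH"], "SH-LH"),
        (["NL"], "NL"),
        (["DS", "SH", "DS"], "DS-SH-DS"),
    ])
    def test_simplify(self, labels, expected):
        assert simplify_call_label(labels) == expected

    def test_simplify_empty_is_error(self):
        with pytest.raises(ValueError):
            simplify_call_label([])

    @pytest.mark.parametrize("labels,expected", [
        (["SH", "DS", "LH"], "LH-containing"),
        (["SH", "NL", "DS"], "other"),
        (["NL"], "lone-NL"),
        (["NL", "NL"], "other"),
        (["DS"], "other"),
    ])
    def test_call_group(self, labels, expected):
        assert assign_call_group(labels) == expected

    def test_call_group_invalid_label(self):
        with pytest.raises(LabelError):
            assign_call_group(["ZZ"])

    @given(st.lists(st.sampled_from(["DS", "LH", "NL", "SH"]), min_size=1,
                    max_size=7))
    @settings(max_examples=200, deadline=None)
    def test_call_group_partition_is_exhaustive_and_exclusive(self, labels):
        groups = {"LH-containing", "lone-NL", "other"}
        assert assign_call_group(labels) in groups


class TestPositionCategories:
    def test_lh_categories(self, tiny_annotation):
        cats = assign_position_category(tiny_annotation, "LH")
        assert [c for _, c in cats] == ["precedes-DS"]

    def test_lh_call_final(self, meta):
        ann = AnnotationSet(meta=meta, units={
            "segment": [VocalUnit(0.1, 0.2, "DS", "segment"),
                        VocalUnit(0.22, 0.5, "LH", "segment")],
            "call": [VocalUnit(0.1, 0.5, "c", "call")],
            "combination": [],
        })
        assert assign_position_category(ann, "LH")[0][1] == "call-final-or-lone"

    def test_nl_lone_vs_combined(self, meta):
        ann = AnnotationSet(meta=meta, units={
            "segment": [VocalUnit(0.1, 0.3, "NL", "segment"),
                        VocalUnit(1.1, 1.3, "NL", "segment"),
                        VocalUnit(1.32, 1.5, "DS", "segment")],
            "call": [VocalUnit(0.1, 0.3, "c1", "call"),
                     VocalUnit(1.1, 1.5, "c2", "call")],
            "combination": [],
        })
        assert [c for _, c in assign_position_category(ann, "NL")] == [
            "lone", "combined",
        ]

    def test_absent_class_gives_empty_result(self, tiny_annotation):
        assert assign_position_category(tiny_annotation, "SH") == []

    def test_unknown_class_rejected(self, tiny_annotation):
        with pytest.raises(LabelError):
            assign_position_category(tiny_annotation, "QQ")


class TestCorpusRoundTrip:
    def test_parsed_counts_match_manifest(self, small_corpus):
        manifest, _, anns = small_corpus
        assert sum(len(a.units["segment"]) for a in anns) == manifest.n_segments
        assert sum(len(a.units["call"]) for a in anns) == manifest.n_calls
        assert sum(len(a.units["combination"]) for a in anns) == manifest.n_combinations

    def test_sequences_match_generator_ground_truth(self, small_corpus):
        manifest, _, anns = small_corpus
        parsed = [s for a in anns for s in derive_sequences(a, "segment")]
        assert parsed == manifest.segment_sequences()

    def test_combination_span_covers_calls_exactly(self, small_corpus):
        _, _, anns = small_corpus
        for ann in anns:
            for comb in ann.units["combination"]:
                calls = ann.calls_of(comb)
                assert comb.start == pytest.approx(calls[0].start, abs=1e-6)
                assert comb.end == pytest.approx(calls[-1].end, abs=1e-6)
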