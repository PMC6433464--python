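"""Catalogues, barcode parsing/writing, and bout segmentation."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethoseq import (
    Bout,
    BoutSequence,
    Ethogram,
    TrialContext,
    build_catalogue,
    catalogue_preset,
    from_jwatcher_events,
    parse_ethogram,
    segment_bouts,
    write_ethogram,
)
from ethoseq.catalogue import NONE_LABEL

from conftest import make_ethogram


class TestCatalogue:
    @pytest.mark.parametrize(
        "preset",
        ["resident_vs_female", "female_intruder", "resident_vs_male", "male_intruder"],
    )
    def test_presets_have_seven_behaviors(self, preset):
        cat = catalogue_preset(preset)
        assert len(cat) == 7
        roles = [cat.roles[l] for l in cat.labels]
        assert roles.count("interactive") == 4
        assert roles.count("individual") == 3
        assert {"drinking", "grooming", "eating"} <= set(cat.labels)

    def test_resident_female_preset_content(self):
        cat = catalogue_preset("resident_vs_female")
        assert cat.labels[0] == "mount_intromission"
        assert cat.colors["eating"] == "black"

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_catalogue({})

    def test_duplicate_label_rejected(self):
        # dict specs cannot literally repeat a key, so the duplicate check
        # lives on the catalogue constructor itself.
        from ethoseq.catalogue import BehaviorCatalogue

        with pytest.raises(ValueError, match="duplicate"):
            BehaviorCatalogue(
                labels=("eating", "eating"),
                roles={"eating": "individual"},
                colors={"eating": "black"},
            )

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="role"):
            build_catalogue({"eating": ("solo", "black")})

    def test_none_token_reserved(self):
        with pytest.raises(ValueError, match="reserved"):
            build_catalogue({NONE_LABEL: ("individual", "gray")})

    def test_drop_preserves_order(self):
        cat = catalogue_preset("resident_vs_female")
        no_food = cat.drop(["eating"])
        assert len(no_food) == 6
        assert "eating" not in no_food
        assert no_food.labels == cat.labels[:-1]

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="preset"):
            catalogue_preset("aviary")


class TestParse:
    def test_missing_seconds_filled_with_none(self, tiny_cat):
        text = "0\teating\n1\teating\n3\tgrooming\n"
        e = parse_ethogram(text, tiny_cat, duration_s=5)
        assert e.labels == ("eating", "eating", NONE_LABEL, "grooming", NONE_LABEL)

    def test_empty_stream_all_none(self, tiny_cat):
        e = parse_ethogram("", tiny_cat, duration_s=3)
        assert e.labels == (NONE_LABEL,) * 3

    def test_unknown_label_rejected(self, resident_cat):
        with pytest.raises(ValueError, match="flying"):
            parse_ethogram("0\tflying\n", resident_cat, duration_s=5)

    def test_second_beyond_duration_rejected(self, tiny_cat):
        with pytest.raises(ValueError, match="duration"):
            parse_ethogram("7\teating\n", tiny_cat, duration_s=5)

    def test_conflicting_seconds_need_priority(self, tiny_cat):
        text = "0\teating\n0\tgrooming\n"
        with pytest.raises(ValueError, match="conflicting"):
            parse_ethogram(text, tiny_cat, duration_s=2)
        e = parse_ethogram(text, tiny_cat, duration_s=2, priority=["grooming", "eating"])
        assert e.labels[0] == "grooming"

    def test_roundtrip_canonical(self, tiny_cat):
        e = make_ethogram(
            ["eating", NONE_LABEL, "grooming", "grooming"],
            tiny_cat,
            subject_id="m01",
            condition="Fasted48",
        )
        text = write_ethogram(e)
        back = parse_ethogram(text, tiny_cat)
        assert back == e
        assert write_ethogram(back) == text  # byte-identical second pass

    def test_metadata_from_comments(self, tiny_cat):
        text = "# subject_id=m7\n# condition=Fasted18\n# duration_s=2\n0\teating\n"
        e = parse_ethogram(text, tiny_cat)
        assert (e.subject_id, e.condition, e.duration_s) == ("m7", "Fasted18", 2)


class TestSegmentBouts:
    def test_hand_enumeration(self, tiny_cat):
        e = make_ethogram(
            ["eating", "eating", NONE_LABEL, NONE_LABEL, "eating", "grooming"], tiny_cat
        )
        bouts = segment_bouts(e).bouts
        assert [(b.label, b.start_s, b.end_s) for b in bouts] == [
            ("eating", 0, 2),
            ("eating", 4, 5),
            ("grooming", 5, 6),
        ]

    def test_all_none_is_empty(self, tiny_cat):
        e = make_ethogram([NONE_LABEL] * 10, tiny_cat)
        assert len(segment_bouts(e)) == 0

    def test_constant_barcode_single_bout(self, tiny_cat):
        e = make_ethogram(["eating"] * 1200, tiny_cat)
        bouts = segment_bouts(e).bouts
        assert len(bouts) == 1 and bouts[0].duration_s == 1200

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.sampled_from(["eating", "grooming", NONE_LABEL]), min_size=1, max_size=200
        )
    )
    def test_conservation_and_merging(self, tiny_cat, labels):
        """Bout durations sum to scored seconds; no adjacent same-label bouts."""
        e = make_ethogram(labels, tiny_cat)
        bs = segment_bouts(e)
        assert bs.total_duration_s == e.scored_seconds
        for a, b in zip(bs.bouts, bs.bouts[1:]):
            assert b.start_s > a.end_s or b.label != a.label


class TestInvariants:
    def test_bout_rejects_empty_span_and_none(self):
        with pytest.raises(ValueError):
            Bout(3, 3, "eating")
        with pytest.raises(ValueError):
            Bout(0, 1, NONE_LABEL)

    def test_bout_sequence_rejects_overlap(self):
        with pytest.raises(ValueError):
            BoutSequence(bouts=(Bout(0, 5, "eating"), Bout(3, 6, "grooming")))

    def test_bout_sequence_rejects_adjacent_same_label(self):
        with pytest.raises(ValueError, match="NONE"):
            BoutSequence(bouts=(Bout(0, 2, "eating"), Bout(2, 4, "eating")))

    def test_context_validation(self):
        with pytest.raises(ValueError):
            TrialContext(intruder="hamster")
        with pytest.raises(ValueError):
            TrialContext(setting="arena")

    def test_ethogram_rejects_foreign_labels(self, tiny_cat):
        with pytest.raises(ValueError, match="outside"):
            make_ethogram(["eating", "flying"], tiny_cat)


class TestJWatcherAdapter:
    def test_onset_persistence(self, tiny_cat):
        events = [(0.0, "eating"), (2.5, "grooming"), (5.0, "stop")]
        e = from_jwatcher_events(events, tiny_cat, duration_s=8)
        assert e.labels == (
            "eating",
            "eating",
            "eating",  # second 2 starts before the 2.5 s grooming onset
            "grooming",
            "grooming",
            NONE_LABEL,
            NONE_LABEL,
            NONE_LABEL,
        )

    def test_unknown_code_rejected(self, tiny_cat):
        with pytest.raises(ValueError, match="code"):
            from_jwatcher_events([(0.0, "flying")], tiny_cat, duration_s=3)

    def test_negative_time_rejected(self, tiny_cat):
        with pytest.raises(ValueError, match="negative"):
            from_jwatcher_events([(-1.0, "eating")], tiny_cat, duration_s=3)
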