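"""Remap planning: per-series vs 4DCT frame-of-reference semantics, freshness."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicom_unlink import RemapOptions, UidGenerator, build_plan, plan_summary
from dicom_unlink.plan import PlanError
from dicom_unlink.scan import FileRecord, SeriesGroup


def _group(series_uid, for_uid, n_files, modality="CT"):
    members = [
        FileRecord(
            path=f"{series_uid}/f{i}",
            modality=modality,
            series_uid=series_uid,
            sop_uid=f"{series_uid}.{i}",
            frame_of_reference_uid=for_uid,
            parse_ok=True,
        )
        for i in range(n_files)
    ]
    return SeriesGroup(
        series_uid=series_uid,
        modality=modality,
        frame_of_reference_uid=for_uid,
        members=members,
    )


def test_empty_groups_rejected():
    with pytest.raises(PlanError):
        build_plan([], RemapOptions())


def test_fourdct_mode_one_for_per_original_value():
    """Ten phase series sharing one FoR get exactly one shared replacement."""
    groups = [_group(f"1.9.{i}", "1.5.0", 3) for i in range(10)]
    options = RemapOptions(
        change_frame_of_reference=True, change_sop_uid=False, fourdct_mode=True
    )
    plan = build_plan(groups, options, UidGenerator(seed=1))
    assert set(plan.for_map) == {"1.5.0"}
    new = plan.for_map["1.5.0"]
    assert new != "1.5.0"
    assert all(plan.new_frame_of_reference(g.series_uid, "1.5.0") == new for g in groups)


def test_plain_mode_one_for_per_series():
    groups = [
        _group("1.9.1", "1.5.0", 1),
        _group("1.9.2", "1.5.0", 1),
        _group("1.9.3", "1.5.1", 1),
    ]
    options = RemapOptions(change_frame_of_reference=True, change_sop_uid=False)
    plan = build_plan(groups, options, UidGenerator(seed=2))
    assert set(plan.for_map) == {"1.9.1", "1.9.2", "1.9.3"}
    assert len(set(plan.for_map.values())) == 3


def test_sop_change_is_the_default():
    groups = [_group("1.9.1", "1.5.0", 7)]
    plan = build_plan(groups, RemapOptions(), UidGenerator(seed=3))
    assert len(plan.sop_map) == 7
    assert plan.for_map == {} and plan.series_map == {}


def test_series_map_per_series():
    groups = [_group(f"1.9.{i}", None, 2) for i in range(4)]
    options = RemapOptions(change_series_uid=True, change_sop_uid=False)
    plan = build_plan(groups, options, UidGenerator(seed=4))
    assert set(plan.series_map) == {g.series_uid for g in groups}
    assert len(set(plan.series_map.values())) == 4


def test_series_without_for_gets_no_for_entry():
    groups = [_group("1.9.1", None, 2)]
    options = RemapOptions(change_frame_of_reference=True, change_sop_uid=False)
    plan = build_plan(groups, options, UidGenerator(seed=5))
    assert plan.for_map == {}
    assert plan.new_frame_of_reference("1.9.1", None) is None


def test_freshness_against_input_uids():
    """A generator rigged to first emit existing UIDs must be re-drawn."""
    groups = [_group("1.9.1", "1.5.0", 2)]
    old = {"1.9.1", "1.5.0", "1.9.1.0", "1.9.1.1"}

    class Rigged:
        def __init__(self):
            self.queue = sorted(old)
            self.gen = UidGenerator(seed=6)

        def __call__(self):
            if self.queue:
                return self.queue.pop()
            return self.gen()

    options = RemapOptions(
        change_frame_of_reference=True, change_series_uid=True, change_sop_uid=True
    )
    plan = build_plan(groups, options, uid_source=Rigged())
    newly = set(plan.for_map.values()) | set(plan.series_map.values()) | set(
        plan.sop_map.values()
    )
    assert newly.isdisjoint(old)


def test_plan_summary_counts_and_determinism():
    groups = [_group(f"1.9.{i}", "1.5.0", 10) for i in range(11)]
    options = RemapOptions(
        change_frame_of_reference=True,
        change_series_uid=True,
        change_sop_uid=True,
        fourdct_mode=True,
    )
    plan = build_plan(groups, options, UidGenerator(seed=7))
    text = plan_summary(plan, groups)
    assert "11 series / 110 files" in text
    assert "1 new value" in text  # single shared FoR
    assert "11 new value" in text
    assert "110 new value" in text
    assert text == plan_summary(plan, groups)


def test_plan_summary_sop_only_single_file():
    groups = [_group("1.9.1", None, 1)]
    plan = build_plan(groups, RemapOptions(), UidGenerator(seed=8))
    assert "1 new value" in plan_summary(plan, groups)


@settings(derandomize=True, max_examples=40)
@given(
    layout=st.lists(
        st.tuples(st.integers(0, 3), st.integers(1, 4)), min_size=1, max_size=8
    ),
    fourdct=st.booleans(),
    seed=st.integers(0, 2**31 - 1),
)
def test_property_for_count_and_freshness(layout, fourdct, seed):
    """In 4DCT mode the count of distinct FoR values is conserved; in plain
    mode it equals the number of series; new UIDs never collide with old."""
    groups = [
        _group(f"1.7.{i}", f"1.5.{f}", n) for i, (f, n) in enumerate(layout)
    ]
    options = RemapOptions(
        change_frame_of_reference=True, change_sop_uid=True, fourdct_mode=fourdct
    )
    plan = build_plan(groups, options, UidGenerator(seed=seed))
    old_fors = {g.frame_of_reference_uid for g in groups}
    new_fors = {
        plan.new_frame_of_reference(g.series_uid, g.frame_of_reference_uid)
        for g in groups
    }
    if fourdct:
        assert len(new_fors) == len(old_fors)
    else:
        assert len(new_fors) == len(groups)
    old = old_fors | {g.series_uid for g in groups} | {
        m.sop_uid for g in groups for m in g.members
    }
    assert new_fors.isdisjoint(old)
    assert set(plan.sop_map.values()).isdisjoint(old)
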