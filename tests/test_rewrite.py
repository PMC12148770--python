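"""On-disk application of remap plans: exact tags, byte preservation, atomicity."""

import pydicom
import pytest

from dicom_unlink import (
    RemapOptions,
    UidGenerator,
    apply_plan,
    build_plan,
    diff_datasets,
    group_by_series,
    scan_directory,
    snapshot,
)
from dicom_unlink.rewrite import atomic_write


def _pixel_bytes(root):
    out = {}
    for path in sorted(root.rglob("*.dcm")):
        out[path.relative_to(root)] = pydicom.dcmread(path).PixelData
    return out


def test_trivial_plan_copies_bytes_exactly(mr_study, tmp_path):
    root, _ = mr_study
    records = scan_directory(root)
    groups = group_by_series(records)
    options = RemapOptions(change_sop_uid=False)
    plan = build_plan(groups, options, UidGenerator(seed=1))
    out = tmp_path / "out"
    report = apply_plan(plan, records, output_dir=out, input_root=root)
    assert report.files_failed == 0
    for rec in records:
        if rec.in_scope:
            copy = out / rec.path.relative_to(root)
            assert copy.read_bytes() == rec.path.read_bytes()


def test_sop_only_rewrite(mr_study):
    root, manifest = mr_study
    records = scan_directory(root)
    groups = group_by_series(records)
    plan = build_plan(groups, RemapOptions(), UidGenerator(seed=2))
    pixels_before = _pixel_bytes(root)
    before = snapshot(root)
    report = apply_plan(plan, records)
    assert report.files_failed == 0

    new_sops = set()
    for path in sorted(root.rglob("*.dcm")):
        ds = pydicom.dcmread(path)
        assert str(ds.file_meta.MediaStorageSOPInstanceUID) == str(ds.SOPInstanceUID)
        new_sops.add(str(ds.SOPInstanceUID))
    assert len(new_sops) == 12
    assert new_sops.isdisjoint(manifest.all_uids)

    diff = diff_datasets(before, snapshot(root))
    for entry in diff.files:
        assert {d.tag for d in entry.differing_tags} == {"(0008,0018)", "(0002,0003)"}
    assert _pixel_bytes(root) == pixels_before


def test_full_4dct_rewrite_in_place(fourdct_study):
    root, manifest = fourdct_study
    records = scan_directory(root)
    groups = group_by_series(records)
    options = RemapOptions(
        change_frame_of_reference=True,
        change_series_uid=True,
        change_sop_uid=True,
        fourdct_mode=True,
    )
    plan = build_plan(groups, options, UidGenerator(seed=3))
    report = apply_plan(plan, records)
    assert report.files_failed == 0

    regroups = group_by_series(scan_directory(root))
    assert len(regroups) == 11
    assert sorted(len(g) for g in regroups) == sorted(len(g) for g in groups)
    new_fors = {g.frame_of_reference_uid for g in regroups}
    assert len(new_fors) == 1  # FoR count conserved: 1 before, 1 after
    assert new_fors.isdisjoint(manifest.all_uids)
    assert {g.series_uid for g in regroups}.isdisjoint(manifest.all_uids)


def test_progress_sink_called_per_file(mr_study):
    root, _ = mr_study
    records = scan_directory(root)
    plan = build_plan(group_by_series(records), RemapOptions(), UidGenerator(seed=4))
    seen = []
    apply_plan(plan, records, progress_sink=seen.append)
    assert len(seen) == sum(r.in_scope for r in records)


def test_failure_recorded_and_processing_continues(mr_study, monkeypatch):
    root, _ = mr_study
    records = scan_directory(root)
    plan = build_plan(group_by_series(records), RemapOptions(), UidGenerator(seed=5))
    victim = sorted(r.path for r in records if r.in_scope)[0]
    original_bytes = victim.read_bytes()

    import dicom_unlink.rewrite as rw

    real = rw.atomic_write

    def failing(ds, destination):
        if destination == victim:
            raise OSError("disk full (injected)")
        real(ds, destination)

    monkeypatch.setattr(rw, "atomic_write", failing)
    report = apply_plan(plan, records)
    assert report.files_failed == 1
    assert report.files_changed == sum(r.in_scope for r in records) - 1
    failed = [e for e in report.entries if not e.write_ok]
    assert failed[0].error and "injected" in failed[0].error
    # the original file is untouched
    assert victim.read_bytes() == original_bytes


def test_atomic_write_failure_leaves_destination_intact(mr_study, monkeypatch):
    root, _ = mr_study
    path = sorted(root.rglob("*.dcm"))[0]
    original = path.read_bytes()
    ds = pydicom.dcmread(path)
    ds.SOPInstanceUID = "9.9.9"

    def exploding_save(self, *a, **k):
        raise OSError("simulated mid-write failure")

    monkeypatch.setattr(type(ds), "save_as", exploding_save)
    with pytest.raises(OSError):
        atomic_write(ds, path)
    assert path.read_bytes() == original
    assert not list(root.rglob("*.tmp"))


def test_atomic_write_roundtrip(mr_study, tmp_path):
    root, _ = mr_study
    src = sorted(root.rglob("*.dcm"))[0]
    ds = pydicom.dcmread(src)
    dest = tmp_path / "copy.dcm"
    atomic_write(ds, dest)
    back = pydicom.dcmread(dest)
    assert back.SOPInstanceUID == ds.SOPInstanceUID
    assert {e.tag for e in back} == {e.tag for e in pydicom.dcmread(src)}
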