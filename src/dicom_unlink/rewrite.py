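"""Apply a remap plan to DICOM files on disk.

Step two of the workflow: each in-scope file is fully read, exactly the
planned UID tags are replaced, and the result is written atomically — by
default over the original file, or into a mirror tree when ``output_dir`` is
given. Everything else, including pixel data and transfer syntax, is
preserved as read (pydicom keeps untouched elements raw, so their bytes
round-trip unchanged).
"""

from __future__ import annotations

import json
import logging
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pydicom

from .plan import RemapPlan
from .scan import FileRecord

log = logging.getLogger(__name__)

__all__ = ["TagChange", "FileChange", "ChangeReport", "apply_plan", "atomic_write"]

TAG_FRAME_OF_REFERENCE = "(0020,0052)"
TAG_SERIES_UID = "(0020,000E)"
TAG_SOP_UID = "(0008,0018)"
TAG_MEDIA_STORAGE_SOP_UID = "(0002,0003)"


@dataclass(frozen=True)
class TagChange:
    tag: str
    old: str
    new: str


@dataclass
class FileChange:
    path: Path
    tags_changed: list[TagChange] = field(default_factory=list)
    write_ok: bool = True
    error: str | None = None


@dataclass
class ChangeReport:
    """Per-file outcomes of one apply run."""

    entries: list[FileChange] = field(default_factory=list)

    @property
    def files_changed(self) -> int:
        return sum(e.write_ok for e in self.entries)

    @property
    def files_failed(self) -> int:
        return sum(not e.write_ok for e in self.entries)

    def to_json(self) -> str:
        payload = {
            "files_changed": self.files_changed,
            "files_failed": self.files_failed,
            "files": [
                {
                    "path": str(e.path),
                    "write_ok": e.write_ok,
                    "error": e.error,
                    "tags_changed": [
                        {"tag": c.tag, "old": c.old, "new": c.new}
                        for c in e.tags_changed
                    ],
                }
                for e in self.entries
            ],
        }
        return json.dumps(payload, indent=2)


def atomic_write(dataset: pydicom.Dataset, destination: Path) -> None:
    """Write ``dataset`` via a temporary sibling file and an atomic rename.

    An interrupted write never leaves a truncated file at ``destination``;
    on failure the temporary file is removed and the original (if any) is
    untouched.
    """
    destination = Path(destination)
    fd, tmp_name = tempfile.mkstemp(
        prefix=destination.name + ".", suffix=".tmp", dir=destination.parent
    )
    os.close(fd)
    tmp = Path(tmp_name)
    try:
        dataset.save_as(tmp, enforce_file_format=True)
        os.replace(tmp, destination)
    except Exception:
        tmp.unlink(missing_ok=True)
        raise


def _rewrite_one(
    record: FileRecord, plan: RemapPlan, destination: Path
) -> FileChange:
    entry = FileChange(path=destination)
    if plan.options.trivial:
        # Nothing to change: copy bytes verbatim rather than re-encode.
        if destination != record.path:
            shutil.copyfile(record.path, destination)
        return entry
    ds = pydicom.dcmread(record.path)

    new_for = plan.new_frame_of_reference(
        record.series_uid, record.frame_of_reference_uid
    )
    if new_for is not None and "FrameOfReferenceUID" in ds:
        entry.tags_changed.append(
            TagChange(TAG_FRAME_OF_REFERENCE, ds.FrameOfReferenceUID, new_for)
        )
        ds.FrameOfReferenceUID = new_for

    if plan.options.change_series_uid:
        new_series = plan.series_map.get(record.series_uid)
        if new_series is None:
            raise KeyError(f"series {record.series_uid} not in plan")
        entry.tags_changed.append(
            TagChange(TAG_SERIES_UID, ds.SeriesInstanceUID, new_series)
        )
        ds.SeriesInstanceUID = new_series

    if plan.options.change_sop_uid:
        new_sop = plan.sop_map.get(record.sop_uid)
        if new_sop is None:
            raise KeyError(f"SOP instance {record.sop_uid} not in plan")
        entry.tags_changed.append(TagChange(TAG_SOP_UID, ds.SOPInstanceUID, new_sop))
        ds.SOPInstanceUID = new_sop
        # DICOM Part-10 requires the file-meta Media Storage SOP Instance UID
        # to match the dataset SOP Instance UID; importers reject mismatches.
        if ds.file_meta is not None:
            entry.tags_changed.append(
                TagChange(
                    TAG_MEDIA_STORAGE_SOP_UID,
                    str(ds.file_meta.MediaStorageSOPInstanceUID),
                    new_sop,
                )
            )
            ds.file_meta.MediaStorageSOPInstanceUID = new_sop

    atomic_write(ds, destination)
    return entry


def apply_plan(
    plan: RemapPlan,
    records: list[FileRecord],
    output_dir: Path | str | None = None,
    progress_sink: Callable[[FileChange], None] | None = None,
    input_root: Path | str | None = None,
) -> ChangeReport:
    """Rewrite every in-scope file according to ``plan``.

    With ``output_dir`` set, modified copies are written into a mirror of the
    tree rooted at ``input_root`` (required in that case) and the originals
    are left alone; otherwise files are overwritten in place. A failure on
    one file is recorded and processing continues.
    """
    report = ChangeReport()
    in_scope = sorted((r for r in records if r.in_scope), key=lambda r: r.path)
    out_root = Path(output_dir) if output_dir is not None else None
    if out_root is not None and input_root is None:
        raise ValueError("output_dir requires input_root to mirror the tree")

    for record in in_scope:
        if out_root is None:
            destination = record.path
        else:
            destination = out_root / record.path.relative_to(Path(input_root))
            destination.parent.mkdir(parents=True, exist_ok=True)
        try:
            entry = _rewrite_one(record, plan, destination)
        except Exception as exc:
            entry = FileChange(path=destination, write_ok=False, error=str(exc))
            log.error("failed to rewrite %s: %s", record.path, exc)
        report.entries.append(entry)
        if progress_sink is not None:
            progress_sink(entry)
    log.info(
        "rewrote %d file(s), %d failure(s)", report.files_changed, report.files_failed
    )
    return report
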