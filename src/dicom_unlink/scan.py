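"""Directory scanning and grouping of DICOM files.

Step one of the rewrite workflow: walk a directory, parse headers only
(stopping before pixel data), filter by modality, and partition the files by
Series Instance UID and by Frame of Reference UID.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pydicom
from pydicom.errors import InvalidDicomError

from .uids import is_valid_uid

log = logging.getLogger(__name__)

__all__ = [
    "FileRecord",
    "SeriesGroup",
    "ScanError",
    "normalize_modalities",
    "scan_directory",
    "group_by_series",
    "group_by_frame_of_reference",
]

# User-facing modality tokens -> DICOM (0008,0060) codes. "4DCT" is a planning
# mode, not a modality, and is deliberately absent here.
_MODALITY_ALIASES = {"CT": "CT", "MR": "MR", "MRI": "MR", "PET": "PT", "PT": "PT"}


class ScanError(Exception):
    """Fatal scan failure (nonexistent or unreadable root)."""


@dataclass
class FileRecord:
    """One file encountered during a scan.

    ``parse_ok`` implies the series and SOP UIDs are present and valid;
    a skipped record carries a human-readable ``skip_reason`` and is excluded
    from all grouping.
    """

    path: Path
    modality: str | None = None
    series_uid: str | None = None
    sop_uid: str | None = None
    frame_of_reference_uid: str | None = None
    parse_ok: bool = False
    skip_reason: str | None = None

    @property
    def in_scope(self) -> bool:
        return self.parse_ok and self.skip_reason is None


@dataclass
class SeriesGroup:
    """All in-scope files sharing one Series Instance UID."""

    series_uid: str
    modality: str
    frame_of_reference_uid: str | None
    members: list[FileRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def normalize_modalities(tokens) -> set[str] | None:
    """Map user tokens (case-insensitive; PET->PT) to DICOM modality codes.

    ``None`` or an empty collection means "no filter".
    """
    if not tokens:
        return None
    codes = set()
    for token in tokens:
        code = _MODALITY_ALIASES.get(str(token).strip().upper())
        if code is None:
            raise ValueError(
                f"unknown modality {token!r}; expected one of CT, MR, PET"
            )
        codes.add(code)
    return codes


def _probe(path: Path, modality_filter: set[str] | None) -> FileRecord:
    record = FileRecord(path=path)
    try:
        ds = pydicom.dcmread(path, stop_before_pixels=True)
    except InvalidDicomError:
        record.skip_reason = "not a DICOM file"
        return record
    except Exception as exc:  # unreadable / truncated
        record.skip_reason = f"unreadable: {exc}"
        return record

    record.modality = str(ds.get("Modality", "")) or None
    record.series_uid = str(ds.get("SeriesInstanceUID", "")) or None
    record.sop_uid = str(ds.get("SOPInstanceUID", "")) or None
    for_uid = str(ds.get("FrameOfReferenceUID", "")) or None
    record.frame_of_reference_uid = for_uid

    if not record.series_uid or not is_valid_uid(record.series_uid):
        record.skip_reason = "missing or invalid SeriesInstanceUID"
        return record
    if not record.sop_uid or not is_valid_uid(record.sop_uid):
        record.skip_reason = "missing or invalid SOPInstanceUID"
        return record
    record.parse_ok = True
    if modality_filter is not None and record.modality not in modality_filter:
        record.skip_reason = "modality filtered"
    return record


def scan_directory(
    root: Path | str,
    modality_filter: set[str] | None = None,
    recurse: bool = True,
) -> list[FileRecord]:
    """Probe every regular file under ``root`` for a DICOM header.

    Discovery does not rely on a ``.dcm`` extension; non-DICOM files are
    skipped gracefully, never fatally. Records are returned path-sorted so a
    repeat scan of an unmodified tree is identical.
    """
    root = Path(root)
    if not root.is_dir():
        raise ScanError(f"input directory does not exist: {root}")
    paths = sorted(p for p in (root.rglob("*") if recurse else root.glob("*")) if p.is_file())
    records = [_probe(p, modality_filter) for p in paths]
    n_scope = sum(r.in_scope for r in records)
    log.info("scanned %d files under %s: %d in scope", len(records), root, n_scope)
    return records


def group_by_series(records: list[FileRecord]) -> list[SeriesGroup]:
    """Partition in-scope records into one group per Series Instance UID.

    A series whose members disagree on Frame of Reference UID (the standard
    assumes consistency) triggers a warning and the group carries the most
    frequent value.
    """
    by_series: dict[str, list[FileRecord]] = defaultdict(list)
    for rec in records:
        if rec.in_scope:
            by_series[rec.series_uid].append(rec)

    groups = []
    for series_uid in sorted(by_series):
        members = sorted(by_series[series_uid], key=lambda r: r.path)
        fors = Counter(m.frame_of_reference_uid for m in members)
        if len(fors) > 1:
            log.warning(
                "series %s has inconsistent FrameOfReferenceUID values %s; "
                "using the most frequent",
                series_uid,
                sorted(k for k in fors if k is not None),
            )
        group_for = fors.most_common(1)[0][0]
        groups.append(
            SeriesGroup(
                series_uid=series_uid,
                modality=members[0].modality or "",
                frame_of_reference_uid=group_for,
                members=members,
            )
        )
    return groups


def group_by_frame_of_reference(
    groups: list[SeriesGroup],
) -> tuple[dict[str, list[SeriesGroup]], list[SeriesGroup]]:
    """Index series groups by their Frame of Reference UID.

    Returns ``(mapping, without_for)`` where series lacking (0020,0052) are
    collected in ``without_for``.
    """
    mapping: dict[str, list[SeriesGroup]] = defaultdict(list)
    without: list[SeriesGroup] = []
    for group in groups:
        if group.frame_of_reference_uid is None:
            without.append(group)
        else:
            mapping[group.frame_of_reference_uid].append(group)
    return dict(mapping), without
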