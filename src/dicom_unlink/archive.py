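"""Extraction of zipped DICOM exports before scanning.

Sites often deliver exports as zip archives; this step expands every
``.zip`` found under the input root so a single run can go straight from
archive to rewritten files. Only zip is handled. Entries that would escape
the extraction directory (zip-slip) cause the whole archive to be rejected.
"""

from __future__ import annotations

import logging
import zipfile
from dataclasses import dataclass
from pathlib import Path

log = logging.getLogger(__name__)

__all__ = ["ExtractionResult", "extract_archives"]


@dataclass
class ExtractionResult:
    archives_found: int = 0
    files_extracted: int = 0
    destination: Path | None = None


def _safe_members(zf: zipfile.ZipFile, dest: Path) -> list[zipfile.ZipInfo]:
    resolved_dest = dest.resolve()
    members = []
    for info in zf.infolist():
        target = (dest / info.filename).resolve()
        if not target.is_relative_to(resolved_dest):
            raise zipfile.BadZipFile(f"path traversal entry: {info.filename!r}")
        members.append(info)
    return members


def extract_archives(root: Path | str, delete_after: bool = False) -> ExtractionResult:
    """Expand every zip archive under ``root`` beside itself.

    Each archive ``X.zip`` is extracted into a sibling directory ``X/``,
    preserving internal structure. Corrupt archives are skipped with a
    warning; with ``delete_after`` an archive is removed once extracted.
    """
    root = Path(root)
    result = ExtractionResult(destination=root)
    for archive in sorted(root.rglob("*.zip")):
        result.archives_found += 1
        dest = archive.with_suffix("")
        try:
            with zipfile.ZipFile(archive) as zf:
                members = _safe_members(zf, dest)
                dest.mkdir(parents=True, exist_ok=True)
                for info in members:
                    zf.extract(info, dest)
                    if not info.is_dir():
                        result.files_extracted += 1
        except zipfile.BadZipFile as exc:
            log.warning("skipping archive %s: %s", archive, exc)
            continue
        if delete_after:
            archive.unlink()
        log.info("extracted %s -> %s", archive, dest)
    return result
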