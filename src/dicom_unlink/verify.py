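"""Tag-level snapshot and diff of DICOM trees.

Automated check that a rewrite changed *only* the intended attributes: take
an element inventory of every file before and after, pair files by relative
path, and list exactly the tags whose value bytes differ. Bulk data (pixel
data and friends) is represented by a content digest so snapshots stay
small; sequence items are walked recursively with indexed tag paths like
``(0008,1140)[0].(0008,1150)``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pydicom
from pydicom.dataset import Dataset

log = logging.getLogger(__name__)

__all__ = [
    "TagDiff",
    "FileDiff",
    "AttributeDiff",
    "Verdict",
    "snapshot",
    "snapshot_file",
    "diff_datasets",
    "assert_only_changed",
]


def _format_tag(tag) -> str:
    return f"({tag.group:04X},{tag.element:04X})"


def _digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _element_repr(elem) -> str:
    """Stable representation of an element's value for comparison.

    Large binary values are digested; everything else compares by its string
    rendering, which is faithful for the UI/CS/DS/IS/etc. text VRs this tool
    touches and deterministic for the rest.
    """
    value = elem.value
    if isinstance(value, (bytes, bytearray, memoryview)):
        return f"sha256:{_digest(bytes(value))}"
    return f"{elem.VR}:{value!r}"


def _walk(ds: Dataset, prefix: str, inventory: dict[str, str]) -> None:
    for elem in ds:
        if elem.tag.element == 0x0000:
            # Group lengths are derived encoding artefacts, not attributes.
            continue
        path = prefix + _format_tag(elem.tag)
        if elem.VR == "SQ":
            inventory[path] = f"SQ:{len(elem.value)}"
            for i, item in enumerate(elem.value):
                _walk(item, f"{path}[{i}].", inventory)
        else:
            inventory[path] = _element_repr(elem)


def snapshot_file(path: Path) -> dict[str, str]:
    """Inventory of one file: tag path -> value representation/digest."""
    ds = pydicom.dcmread(path)
    inventory: dict[str, str] = {}
    if ds.file_meta is not None:
        _walk(ds.file_meta, "", inventory)
    _walk(ds, "", inventory)
    return inventory


def snapshot(root: Path | str) -> dict[str, dict[str, str]]:
    """Inventory every DICOM file under ``root``, keyed by relative path.

    Unreadable files are recorded with a warning and excluded.
    """
    root = Path(root)
    result: dict[str, dict[str, str]] = {}
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        rel = path.relative_to(root).as_posix()
        try:
            result[rel] = snapshot_file(path)
        except Exception as exc:
            log.warning("snapshot: skipping unreadable %s: %s", rel, exc)
    return result


@dataclass(frozen=True)
class TagDiff:
    tag: str  # tag path; sequence items carry an indexed prefix
    old: str | None
    new: str | None


@dataclass
class FileDiff:
    path: str
    differing_tags: list[TagDiff] = field(default_factory=list)


@dataclass
class AttributeDiff:
    """Differences between two snapshots, paired by relative path."""

    files: list[FileDiff] = field(default_factory=list)
    added: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)
    files_compared: int = 0

    @property
    def clean(self) -> bool:
        return not self.added and not self.removed and all(
            not f.differing_tags for f in self.files
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "files_compared": self.files_compared,
                "added": self.added,
                "removed": self.removed,
                "files": [
                    {
                        "path": f.path,
                        "differing_tags": [
                            {"tag": d.tag, "old": d.old, "new": d.new}
                            for d in f.differing_tags
                        ],
                    }
                    for f in self.files
                    if f.differing_tags
                ],
            },
            indent=2,
        )


def diff_datasets(
    before: dict[str, dict[str, str]], after: dict[str, dict[str, str]]
) -> AttributeDiff:
    """List exactly the tags whose value bytes differ between two snapshots.

    Files present on only one side are reported as added/removed, never
    silently dropped.
    """
    diff = AttributeDiff()
    diff.added = sorted(set(after) - set(before))
    diff.removed = sorted(set(before) - set(after))
    for rel in sorted(set(before) & set(after)):
        inv_b, inv_a = before[rel], after[rel]
        entry = FileDiff(path=rel)
        for tag in sorted(set(inv_b) | set(inv_a)):
            old, new = inv_b.get(tag), inv_a.get(tag)
            if old != new:
                entry.differing_tags.append(TagDiff(tag=tag, old=old, new=new))
        diff.files.append(entry)
        diff.files_compared += 1
    return diff


@dataclass
class Verdict:
    ok: bool
    violations: list[str] = field(default_factory=list)


def assert_only_changed(diff: AttributeDiff, allowed: set[str]) -> Verdict:
    """Pass iff every differing tag of every compared file is in ``allowed``.

    ``allowed`` holds bare tag strings like ``"(0020,0052)"``; for sequence
    paths the final tag component is what is matched.
    """
    verdict = Verdict(ok=True)
    for rel in diff.added:
        verdict.violations.append(f"{rel}: file added")
    for rel in diff.removed:
        verdict.violations.append(f"{rel}: file removed")
    for entry in diff.files:
        for tag_diff in entry.differing_tags:
            leaf = tag_diff.tag.split(".")[-1].split("[")[0]
            if leaf not in allowed:
                verdict.violations.append(
                    f"{entry.path}: unexpected change in {tag_diff.tag}"
                )
    verdict.ok = not verdict.violations
    return verdict
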