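"""Remap planning: decide the replacement UID for every targeted attribute.

The consistency rules live here. Series UID remapping is always per series
and SOP UID remapping per file; only the Frame of Reference semantics depend
on the mode:

* plain mode — one fresh Frame of Reference UID per *series*, unlinking every
  series from every other;
* 4DCT mode — one fresh Frame of Reference UID per *original* Frame of
  Reference value, so all phase series of a 4DCT (which share one frame of
  reference) stay mutually registered while their link to anything outside
  the folder that keeps the old UID is broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .scan import SeriesGroup
from .uids import UidGenerator

__all__ = ["RemapOptions", "RemapPlan", "PlanError", "build_plan", "plan_summary"]


class PlanError(Exception):
    """Raised when no plan can be built (e.g. nothing in scope)."""


@dataclass(frozen=True)
class RemapOptions:
    """Which attributes to change and how.

    The SOP Instance UID change defaults on; note that changing it breaks
    existing associations with RT plan / structure-set objects, which this
    tool does not repair.
    """

    change_frame_of_reference: bool = False
    change_series_uid: bool = False
    change_sop_uid: bool = True
    fourdct_mode: bool = False

    @property
    def trivial(self) -> bool:
        return not (
            self.change_frame_of_reference
            or self.change_series_uid
            or self.change_sop_uid
        )


@dataclass
class RemapPlan:
    """Old-to-new UID mappings for one run.

    ``for_map`` is keyed by series UID in plain mode and by the original
    Frame of Reference UID in 4DCT mode (``options.fourdct_mode`` records
    which). All mapped values are fresh: distinct from each other and from
    every UID seen in the input.
    """

    options: RemapOptions
    for_map: dict[str, str] = field(default_factory=dict)
    series_map: dict[str, str] = field(default_factory=dict)
    sop_map: dict[str, str] = field(default_factory=dict)

    def new_frame_of_reference(self, series_uid: str, old_for: str | None) -> str | None:
        """Replacement FoR UID for a file of ``series_uid``, or None if unchanged."""
        if not self.options.change_frame_of_reference or old_for is None:
            return None
        key = old_for if self.options.fourdct_mode else series_uid
        return self.for_map.get(key)

    @property
    def n_files(self) -> int:
        return len(self.sop_map)


def build_plan(
    groups: list[SeriesGroup],
    options: RemapOptions,
    uid_source: UidGenerator | None = None,
) -> RemapPlan:
    """Assign fresh UIDs for every targeted attribute across ``groups``.

    Raises :class:`PlanError` on an empty input. Freshness against the input
    is enforced by re-drawing on the (practically impossible) event that the
    generator emits a UID already present in the scanned files.
    """
    if not groups:
        raise PlanError("no DICOM series in scope; nothing to plan")
    gen = uid_source if uid_source is not None else UidGenerator()

    old_uids: set[str] = set()
    for g in groups:
        old_uids.add(g.series_uid)
        if g.frame_of_reference_uid:
            old_uids.add(g.frame_of_reference_uid)
        for m in g.members:
            old_uids.add(m.sop_uid)

    def fresh() -> str:
        uid = gen()
        while uid in old_uids:
            uid = gen()
        return uid

    plan = RemapPlan(options=options)

    if options.change_frame_of_reference:
        if options.fourdct_mode:
            for g in groups:
                old = g.frame_of_reference_uid
                if old is not None and old not in plan.for_map:
                    plan.for_map[old] = fresh()
        else:
            for g in groups:
                if g.frame_of_reference_uid is not None:
                    plan.for_map[g.series_uid] = fresh()

    if options.change_series_uid:
        for g in groups:
            plan.series_map[g.series_uid] = fresh()

    if options.change_sop_uid:
        for g in groups:
            for m in g.members:
                plan.sop_map[m.sop_uid] = fresh()

    return plan


def plan_summary(plan: RemapPlan, groups: list[SeriesGroup]) -> str:
    """Deterministic human-readable summary of what a plan will change."""
    n_series = len(groups)
    n_files = sum(len(g) for g in groups)
    lines = [f"{n_series} series / {n_files} files in scope"]
    opts = plan.options
    if opts.change_frame_of_reference:
        mode = "shared per original frame of reference (4DCT mode)" if opts.fourdct_mode else "one per series"
        lines.append(f"  Frame of Reference UID (0020,0052): {len(plan.for_map)} new value(s), {mode}")
    if opts.change_series_uid:
        lines.append(f"  Series Instance UID (0020,000E): {len(plan.series_map)} new value(s)")
    if opts.change_sop_uid:
        lines.append(
            f"  SOP Instance UID (0008,0018): {len(plan.sop_map)} new value(s)"
            " (file meta (0002,0003) kept in sync)"
        )
    if opts.trivial:
        lines.append("  no attribute changes selected")
    return "\n".join(lines)
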