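"""Break the implicit registration between MR sequences of one study.

Builds a synthetic 3-series brain MR study (T1/T2/FLAIR) that shares one
Frame of Reference UID, then assigns each series its own fresh frame of
reference so a planning system will no longer auto-fuse them.
"""

import tempfile
from pathlib import Path

from dicom_unlink import (
    RemapOptions,
    UidGenerator,
    apply_plan,
    build_plan,
    group_by_series,
    make_mr_study,
    scan_directory,
)

root = Path(tempfile.mkdtemp()) / "brain_mr"
make_mr_study(root, n_series=3, n_slices=4, seed=1)

records = scan_directory(root)
groups = group_by_series(records)
print(f"before: {len(groups)} series, "
      f"{len({g.frame_of_reference_uid for g in groups})} distinct frame(s) of reference")

options = RemapOptions(change_frame_of_reference=True)  # SOP change is on by default
plan = build_plan(groups, options, UidGenerator(seed=2))
report = apply_plan(plan, records)

after = group_by_series(scan_directory(root))
print(f"after:  {len(after)} series, "
      f"{len({g.frame_of_reference_uid for g in after})} distinct frame(s) of reference")
print(f"{report.files_changed} file(s) rewritten, {report.files_failed} failure(s)")
# One shared frame of reference becomes three distinct ones: each MR sequence
# is now an independent image set the planning system must be registered anew.
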