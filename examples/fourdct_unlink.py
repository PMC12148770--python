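"""Unlink a 4DCT from its free-breathing scan while keeping the phases together.

A 4DCT's phase series and the free-breathing CT acquired at simulation share
one Frame of Reference UID. In 4DCT mode, every series that shared an
original frame of reference receives the SAME fresh replacement, so the ten
phases stay mutually registered — but any copy of the study elsewhere that
keeps the old UID is no longer linked.
"""

import tempfile
from pathlib import Path

from dicom_unlink import RemapOptions, RunConfig, make_4dct_study, run, scan_directory, group_by_series

root = Path(tempfile.mkdtemp()) / "lung"
make_4dct_study(root, n_phases=10, n_slices=3, include_free_breathing=True, seed=3)

groups = group_by_series(scan_directory(root))
print(f"before: {len(groups)} CT series sharing "
      f"{len({g.frame_of_reference_uid for g in groups})} frame of reference")

config = RunConfig(
    input_dir=root,
    options=RemapOptions(change_frame_of_reference=True, fourdct_mode=True),
    modalities=("CT",),
    seed=4,
)
result = run(config)
print(result.summary)

after = group_by_series(scan_directory(root))
print(f"after:  {len(after)} series sharing "
      f"{len({g.frame_of_reference_uid for g in after})} frame of reference")
# Still exactly one frame of reference — but a brand-new UID: the 4DCT stays
# internally consistent while its link to the outside world is broken.
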