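# dicom-unlink

Batch rewriting of the three DICOM attributes that control how treatment
planning systems link images together: the **Frame of Reference UID**
(0020,0052), the **Series Instance UID** (0020,000E) and the **SOP Instance
UID** (0008,0018) — with a built-in verifier proving that nothing else in
the files changed.

## Why

Planning systems (RayStation, Eclipse, MIM, ...) treat image sets that share
a Frame of Reference UID as inherently co-registered. That is usually
right — all MR sequences of one session, or all phases of a 4DCT, really
were acquired in one coordinate system — but it becomes a hindrance when a
physicist needs to *re*-register them: move a patient between scans, fuse a
PET/CT about two different anatomical regions, or register a free-breathing
CT independently of its 4DCT. Breaking that implicit link means editing
UIDs, which done by hand risks corrupting files or silently changing
unrelated attributes.

`dicom-unlink` does exactly three things, and provably nothing else:

- assign fresh Frame of Reference UIDs — either one per series (full
  unlinking) or, in **4DCT mode**, one per *original* frame of reference, so
  all phase series that shared a frame keep sharing the (new) one and stay
  mutually registered;
- assign fresh Series Instance UIDs, one per series;
- assign fresh SOP Instance UIDs, one per file (**on by default**; the
  file-meta Media Storage SOP Instance UID (0002,0003) is kept in sync).
  Note this breaks existing RT plan / structure-set references, which the
  tool does not repair.

Replacement UIDs are minted under the UUID-derived `2.25.` root (or a
configured organisation root), are always ≤ 64 characters, and never collide
with any UID present in the input.

## Worked example

```
$ python examples/fourdct_unlink.py
before: 11 CT series sharing 1 frame of reference
11 series / 33 files in scope
  Frame of Reference UID (0020,0052): 1 new value(s), shared per original frame of reference (4DCT mode)
  SOP Instance UID (0008,0018): 33 new value(s) (file meta (0002,0003) kept in sync)
after:  11 series sharing 1 frame of reference
```

Eleven CT series (ten respiratory phases plus a free-breathing scan) shared
one Frame of Reference UID; after the run they still share exactly one — a
brand-new value — so the 4DCT remains internally consistent while any link
to images retaining the old UID is broken. The other examples show per-series
unlinking of an MR study (`break_mr_registration.py`: 1 shared frame becomes
3 distinct ones) and the tag-level verifier (`verify_only_changed.py`).

The same run from the shell:

```
unlink run /path/to/export --change-for --fourdct --modality CT
unlink verify BEFORE_DIR AFTER_DIR --allow "(0020,0052)" --allow "(0008,0018)" --allow "(0002,0003)"
unlink fixtures make-4dct --out demo --phases 10 --slices 5 --seed 1
```

`unlink run` also supports `--change-series`, `--keep-sop`, `--unzip` (expand
zipped exports first), `--output-dir` (write copies instead of overwriting in
place), `--dry-run`, `--seed` and `--report report.json`. Writes are atomic
(temporary file + rename), so an interrupted run never truncates a file.

Synthetic studies stand in for real exports everywhere: a multi-sequence
brain MR study and a free-breathing + 10-phase 4DCT study, both with every
series on one shared frame of reference, generated by
`dicom_unlink.fixtures` with a manifest of all UIDs.

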