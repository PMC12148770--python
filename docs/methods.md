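# Methods

## The problem being modelled

DICOM encodes spatial linkage between image sets through the Frame of
Reference UID (0020,0052): a treatment planning system importing two image
sets with the same value treats them as rigidly co-registered and will not
let the user register them independently. Identity of a series and of a
single object is carried by the Series Instance UID (0020,000E) and SOP
Instance UID (0008,0018). "Unlinking" image sets therefore means assigning
new values to some subset of these three attributes across a whole export,
consistently, without disturbing anything else in the files.

## Procedure

A run is a fixed pipeline:

1. **Extract** (optional): every `*.zip` under the input root is expanded
   into a sibling directory. Only zip is handled; entries that would escape
   the extraction directory are rejected per archive.
2. **Scan**: every regular file is probed for a DICOM Part-10 header
   (header-only parse, stopping before pixel data); discovery never relies
   on file extensions. Non-DICOM and unreadable files are skipped with a
   recorded reason, never fatally. A modality filter (user tokens CT/MR/PET,
   case-insensitive, PET → PT) marks out-of-scope files as skipped.
3. **Group**: in-scope files are partitioned by Series Instance UID; series
   are further indexed by Frame of Reference UID. A series whose members
   disagree on frame of reference (the standard assumes they cannot) is
   kept, with a warning, under its most frequent value.
4. **Plan**: fresh UIDs are assigned per the selected options (below).
5. **Apply**: each file is fully read, exactly the planned tags are
   replaced, and the file is written atomically — over the original by
   default, or into a mirror tree under `--output-dir`.

## Replacement semantics

- **SOP Instance UID** — one fresh value per file; on by default because it
  is the change users nearly always need alongside the others. When it
  changes, the file-meta Media Storage SOP Instance UID (0002,0003) is
  updated to match: Part-10 requires the two to agree and importers reject
  mismatches. Existing RT plan / structure-set references to the old SOP
  UIDs become orphans; repairing them is out of scope by design.
- **Series Instance UID** — one fresh value per series, shared by all its
  files, in every mode.
- **Frame of Reference UID** — mode-dependent:
  - *plain mode*: one fresh value per series. Every series becomes an
    independent coordinate system.
  - *4DCT mode*: one fresh value per **original** frame-of-reference value,
    shared by all series that shared it. The number of distinct frames is
    conserved while every value is new: the phases of a 4DCT stay mutually
    registered, but their link to anything outside the folder that keeps the
    old UID is broken. A free-breathing series inside the same folder that
    shares the 4DCT's frame will, by this literal rule, receive the same new
    value and remain linked to the phases; to split it from the phases, run
    it separately or use plain mode. This caveat is inherent in the
    group-by-original-frame rule and is the documented behaviour.
  - Series without a (0020,0052) element are left without one; the tool
    never inserts the attribute.
- The Study Instance UID is never modified.

Freshness is absolute: new values are drawn until disjoint from every UID
seen in the input (with a well-behaved generator a redraw never actually
occurs), and each of the three maps is injective.

## UID generation

Replacements are minted under the UUID-derived root `2.25.` — decimal
rendering of a 128-bit UUID — which requires no registered organisation
root and always fits the 64-character limit of the UI value representation.
Sites with a registered root can configure one (`--uid-root`); the suffix is
then reduced modulo the remaining digit budget. Unseeded generation uses
random (version-4) UUIDs; seeded generation feeds a counter into a
name-based (version-5) UUID under a fixed namespace, so a seed reproduces
the exact UID stream across runs and platforms — this is what makes whole
pipeline runs replayable. The validator enforces the UI VR rules as a total
function: ≤ 64 characters, dotted non-empty numeric components, no leading
zeros (a bare `0` component is legal).

## Verification

The differ is the automated stand-in for inspecting files in a viewer: it
inventories every element of file meta and dataset (sequences walked
recursively with indexed tag paths like `(0008,1140)[0].(0008,1155)`),
pairs files by relative path, and reports exactly the tags whose values
differ. Bulk values are represented by SHA-256 digests so snapshots stay
small and pixel-data preservation is still checked content-exactly. Group
length elements (element 0x0000) are excluded: they are derived encoding
artefacts, not attributes. `assert_only_changed` then compares the observed
diff against the allow-list implied by the selected options — the package's
headline safety property, exercised over all eight flag combinations on
both fixture studies.

Byte preservation of untouched elements follows from pydicom's lazy
decoding: elements never accessed are written back from their original raw
bytes. The no-op plan short-circuits to a literal byte copy. The original
transfer syntax is preserved; there is no transcoding.

## Synthetic studies

Two generators emulate the study layouts this workflow exists for:

- `make_mr_study` — *n* MR series (labelled T1, T2, FLAIR, ...) of *n*
  slices, one Study and one shared Frame of Reference UID, distinct Series
  UIDs, unique SOP UIDs. Defaults 3 × 4.
- `make_4dct_study` — a free-breathing CT series plus *n* phase series
  labelled "0%", "10%", ... by respiratory phase, all sharing one frame of
  reference. Defaults 10 phases × 5 slices plus the free-breathing series —
  eleven series, the canonical thoracic simulation layout.
- `make_pet_study` — a PT variant for modality-filter exercises.

Pixel content is a 16×16 16-bit gradient plus seeded noise: enough to make
byte-preservation checks meaningful, with no anatomical realism — the tool
never interprets pixels, so none is needed. What the fixtures deliberately
do not emulate: private elements, compressed transfer syntaxes, RT
plan/structure-set objects, and vendor quirks (implicit VR, odd group
lengths). Passing tests therefore demonstrate the UID logic and the
only-these-tags guarantee, not robustness to every encoding found in the
wild; pydicom's reader/writer carries that load. A JSON manifest of all
generated UIDs is written beside each study so tests derive expectations
without re-parsing.

## Numerical and operational choices

- Writes go to a temporary sibling file then `rename()` over the
  destination, so a crash never leaves a truncated DICOM file.
- Files are processed in sorted path order; reports and plan summaries are
  deterministic.
- Per-file failures (permissions, disk full) are recorded in the change
  report and processing continues; the exit status is nonzero iff any file
  failed, with a distinct status for "nothing in scope".
- Scanning recurses into subdirectories by default (exports routinely nest
  folders); `--no-recurse` disables it.
- Acceptance measurements use the default fixture sizes (11 series × 5
  slices for the 4DCT study, 3 × 4 for MR; 10,000 UIDs for the uniqueness
  check) — small enough to run in seconds, large enough that grouping,
  consistency and freshness properties are non-trivial.

## Known limitations

- References inside RTSTRUCT/RTPLAN/RTDOSE/REG objects are not updated;
  changing SOP UIDs orphans them; `--keep-sop` is the escape hatch when
  those associations must survive.
- No DICOMDIR, no network transfer, no re-zipping of outputs, no
  anonymisation of names/dates.
- The intra-series frame-of-reference majority rule is a repair heuristic
  for malformed inputs; conforming data never triggers it.
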