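"""Synthetic DICOM study generators.

Two study layouts recur in practice and drive every test here:

* a multi-series brain MR study (e.g. T1, T2, FLAIR) acquired in one
  session, so all series share a single Frame of Reference UID — the case
  where a physician wants to break the implicit registration between
  sequences;
* a thoracic simulation study of a free-breathing CT plus a multi-phase
  4DCT (phase series labelled "0%", "10%", ...), all sharing one Frame of
  Reference UID — the case where the 4DCT phases must stay mutually
  registered while the link to other images is broken.

Pixel content is a small deterministic gradient plus seeded noise; it is
irrelevant to UID rewriting but must survive byte-preservation checks. A
JSON manifest of every generated UID is written beside each study so tests
can build expectations without re-parsing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import (
    CTImageStorage,
    ExplicitVRLittleEndian,
    MRImageStorage,
    PositronEmissionTomographyImageStorage,
)

from .uids import UidGenerator

__all__ = ["StudyManifest", "make_mr_study", "make_4dct_study", "make_pet_study"]

_SOP_CLASS = {
    "CT": CTImageStorage,
    "MR": MRImageStorage,
    "PT": PositronEmissionTomographyImageStorage,
}

MANIFEST_NAME = "study_manifest.json"


@dataclass
class StudyManifest:
    """Self-describing record of a generated study's UID layout."""

    study_uid: str
    frame_of_reference_uids: list[str]
    series: list[dict] = field(default_factory=list)

    def write(self, directory: Path) -> Path:
        path = Path(directory) / MANIFEST_NAME
        path.write_text(
            json.dumps(
                {
                    "study_uid": self.study_uid,
                    "frame_of_reference_uids": self.frame_of_reference_uids,
                    "series": self.series,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def read(cls, directory: Path) -> "StudyManifest":
        data = json.loads((Path(directory) / MANIFEST_NAME).read_text())
        return cls(
            study_uid=data["study_uid"],
            frame_of_reference_uids=data["frame_of_reference_uids"],
            series=data["series"],
        )

    @property
    def all_uids(self) -> set[str]:
        uids = {self.study_uid, *self.frame_of_reference_uids}
        for s in self.series:
            uids.add(s["series_uid"])
            uids.update(s["sop_uids"])
        return uids


def _write_slice(
    out: Path,
    *,
    modality: str,
    study_uid: str,
    series_uid: str,
    sop_uid: str,
    for_uid: str,
    series_number: int,
    instance_number: int,
    description: str,
    rows: int,
    cols: int,
    rng: np.random.Generator,
) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _SOP_CLASS[modality]
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _SOP_CLASS[modality]
    ds.SOPInstanceUID = sop_uid
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.FrameOfReferenceUID = for_uid
    ds.Modality = modality
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = "SYN000"
    ds.StudyDate = "20240101"
    ds.SeriesDescription = description
    ds.SeriesNumber = series_number
    ds.InstanceNumber = instance_number
    ds.ImagePositionPatient = [0.0, 0.0, float(instance_number) * 2.5]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [1.0, 1.0]
    ds.Rows = rows
    ds.Columns = cols
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"

    gradient = np.add.outer(np.arange(rows), np.arange(cols))
    noise = rng.integers(0, 64, size=(rows, cols))
    ds.PixelData = ((gradient * 16 + noise) % 65536).astype("<u2").tobytes()

    ds.save_as(out, enforce_file_format=True)


def _make_study(
    out_dir: Path | str,
    series_specs: list[dict],
    *,
    seed: int,
    rows: int = 16,
    cols: int = 16,
    shared_for: bool = True,
) -> StudyManifest:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen = UidGenerator(seed=seed)
    rng = np.random.default_rng(seed)

    study_uid = gen()
    for_uids = [gen()] if shared_for else [gen() for _ in series_specs]
    manifest = StudyManifest(study_uid=study_uid, frame_of_reference_uids=for_uids)

    for idx, spec in enumerate(series_specs):
        series_uid = gen()
        for_uid = for_uids[0] if shared_for else for_uids[idx]
        series_dir = out_dir / f"series_{idx:02d}_{spec['modality']}"
        series_dir.mkdir(exist_ok=True)
        sop_uids = []
        for inst in range(spec["n_slices"]):
            sop_uid = gen()
            sop_uids.append(sop_uid)
            _write_slice(
                series_dir / f"slice_{inst:03d}.dcm",
                modality=spec["modality"],
                study_uid=study_uid,
                series_uid=series_uid,
                sop_uid=sop_uid,
                for_uid=for_uid,
                series_number=idx + 1,
                instance_number=inst + 1,
                description=spec["description"],
                rows=rows,
                cols=cols,
                rng=rng,
            )
        manifest.series.append(
            {
                "modality": spec["modality"],
                "description": spec["description"],
                "series_uid": series_uid,
                "frame_of_reference_uid": for_uid,
                "sop_uids": sop_uids,
                "directory": series_dir.name,
            }
        )
    manifest.write(out_dir)
    return manifest


def make_mr_study(
    out_dir: Path | str, n_series: int = 3, n_slices: int = 4, seed: int = 0
) -> StudyManifest:
    """Multi-sequence brain MR study, all series sharing one frame of reference."""
    if n_series < 1 or n_slices < 1:
        raise ValueError("n_series and n_slices must be >= 1")
    names = ["T1", "T2", "FLAIR", "T1-POST", "DWI", "ADC"]
    specs = [
        {
            "modality": "MR",
            "n_slices": n_slices,
            "description": names[i % len(names)] if i < len(names) else f"MR-{i}",
        }
        for i in range(n_series)
    ]
    return _make_study(out_dir, specs, seed=seed)


def make_4dct_study(
    out_dir: Path | str,
    n_phases: int = 10,
    n_slices: int = 5,
    include_free_breathing: bool = True,
    seed: int = 0,
) -> StudyManifest:
    """Free-breathing CT plus an ``n_phases``-phase 4DCT sharing one frame of reference.

    Phase series are labelled by respiratory phase percentage ("0%", "10%",
    ...), mirroring how 4DCT reconstructions are exported.
    """
    if n_phases < 2:
        raise ValueError("a 4DCT needs at least 2 phases")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    specs = []
    if include_free_breathing:
        specs.append(
            {"modality": "CT", "n_slices": n_slices, "description": "Free-breathing"}
        )
    step = 100 // n_phases if n_phases <= 100 else 1
    specs.extend(
        {
            "modality": "CT",
            "n_slices": n_slices,
            "description": f"4DCT phase {i * step}%",
        }
        for i in range(n_phases)
    )
    return _make_study(out_dir, specs, seed=seed)


def make_pet_study(
    out_dir: Path | str, n_series: int = 1, n_slices: int = 4, seed: int = 0
) -> StudyManifest:
    """PET study variant (modality "PT") for modality-filter tests."""
    if n_series < 1 or n_slices < 1:
        raise ValueError("n_series and n_slices must be >= 1")
    specs = [
        {"modality": "PT", "n_slices": n_slices, "description": f"PET-{i}"}
        for i in range(n_series)
    ]
    return _make_study(out_dir, specs, seed=seed)
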