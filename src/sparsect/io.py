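"""Serialization: phantom TIFFs with metadata sidecars, annotation CSVs.

HU images are written as 16-bit TIFF with a +1024 offset (so -1024 HU maps
to 0); masks as 8-bit TIFFs or run-length-encoded strings inside CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from sparsect.synthetic import AnnotationRecord, PhantomSlice

HU_OFFSET = 1024


def save_phantom(slice_: PhantomSlice, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # integer-HU quantization (clinical CT stores integer HU); error <= 0.5 HU
    hu16 = np.clip(np.round(slice_.image) + HU_OFFSET, 0, 65535).astype(np.uint16)
    tifffile.imwrite(directory / f"{slice_.subject_id}.tif", hu16)
    tifffile.imwrite(
        directory / f"{slice_.subject_id}_mask.tif",
        slice_.nodule_mask.astype(np.uint8),
    )
    meta = {
        "subject_id": slice_.subject_id,
        "pixel_spacing": slice_.pixel_spacing,
        "diseased": bool(slice_.diseased),
        "nodule_diameter": slice_.nodule_diameter,
    }
    (directory / f"{slice_.subject_id}.json").write_text(json.dumps(meta, indent=2))


def load_phantom(directory: str | Path, subject_id: str) -> PhantomSlice:
    directory = Path(directory)
    meta = json.loads((directory / f"{subject_id}.json").read_text())
    image = tifffile.imread(directory / f"{subject_id}.tif").astype(np.float64) - HU_OFFSET
    mask = tifffile.imread(directory / f"{subject_id}_mask.tif").astype(bool)
    return PhantomSlice(
        subject_id=meta["subject_id"],
        image=image,
        pixel_spacing=meta["pixel_spacing"],
        diseased=meta["diseased"],
        nodule_mask=mask,
        nodule_diameter=meta["nodule_diameter"],
    )


def save_cohort(slices: Sequence[PhantomSlice], directory: str | Path) -> None:
    for s in slices:
        save_phantom(s, directory)
    index = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in slices],
            "diseased": [s.diseased for s in slices],
            "nodule_diameter_cm": [s.nodule_diameter for s in slices],
            "pixel_spacing_mm": [s.pixel_spacing for s in slices],
        }
    )
    index.to_csv(Path(directory) / "cohort.csv", index=False)


def load_cohort(directory: str | Path) -> list[PhantomSlice]:
    index = pd.read_csv(Path(directory) / "cohort.csv")
    return [load_phantom(directory, sid) for sid in index["subject_id"]]


def rle_encode(mask: np.ndarray) -> str:
    """Run-length encode a flattened boolean mask as 'H,W:start-len;...'."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    h, w = mask.shape
    if not flat.any():
        return f"{h},{w}:"
    padded = np.concatenate([[False], flat, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[::2], changes[1::2]
    runs = ";".join(f"{s}-{e - s}" for s, e in zip(starts, ends))
    return f"{h},{w}:{runs}"


def rle_decode(text: str) -> np.ndarray:
    header, _, runs = text.partition(":")
    h, w = (int(t) for t in header.split(","))
    mask = np.zeros(h * w, dtype=bool)
    if runs:
        for run in runs.split(";"):
            start, length = (int(t) for t in run.split("-"))
            mask[start : start + length] = True
    return mask.reshape(h, w)


def save_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "reader_id": [r.reader_id for r in records],
            "subject_id": [r.subject_id for r in records],
            "view_count": [r.view_count for r in records],
            "arm": [r.arm for r in records],
            "quality": [r.quality for r in records],
            "confidence": [r.confidence for r in records],
            "artifact": [r.artifact for r in records],
            "segmentation_rle": [rle_encode(r.segmentation) for r in records],
        }
    )
    frame.to_csv(path, index=False)


def load_annotations(path: str | Path) -> list[AnnotationRecord]:
    frame = pd.read_csv(path, keep_default_na=False)
    return [
        AnnotationRecord(
            reader_id=str(row.reader_id),
            subject_id=str(row.subject_id),
            view_count=int(row.view_count),
            arm=str(row.arm),
            quality=int(row.quality),
            confidence=int(row.confidence),
            artifact=int(row.artifact),
            segmentation=rle_decode(str(row.segmentation_rle)),
        )
        for row in frame.itertuples()
    ]
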