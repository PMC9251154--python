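"""Reading and writing slices, volumes, truth sidecars and results."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from ._core import ImageSlice, ImageVolume, ValidationError
from .phantom import PhantomTruth


def write_slice(path, image: ImageSlice) -> None:
    """Write a slice as 16-bit PNG/TIFF, linearly rescaled to the dtype range."""
    path = Path(path)
    arr = image.data
    lo, hi = float(arr.min()), float(arr.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    iio.imwrite(path, ((arr - lo) * scale).astype(np.uint16))


def read_slice(path, spacing_mm=(1.0, 1.0)) -> ImageSlice:
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # collapse RGB(A)
        arr = arr[..., :3].mean(axis=-1)
    return ImageSlice(arr, spacing_mm=tuple(spacing_mm))


def write_volume(path, volume: ImageVolume) -> None:
    """Write a volume as NIfTI-1 with spacing carried in the affine."""
    # NIfTI axes are (x, y, z); our array is (slice, row, col)
    data = np.transpose(volume.data, (2, 1, 0)).astype(np.float32)
    affine = np.diag([volume.spacing_mm[2], volume.spacing_mm[1],
                      volume.spacing_mm[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    data = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 1, 0))
    return ImageVolume(data, spacing_mm=(float(zooms[2]), float(zooms[1]),
                                         float(zooms[0])))


def write_truth(path, truth: PhantomTruth) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)


def read_truth(path) -> PhantomTruth:
    with open(path) as fh:
        doc = json.load(fh)
    return PhantomTruth(
        true_circles=[tuple(c) for c in doc.get("true_circles", [])],
        true_lines=[tuple(l) for l in doc.get("true_lines", [])],
        true_ac=tuple(doc["true_ac"]) if doc.get("true_ac") else None,
        true_pc=tuple(doc["true_pc"]) if doc.get("true_pc") else None,
        frame_points=[tuple(p) for p in doc.get("frame_points", [])],
    )


def write_json(path, obj) -> None:
    """Dump dataclasses / numpy containers as plain JSON."""
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
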