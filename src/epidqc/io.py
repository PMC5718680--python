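"""Reading and writing portal images (DICOM, TIFF, BMP).

TIFF and DICOM are written as 16-bit grayscale and round-trip bit-exactly.
BMP is an 8-bit format: on write, gray values are linearly rescaled from the
16-bit range [0, 65535] to [0, 255] (lossy, kept only because the format is
in common clinical use); on read they are expanded back with the inverse
scale.  Imager geometry travels with the file where the format allows it
(a JSON block in the TIFF ImageDescription, PixelSpacing + ImageComments in
DICOM); BMP carries no metadata, so reading a BMP requires an explicit
:class:`~epidqc.phantom.ImagerSpec`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pydicom
import tifffile
from PIL import Image as PILImage
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .errors import FormatError
from .phantom import ImagerSpec
from .simulate import MAX_GRAY, PortalImage

__all__ = ["write_image", "read_image"]

_FORMATS = ("dicom", "tiff", "bmp")
_EXT_TO_FORMAT = {".dcm": "dicom", ".dicom": "dicom",
                  ".tif": "tiff", ".tiff": "tiff", ".bmp": "bmp"}


def _imager_blob(imager: ImagerSpec) -> str:
    return json.dumps({"epidqc_imager": dataclasses.asdict(imager)})


def _imager_from_blob(text: str) -> ImagerSpec | None:
    try:
        data = json.loads(text)["epidqc_imager"]
    except (json.JSONDecodeError, KeyError, TypeError):
        return None
    data["n_pixels"] = tuple(data["n_pixels"])
    data["panel_extent"] = tuple(data["panel_extent"])
    return ImagerSpec(**data)


def _as_uint16(pixels: np.ndarray) -> np.ndarray:
    if pixels.dtype == np.uint16:
        return pixels
    return np.round(np.clip(np.asarray(pixels, dtype=float), 0, MAX_GRAY)).astype(np.uint16)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = _EXT_TO_FORMAT.get(path.suffix.lower())
    if fmt not in _FORMATS:
        raise FormatError(f"unsupported image format for {path.name!r} "
                          f"(supported: {', '.join(_FORMATS)})")
    return fmt


def write_image(image: PortalImage, path, format: str | None = None) -> Path:
    """Write a portal image; the format is inferred from the suffix if omitted."""
    path = Path(path)
    fmt = _infer_format(path, format)
    px = _as_uint16(image.pixels)
    if fmt == "tiff":
        tifffile.imwrite(path, px, description=_imager_blob(image.imager))
    elif fmt == "dicom":
        _write_dicom(px, image.imager, path)
    else:  # bmp: 8-bit, linear rescale from the 16-bit range
        px8 = np.round(px.astype(float) * (255.0 / MAX_GRAY)).astype(np.uint8)
        PILImage.fromarray(px8, mode="L").save(path, format="BMP")
    return path


def _write_dicom(px: np.ndarray, imager: ImagerSpec, path: Path) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SeriesDescription = f"epidqc synthetic portal image ({imager.vendor_label})"
    ds.Rows, ds.Columns = px.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [str(imager.pixel_pitch), str(imager.pixel_pitch)]
    ds.ImageComments = _imager_blob(imager)
    ds.PixelData = px.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_image(path, imager: ImagerSpec | None = None) -> PortalImage:
    """Read a portal image written by :func:`write_image`.

    For TIFF/DICOM the imager geometry is recovered from the embedded
    metadata when ``imager`` is not given.  BMP files carry no metadata and
    require the ``imager`` argument.
    """
    path = Path(path)
    fmt = _infer_format(path, None)
    if fmt == "tiff":
        try:
            with tifffile.TiffFile(path) as tf:
                px = tf.asarray()
                desc = tf.pages[0].description or ""
        except (tifffile.TiffFileError, ValueError) as exc:
            raise FormatError(f"cannot parse TIFF {path.name!r}: {exc}") from exc
        found = _imager_from_blob(desc)
    elif fmt == "dicom":
        try:
            ds = pydicom.dcmread(path)
            px = ds.pixel_array
        except Exception as exc:
            raise FormatError(f"cannot parse DICOM {path.name!r}: {exc}") from exc
        found = _imager_from_blob(getattr(ds, "ImageComments", ""))
        if found is None and "PixelSpacing" in ds:
            pitch = float(ds.PixelSpacing[0])
            found = ImagerSpec("unknown", tuple(px.shape), pitch,
                               (px.shape[1] * pitch / 10.0, px.shape[0] * pitch / 10.0),
                               160.0)
    else:  # bmp
        try:
            pil = PILImage.open(path)
            px8 = np.asarray(pil.convert("L"))
        except Exception as exc:
            raise FormatError(f"cannot parse BMP {path.name!r}: {exc}") from exc
        px = np.round(px8.astype(float) * (MAX_GRAY / 255.0)).astype(np.uint16)
        found = None

    px = np.asarray(px)
    if px.ndim != 2:
        raise FormatError(f"{path.name!r} does not hold a 2-D grayscale image")
    spec = imager or found
    if spec is None:
        raise FormatError(
            f"{path.name!r} carries no imager metadata; pass an ImagerSpec")
    return PortalImage(pixels=px, imager=spec,
                       metadata={"source_path": str(path), "format": fmt})
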