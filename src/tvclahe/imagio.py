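"""Grayscale image container and lossless I/O.

All enhancement and metric code in this package operates on a single
in-memory currency, :class:`GrayImage`: a 2-D grid of non-negative
integer gray levels with a declared bit depth (8 or 16).  Periapical
radiographs are typically stored as 16-bit single-frame monochrome
DICOM; PNG and TIFF are supported for phantoms and exported results.

The enhancement pipeline and the 256-bin histogram metrics are defined
on 8-bit images, so 16-bit inputs are reduced with :func:`to_8bit`
(observed min--max rescale) before processing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GrayImage",
    "UnsupportedFormatError",
    "read_image",
    "write_image",
    "to_8bit",
]


class UnsupportedFormatError(ValueError):
    """Raised for inputs outside the supported grayscale formats."""


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest integer with halves away from zero (upward).

    A single fixed rounding rule keeps every pipeline stage
    bit-reproducible across platforms (numpy's default rounds half to
    even, which is correct numerically but surprises in histogram
    mappings).
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with an explicit bit depth.

    Attributes
    ----------
    pixels : numpy.ndarray
        2-D integer array, dtype uint8 (bit_depth 8) or uint16 (16).
    bit_depth : int
        8 or 16; the number of gray levels is ``L = 2**bit_depth``.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"image too small: {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(px == np.floor(px)):
                raise ValueError("pixels must be integer-valued")
        lo, hi = int(px.min()), int(px.max())
        if lo < 0 or hi > self.max_value:
            raise ValueError(
                f"pixel values [{lo}, {hi}] outside [0, {self.max_value}] "
                f"for bit depth {self.bit_depth}"
            )
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        object.__setattr__(self, "pixels", px.astype(dtype, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_levels(self) -> int:
        """Number of representable gray levels, L = 2**bit_depth."""
        return 1 << self.bit_depth

    @property
    def max_value(self) -> int:
        """Maximum representable intensity, MAX = L - 1."""
        return (1 << self.bit_depth) - 1

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.bit_depth == other.bit_depth and np.array_equal(
            self.pixels, other.pixels
        )


def to_8bit(img: GrayImage) -> GrayImage:
    """Reduce an image to 8 bits by observed min--max rescale.

    8-bit inputs are returned as an identical copy.  16-bit inputs are
    mapped linearly so the observed minimum becomes 0 and the observed
    maximum 255 (round half up); a constant image maps to the mid-gray
    128.  The map is monotone and idempotent.
    """
    if img.bit_depth == 8:
        return GrayImage(img.pixels.copy(), 8)
    px = img.astype_float()
    lo, hi = px.min(), px.max()
    if hi == lo:
        return GrayImage(np.full(px.shape, 128, dtype=np.uint8), 8)
    out = round_half_up((px - lo) / (hi - lo) * 255.0)
    return GrayImage(out.astype(np.uint8), 8)


def _read_dicom(path: Path) -> GrayImage:
    import pydicom

    ds = pydicom.dcmread(path)
    tsyntax = ds.file_meta.TransferSyntaxUID if hasattr(ds, "file_meta") else None
    if tsyntax is not None and tsyntax.is_compressed:
        raise UnsupportedFormatError(
            f"compressed TransferSyntaxUID {tsyntax} is not supported"
        )
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise UnsupportedFormatError(
            f"multi-frame DICOM (NumberOfFrames={ds.NumberOfFrames}) is not supported"
        )
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError(
            f"color DICOM (SamplesPerPixel={ds.SamplesPerPixel}) is not supported"
        )
    bits = int(getattr(ds, "BitsAllocated", 16))
    if bits not in (8, 16):
        raise UnsupportedFormatError(f"BitsAllocated={bits} is not supported")
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    arr = np.clip(round_half_up(arr), 0, (1 << bits) - 1)
    return GrayImage(arr.astype(np.uint8 if bits == 8 else np.uint16), bits)


def _read_raster(path: Path) -> GrayImage:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        raise UnsupportedFormatError(
            f"color image with {arr.shape[2]} channels is not supported (file {path.name})"
        )
    if arr.dtype == np.uint8:
        return GrayImage(arr, 8)
    if arr.dtype == np.uint16:
        return GrayImage(arr, 16)
    raise UnsupportedFormatError(f"unsupported pixel dtype {arr.dtype}")


def read_image(path: str | os.PathLike) -> GrayImage:
    """Read a single-frame grayscale image (DICOM, PNG or TIFF).

    Bit depth is inferred from the stored data; DICOM rescale
    slope/intercept are applied and the result clamped to the stored
    bit depth.  No resampling is performed.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return _read_dicom(path)
    if suffix in (".png", ".tif", ".tiff"):
        return _read_raster(path)
    # fall back on content sniffing for extension-less DICOM
    with open(path, "rb") as fh:
        preamble = fh.read(132)
    if preamble[128:132] == b"DICM":
        return _read_dicom(path)
    raise UnsupportedFormatError(f"unrecognized image format: {path.name}")


def _write_dicom(img: GrayImage, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = img.height, img.width
    ds.BitsAllocated = img.bit_depth
    ds.BitsStored = img.bit_depth
    ds.HighBit = img.bit_depth - 1
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(img.pixels).tobytes()
    ds.save_as(path, enforce_file_format=True)


def write_image(img: GrayImage, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write ``img`` losslessly at its native bit depth.

    ``fmt`` is one of ``png``, ``tiff``, ``dicom``; when omitted it is
    inferred from the path suffix.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".png": "png", ".tif": "tiff", ".tiff": "tiff", ".dcm": "dicom",
               ".dicom": "dicom"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix of {path.name}")
    fmt = fmt.lower()
    if path.is_dir():
        raise IsADirectoryError(path)
    if fmt == "dicom":
        _write_dicom(img, path)
    elif fmt in ("png", "tiff"):
        import imageio.v3 as iio

        iio.imwrite(path, img.pixels, extension=".png" if fmt == "png" else ".tiff")
    else:
        raise ValueError(f"unsupported format {fmt!r} (png, tiff, dicom)")
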