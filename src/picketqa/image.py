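"""Raw portal-image handling: decoding, open-field normalization, DICOM I/O.

The imager stores 16-bit values in an inverted ("raw") encoding: the signal
deposited by the beam is ``65535 - stored``.  Every picket-fence image is
divided by an open-field image acquired in the same session, which cancels
session-to-session output and beam-energy fluctuations (both images share
the same output factor) and flattens the panel response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .geometry import GeometryModel

__all__ = [
    "EpidImage",
    "NormalizedImage",
    "decode_signal",
    "encode_signal",
    "normalize",
    "read_dicom",
    "write_dicom",
]

RAW_FULL_SCALE = 65535


@dataclass
class EpidImage:
    """A raw-encoded 16-bit portal image plus acquisition metadata."""

    pixels: np.ndarray  # uint16 stored values, shape (rows, cols)
    geometry: GeometryModel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixels.dtype != np.uint16:
            if self.pixels.min() < 0 or self.pixels.max() > RAW_FULL_SCALE:
                raise ValueError("stored values must lie in [0, 65535]")
            self.pixels = self.pixels.astype(np.uint16)

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class NormalizedImage:
    """Open-field-normalized image: unitless ratios on the panel grid.

    ``values`` is a masked array; pixels where the open field carries no
    usable signal are masked rather than divided through.
    """

    values: np.ma.MaskedArray
    geometry: GeometryModel

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            data=np.ma.filled(self.values, np.nan),
            mask=np.ma.getmaskarray(self.values),
            geometry=json.dumps(
                {
                    "sdd": self.geometry.sdd,
                    "sad": self.geometry.sad,
                    "pixel_pitch_panel": self.geometry.pixel_pitch_panel,
                    "rows": self.geometry.rows,
                    "cols": self.geometry.cols,
                    "origin_row": self.geometry.origin_row,
                    "origin_col": self.geometry.origin_col,
                }
            ),
        )

    @classmethod
    def load(cls, path) -> "NormalizedImage":
        with np.load(path, allow_pickle=False) as z:
            geom = GeometryModel(**json.loads(str(z["geometry"])))
            values = np.ma.MaskedArray(z["data"], mask=z["mask"])
        return cls(values=values, geometry=geom)


def decode_signal(image: EpidImage | np.ndarray) -> np.ndarray:
    """Decode stored values to beam signal: ``65535 - stored``."""
    stored = image.pixels if isinstance(image, EpidImage) else np.asarray(image)
    return RAW_FULL_SCALE - stored.astype(np.int64)


def encode_signal(signal: np.ndarray) -> np.ndarray:
    """Encode a (non-negative) signal grid back to stored uint16 values."""
    s = np.rint(np.asarray(signal)).astype(np.int64)
    s = np.clip(s, 0, RAW_FULL_SCALE)
    return (RAW_FULL_SCALE - s).astype(np.uint16)


def open_field_floor(open_signal: np.ndarray, fraction: float = 0.05) -> float:
    """Default usable-signal floor: a fraction of the median in-field signal.

    "In field" is taken as the upper half of the open image's signal range,
    which is robust to the blocked border of the panel.
    """
    sig = np.asarray(open_signal, dtype=float)
    hi = sig[sig > 0.5 * sig.max()] if sig.max() > 0 else sig
    return fraction * float(np.median(hi))


def normalize(
    raw_signal: np.ndarray,
    open_signal: np.ndarray,
    geometry: GeometryModel,
    floor: float | None = None,
) -> NormalizedImage:
    """Divide a field image by the session's open-field image.

    Pixels where the open field is at or below ``floor`` are masked, never
    divided.  ``floor`` defaults to 5% of the open field's median in-field
    signal.
    """
    raw = np.asarray(raw_signal, dtype=float)
    opn = np.asarray(open_signal, dtype=float)
    if raw.shape != opn.shape:
        raise ValueError(f"shape mismatch: raw {raw.shape} vs open {opn.shape}")
    if floor is None:
        floor = open_field_floor(opn)
    usable = opn > floor
    if not usable.any():
        raise ValueError("entire open field below the usable-signal floor")
    values = np.ma.MaskedArray(np.zeros_like(raw), mask=~usable)
    values[usable] = raw[usable] / opn[usable]
    return NormalizedImage(values=values, geometry=geometry)


def normalize_images(field: EpidImage, open_field: EpidImage, floor: float | None = None) -> NormalizedImage:
    """Convenience wrapper: decode both images and normalize."""
    return normalize(decode_signal(field), decode_signal(open_field), field.geometry, floor)


# ---------------------------------------------------------------------------
# DICOM I/O.  Secondary-capture monochrome, 16 bit, raw encoding preserved.
# Geometry and provenance travel in ImageComments as a JSON blob so a file
# read back is analyzable without external configuration.
# ---------------------------------------------------------------------------

def write_dicom(image: EpidImage, path) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTIMAGE"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = image.pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [image.geometry.pixel_pitch_panel, image.geometry.pixel_pitch_panel]
    g = image.geometry
    ds.ImageComments = json.dumps(
        {
            "sdd": g.sdd,
            "sad": g.sad,
            "pixel_pitch_panel": g.pixel_pitch_panel,
            "origin_row": g.origin_row,
            "origin_col": g.origin_col,
            **{k: v for k, v in image.metadata.items() if isinstance(v, (int, float, str, bool))},
        }
    )
    ds.PixelData = image.pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_dicom(path) -> EpidImage:
    ds = pydicom.dcmread(path)
    pixels = ds.pixel_array.astype(np.uint16)
    metadata: dict = {}
    try:
        metadata = json.loads(getattr(ds, "ImageComments", "") or "{}")
    except json.JSONDecodeError:
        metadata = {}
    geometry = GeometryModel(
        sdd=float(metadata.get("sdd", 160.0)),
        sad=float(metadata.get("sad", 100.0)),
        pixel_pitch_panel=float(metadata.get("pixel_pitch_panel", float(ds.PixelSpacing[0]))),
        rows=int(ds.Rows),
        cols=int(ds.Columns),
        origin_row=metadata.get("origin_row"),
        origin_col=metadata.get("origin_col"),
    )
    return EpidImage(pixels=pixels, geometry=geometry, metadata=metadata)
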