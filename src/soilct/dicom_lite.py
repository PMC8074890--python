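"""Tiny DICOM codec for uncompressed CT slices.

Supports exactly one encoding: Part-10 files with a standard preamble and
Explicit VR Little Endian transfer syntax, single-frame 16-bit grayscale
pixel data. That is the subset the pipeline's own exporter writes and the
subset medical CT series commonly use; anything else raises. No DICOM
library exists in the runtime environment, hence this module.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
_UID_ROOT = "1.2.826.0.1.3680043.10.1457"

# VRs whose explicit-VR encoding uses a 2-byte reserved field + 4-byte length
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

TAG_TRANSFER_SYNTAX = (0x0002, 0x0010)
TAG_SOP_CLASS = (0x0008, 0x0016)
TAG_SOP_INSTANCE = (0x0008, 0x0018)
TAG_SERIES_ID = (0x0020, 0x000E)
TAG_INSTANCE_NUMBER = (0x0020, 0x0013)
TAG_IMAGE_POSITION = (0x0020, 0x0032)
TAG_SLICE_LOCATION = (0x0020, 0x1041)
TAG_SAMPLES_PER_PIXEL = (0x0028, 0x0002)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_SLICE_THICKNESS = (0x0018, 0x0050)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_BITS_STORED = (0x0028, 0x0101)
TAG_HIGH_BIT = (0x0028, 0x0102)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
TAG_RESCALE_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)


@dataclass
class DicomSlice:
    pixels: np.ndarray            # (rows, cols) int32, stored values
    position: float               # mm along the slice axis
    instance_number: int
    rescale_slope: float
    rescale_intercept: float
    slice_spacing: float
    pixel_spacing: tuple[float, float]
    series_id: str


def _encode_element(group: int, element: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr != b"UI" else b"\x00"
    head = struct.pack("<HH", group, element) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    if len(value) > 0xFFFF:
        raise ValueError("value too long for short-form VR")
    return head + struct.pack("<H", len(value)) + value


def _txt(s) -> bytes:
    return str(s).encode("ascii")


def write_slice(path, pixels: np.ndarray, *, instance_number: int,
                position: float, slice_spacing: float,
                pixel_spacing: tuple[float, float], series_id: str) -> None:
    """Write one signed-16-bit grayscale slice as an explicit-VR-LE file."""
    pixels = np.ascontiguousarray(pixels, dtype="<i2")
    if pixels.ndim != 2:
        raise ValueError("pixels must be 2D")
    rows, cols = pixels.shape
    sop_uid = f"{_UID_ROOT}.{zlib.crc32(series_id.encode()) % 10**8}.{instance_number}"

    meta = b"".join([
        _encode_element(0x0002, 0x0002, b"UI", _txt(CT_SOP_CLASS)),
        _encode_element(0x0002, 0x0003, b"UI", _txt(sop_uid)),
        _encode_element(0x0002, 0x0010, b"UI", _txt(EXPLICIT_VR_LE)),
    ])
    meta = _encode_element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta))) + meta

    body = b"".join([
        _encode_element(*TAG_SOP_CLASS, b"UI", _txt(CT_SOP_CLASS)),
        _encode_element(*TAG_SOP_INSTANCE, b"UI", _txt(sop_uid)),
        _encode_element(*TAG_SLICE_THICKNESS, b"DS", _txt(slice_spacing)),
        _encode_element(*TAG_SERIES_ID, b"UI", _txt(
            f"{_UID_ROOT}.{zlib.crc32(series_id.encode()) % 10**8}")),
        _encode_element(*TAG_INSTANCE_NUMBER, b"IS", _txt(instance_number)),
        _encode_element(*TAG_IMAGE_POSITION, b"DS", _txt(f"0\\0\\{position}")),
        _encode_element(*TAG_SLICE_LOCATION, b"DS", _txt(position)),
        _encode_element(*TAG_SAMPLES_PER_PIXEL, b"US", struct.pack("<H", 1)),
        _encode_element(*TAG_ROWS, b"US", struct.pack("<H", rows)),
        _encode_element(*TAG_COLS, b"US", struct.pack("<H", cols)),
        _encode_element(*TAG_PIXEL_SPACING, b"DS",
                        _txt(f"{pixel_spacing[0]}\\{pixel_spacing[1]}")),
        _encode_element(*TAG_BITS_ALLOCATED, b"US", struct.pack("<H", 16)),
        _encode_element(*TAG_BITS_STORED, b"US", struct.pack("<H", 16)),
        _encode_element(*TAG_HIGH_BIT, b"US", struct.pack("<H", 15)),
        _encode_element(*TAG_PIXEL_REPRESENTATION, b"US", struct.pack("<H", 1)),
        _encode_element(*TAG_RESCALE_INTERCEPT, b"DS", _txt(0)),
        _encode_element(*TAG_RESCALE_SLOPE, b"DS", _txt(1)),
        _encode_element(*TAG_PIXEL_DATA, b"OW", pixels.tobytes()),
    ])

    Path(path).write_bytes(b"\x00" * 128 + b"DICM" + meta + body)


def _parse_elements(buf: bytes, start: int):
    """Yield (tag, vr, value_bytes) for explicit-VR-LE elements."""
    pos = start
    n = len(buf)
    while pos + 8 <= n:
        group, element = struct.unpack_from("<HH", buf, pos)
        vr = buf[pos + 4:pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            value_start = pos + 12
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            value_start = pos + 8
        if length == 0xFFFFFFFF:
            raise ValueError("undefined-length elements are not supported")
        value_end = value_start + length
        if value_end > n:
            raise ValueError("truncated DICOM element")
        yield (group, element), vr, buf[value_start:value_end]
        pos = value_end


def read_slice(path) -> DicomSlice:
    """Parse one explicit-VR-LE single-frame CT slice."""
    buf = Path(path).read_bytes()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise ValueError(f"{path}: not a Part-10 DICOM file")

    elements: dict[tuple[int, int], bytes] = {}
    meta_end = 132
    # file meta group first; find where group 0002 ends
    for tag, vr, value in _parse_elements(buf, 132):
        if tag[0] != 0x0002:
            break
        if tag == (0x0002, 0x0000):
            (glen,) = struct.unpack("<I", value)
            meta_end = 132 + 12 + glen
        elements[tag] = value
    ts = elements.get(TAG_TRANSFER_SYNTAX, b"").decode("ascii").rstrip("\x00 ")
    if ts and ts != EXPLICIT_VR_LE:
        raise ValueError(f"{path}: unsupported transfer syntax {ts!r}")

    for tag, vr, value in _parse_elements(buf, meta_end):
        elements[tag] = value

    def ds(tag, default=None):
        raw = elements.get(tag)
        if raw is None:
            if default is None:
                raise ValueError(f"{path}: missing required tag {tag}")
            return default
        return [float(v) for v in raw.decode("ascii").strip("\x00 ").split("\\")]

    def us(tag):
        raw = elements.get(tag)
        if raw is None:
            raise ValueError(f"{path}: missing required tag {tag}")
        return struct.unpack("<H", raw[:2])[0]

    rows, cols = us(TAG_ROWS), us(TAG_COLS)
    bits = us(TAG_BITS_ALLOCATED)
    if bits != 16:
        raise ValueError(f"{path}: only 16-bit pixel data supported, got {bits}")
    signed = us(TAG_PIXEL_REPRESENTATION) == 1
    pix = elements.get(TAG_PIXEL_DATA)
    if pix is None:
        raise ValueError(f"{path}: missing pixel data")
    dtype = "<i2" if signed else "<u2"
    arr = np.frombuffer(pix[:rows * cols * 2], dtype=dtype)
    if arr.size != rows * cols:
        raise ValueError(f"{path}: pixel data size mismatch")

    position_vals = ds(TAG_IMAGE_POSITION, default=[0.0, 0.0, float("nan")])
    position = position_vals[-1]
    if position != position:  # NaN -> fall back to slice location / instance no.
        position = ds(TAG_SLICE_LOCATION, default=[float(
            int(elements.get(TAG_INSTANCE_NUMBER, b"0").decode("ascii").strip("\x00 ") or 0)
        )])[0]

    return DicomSlice(
        pixels=arr.reshape(rows, cols).astype(np.int32),
        position=position,
        instance_number=int(
            elements.get(TAG_INSTANCE_NUMBER, b"0").decode("ascii").strip("\x00 ") or 0),
        rescale_slope=ds(TAG_RESCALE_SLOPE, default=[1.0])[0],
        rescale_intercept=ds(TAG_RESCALE_INTERCEPT, default=[0.0])[0],
        slice_spacing=ds(TAG_SLICE_THICKNESS, default=[1.0])[0],
        pixel_spacing=tuple(ds(TAG_PIXEL_SPACING, default=[1.0, 1.0])[:2]),
        series_id=elements.get(TAG_SERIES_ID, b"").decode("ascii").rstrip("\x00 "),
    )
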