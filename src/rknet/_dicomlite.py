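"""Minimal single-frame DICOM codec (explicit VR, little endian, uncompressed).

The sandboxed toolchain ships no general DICOM library, and this package only
needs to round-trip the small, flat datasets its own fixtures and ingestion
path use: Part-10 files with a 128-byte preamble, explicit-VR little-endian
transfer syntax, one uncompressed 16-bit frame, and no sequences. Anything
outside that envelope raises ``ValueError`` rather than guessing.

A dataset is represented as ``dict[str, object]`` keyed by keyword (e.g.
``"PatientName"``); pixel data is a 2-D ``numpy`` array under ``"PixelData"``.
"""

from __future__ import annotations

import struct
from typing import Any, Dict

import numpy as np

MAGIC_OFFSET = 128
MAGIC = b"DICM"

#: transfer syntax UID for explicit VR little endian
EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"

# keyword -> (group, element, VR)
TAGS: Dict[str, tuple] = {
    "TransferSyntaxUID": (0x0002, 0x0010, "UI"),
    "SOPInstanceUID": (0x0008, 0x0018, "UI"),
    "Modality": (0x0008, 0x0060, "CS"),
    "InstitutionName": (0x0008, 0x0080, "LO"),
    "ReferringPhysicianName": (0x0008, 0x0090, "PN"),
    "OperatorsName": (0x0008, 0x1070, "PN"),
    "PatientName": (0x0010, 0x0010, "PN"),
    "PatientID": (0x0010, 0x0020, "LO"),
    "PatientBirthDate": (0x0010, 0x0030, "DA"),
    "PatientAddress": (0x0010, 0x1040, "LO"),
    "PatientTelephoneNumbers": (0x0010, 0x2154, "SH"),
    "SeriesInstanceUID": (0x0020, 0x000E, "UI"),
    "InstanceNumber": (0x0020, 0x0013, "IS"),
    "ImagePositionPatient": (0x0020, 0x0032, "DS"),
    "SliceLocation": (0x0020, 0x1041, "DS"),
    "Rows": (0x0028, 0x0010, "US"),
    "Columns": (0x0028, 0x0011, "US"),
    "BitsAllocated": (0x0028, 0x0100, "US"),
    "BitsStored": (0x0028, 0x0101, "US"),
    "HighBit": (0x0028, 0x0102, "US"),
    "PixelRepresentation": (0x0028, 0x0103, "US"),
    "RescaleIntercept": (0x0028, 0x1052, "DS"),
    "RescaleSlope": (0x0028, 0x1053, "DS"),
    "PixelData": (0x7FE0, 0x0010, "OW"),
}

_TAG_TO_KEYWORD = {(g, e): (kw, vr) for kw, (g, e, vr) in TAGS.items()}

# VRs whose explicit encoding uses a 2-byte reserved field + 4-byte length
_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}

_TEXT_VRS = {"AE", "AS", "CS", "DA", "DS", "DT", "IS", "LO", "LT", "PN",
             "SH", "ST", "TM", "UI", "UC", "UR"}


def _encode_value(vr: str, value: Any) -> bytes:
    if vr == "US":
        return struct.pack("<H", int(value))
    if vr == "UL":
        return struct.pack("<I", int(value))
    if vr == "OW":
        arr = np.asarray(value)
        if arr.dtype not in (np.dtype("<u2"), np.dtype("<i2")):
            raise ValueError("OW payload must be 16-bit")
        return arr.astype(arr.dtype.newbyteorder("<")).tobytes()
    if vr in _TEXT_VRS:
        if isinstance(value, (list, tuple)):
            value = "\\".join(str(v) for v in value)
        raw = str(value).encode("ascii")
        if len(raw) % 2:
            raw += b"\x00" if vr == "UI" else b" "
        return raw
    raise ValueError(f"unsupported VR {vr}")


def _decode_value(vr: str, raw: bytes) -> Any:
    if vr == "US":
        return struct.unpack("<H", raw)[0]
    if vr == "UL":
        return struct.unpack("<I", raw)[0]
    if vr == "OW":
        return raw  # caller reshapes with Rows/Columns/PixelRepresentation
    text = raw.decode("ascii", errors="replace").rstrip("\x00 ")
    if vr == "IS":
        return int(text) if text else None
    if vr == "DS":
        parts = text.split("\\")
        vals = [float(p) for p in parts if p != ""]
        return vals if len(vals) > 1 else (vals[0] if vals else None)
    return text


def _element(group: int, elem: int, vr: str, payload: bytes) -> bytes:
    head = struct.pack("<HH", group, elem) + vr.encode("ascii")
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(payload)) + payload
    if len(payload) > 0xFFFF:
        raise ValueError("value too long for short VR")
    return head + struct.pack("<H", len(payload)) + payload


def write_file(path, dataset: Dict[str, Any]) -> None:
    """Serialize ``dataset`` as a Part-10 explicit-VR-LE file.

    Elements are emitted in ascending tag order as DICOM requires. The file
    meta group is reduced to the transfer syntax UID.
    """
    body = []
    items = []
    for kw, value in dataset.items():
        if kw == "TransferSyntaxUID":
            continue
        if kw not in TAGS:
            raise ValueError(f"unknown keyword {kw!r}")
        group, elem, vr = TAGS[kw]
        items.append((group, elem, vr, value))
    items.sort(key=lambda t: (t[0], t[1]))
    for group, elem, vr, value in items:
        body.append(_element(group, elem, vr, _encode_value(vr, value)))

    meta = _element(0x0002, 0x0010, "UI", _encode_value("UI", EXPLICIT_VR_LE))
    # (0002,0000) FileMetaInformationGroupLength, UL, length of rest of group 2
    head = _element(0x0002, 0x0000, "UL", struct.pack("<I", len(meta)))

    with open(path, "wb") as fh:
        fh.write(b"\x00" * MAGIC_OFFSET)
        fh.write(MAGIC)
        fh.write(head)
        fh.write(meta)
        fh.write(b"".join(body))


def looks_like_dicom(path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(MAGIC_OFFSET)
            return fh.read(4) == MAGIC
    except OSError:
        return False


def read_file(path) -> Dict[str, Any]:
    """Parse a Part-10 explicit-VR-LE file into a keyword-keyed dict.

    Unknown tags are skipped; sequences and compressed pixel data raise.
    ``PixelData`` is reshaped to (Rows, Columns) with signedness taken from
    ``PixelRepresentation``.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if blob[MAGIC_OFFSET:MAGIC_OFFSET + 4] != MAGIC:
        raise ValueError("not a DICOM part-10 file")

    out: Dict[str, Any] = {}
    pos = MAGIC_OFFSET + 4
    n = len(blob)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", blob, pos)
        vr = blob[pos + 4:pos + 6].decode("ascii", errors="replace")
        if vr == "SQ":
            raise ValueError("sequences are not supported")
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", blob, pos + 8)
            start = pos + 12
        else:
            (length,) = struct.unpack_from("<H", blob, pos + 6)
            start = pos + 8
        if length == 0xFFFFFFFF:
            raise ValueError("undefined-length elements are not supported")
        raw = blob[start:start + length]
        if len(raw) != length:
            raise ValueError("truncated element")
        pos = start + length
        key = _TAG_TO_KEYWORD.get((group, elem))
        if key is None:
            continue
        kw, expected_vr = key
        out[kw] = _decode_value(expected_vr, raw)

    if "PixelData" in out:
        rows, cols = int(out["Rows"]), int(out["Columns"])
        signed = int(out.get("PixelRepresentation", 0)) == 1
        dtype = "<i2" if signed else "<u2"
        arr = np.frombuffer(out["PixelData"], dtype=dtype)
        if arr.size != rows * cols:
            raise ValueError("pixel data size mismatch")
        out["PixelData"] = arr.reshape(rows, cols).copy()
    return out
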