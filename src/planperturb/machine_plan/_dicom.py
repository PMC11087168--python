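"""Minimal DICOM codec: explicit-VR little-endian datasets with sequences.

Only the small element vocabulary needed for RT Plan files is supported.
Datasets are plain dicts mapping ``(group, element)`` tags to ``(VR, value)``
tuples; SQ values are lists of nested dataset dicts, text VRs are Python
strings (multi-valued DS/IS joined with ``\\``), OB values are bytes.
"""

from __future__ import annotations

import struct
from typing import Dict, List, Tuple, Union

Tag = Tuple[int, int]
Value = Union[str, bytes, List["Dataset"]]
Dataset = Dict[Tag, Tuple[str, Value]]

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"

_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}
_TEXT_VRS = {"AE", "AS", "CS", "DA", "DS", "DT", "IS", "LO", "LT", "PN", "SH", "ST", "TM", "UI"}

_ITEM = (0xFFFE, 0xE000)
_ITEM_DELIM = (0xFFFE, 0xE00D)
_SEQ_DELIM = (0xFFFE, 0xE00E)


class DicomError(ValueError):
    """Raised on malformed or unsupported DICOM input."""


def format_ds(x: float) -> str:
    """Format a float as a DICOM decimal string (<= 16 chars)."""
    s = f"{float(x):.10g}"
    if len(s) > 16:
        s = f"{float(x):.8g}"
    return s


def _pad(value: bytes, vr: str) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in ("UI", "OB") else b" "
    return value


def _encode_element(tag: Tag, vr: str, value: Value) -> bytes:
    group, elem = tag
    if vr == "SQ":
        body = b""
        for item in value:  # type: ignore[union-attr]
            item_bytes = encode_dataset(item)
            body += struct.pack("<HHI", *_ITEM, len(item_bytes)) + item_bytes
        header = struct.pack("<HH2sHI", group, elem, b"SQ", 0, len(body))
        return header + body
    if isinstance(value, bytes):
        raw = value
    else:
        raw = str(value).encode("ascii")
    raw = _pad(raw, vr)
    if vr in _LONG_VRS:
        header = struct.pack("<HH2sHI", group, elem, vr.encode(), 0, len(raw))
    else:
        if len(raw) > 0xFFFF:
            raise DicomError(f"value too long for short VR {vr}")
        header = struct.pack("<HH2sH", group, elem, vr.encode(), len(raw))
    return header + raw


def encode_dataset(ds: Dataset) -> bytes:
    return b"".join(
        _encode_element(tag, vr, value)
        for tag, (vr, value) in sorted(ds.items())
    )


def write_file(path, ds: Dataset, sop_class: str = RTPLAN_SOP_CLASS,
               sop_instance: str = "2.25.0") -> None:
    """Write ``ds`` as a DICOM Part-10 file (explicit VR little endian)."""
    meta: Dataset = {
        (0x0002, 0x0001): ("OB", b"\x00\x01"),
        (0x0002, 0x0002): ("UI", sop_class),
        (0x0002, 0x0003): ("UI", sop_instance),
        (0x0002, 0x0010): ("UI", EXPLICIT_VR_LE),
        (0x0002, 0x0012): ("UI", "2.25.999.1"),
    }
    meta_bytes = encode_dataset(meta)
    group_len = _encode_element((0x0002, 0x0000), "UL", struct.pack("<I", len(meta_bytes)))
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        fh.write(group_len)
        fh.write(meta_bytes)
        fh.write(encode_dataset(ds))


class _Reader:
    def __init__(self, buf: bytes, pos: int = 0):
        self.buf = buf
        self.pos = pos

    def eof(self) -> bool:
        return self.pos >= len(self.buf)

    def _take(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise DicomError("truncated DICOM stream")
        chunk = self.buf[self.pos:self.pos + n]
        self.pos += n
        return chunk

    def read_element(self) -> Tuple[Tag, str, Value]:
        group, elem = struct.unpack("<HH", self._take(4))
        tag = (group, elem)
        if group == 0xFFFE:  # delimitation items carry no VR
            (length,) = struct.unpack("<I", self._take(4))
            return tag, "", self._take(length) if length != 0xFFFFFFFF else b""
        vr = self._take(2).decode("ascii")
        if vr in _LONG_VRS:
            self._take(2)  # reserved
            (length,) = struct.unpack("<I", self._take(4))
        else:
            (length,) = struct.unpack("<H", self._take(2))
        if vr == "SQ":
            return tag, vr, self._read_sequence(length)
        if length == 0xFFFFFFFF:
            raise DicomError("undefined length outside SQ is unsupported")
        raw = self._take(length)
        if vr in _TEXT_VRS:
            return tag, vr, raw.decode("ascii").rstrip("\x00 ").strip()
        return tag, vr, raw

    def _read_sequence(self, length: int) -> List[Dataset]:
        items: List[Dataset] = []
        end = None if length == 0xFFFFFFFF else self.pos + length
        while True:
            if end is not None and self.pos >= end:
                break
            group, elem = struct.unpack("<HH", self._take(4))
            (item_len,) = struct.unpack("<I", self._take(4))
            if (group, elem) == _SEQ_DELIM:
                break
            if (group, elem) != _ITEM:
                raise DicomError("malformed sequence item")
            items.append(self._read_item(item_len))
        return items

    def _read_item(self, length: int) -> Dataset:
        item: Dataset = {}
        end = None if length == 0xFFFFFFFF else self.pos + length
        while True:
            if end is not None:
                if self.pos >= end:
                    break
            elif self.eof():
                raise DicomError("unterminated undefined-length item")
            mark = self.pos
            tag, vr, value = self.read_element()
            if tag == _ITEM_DELIM:
                break
            if tag[0] == 0xFFFE:
                raise DicomError(f"unexpected delimiter at offset {mark}")
            item[tag] = (vr, value)
        return item


def read_file(path) -> Dataset:
    """Read a DICOM Part-10 file written in explicit VR little endian."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomError("not a DICOM Part-10 file (missing DICM magic)")
    reader = _Reader(buf, 132)
    ds: Dataset = {}
    transfer_syntax = EXPLICIT_VR_LE
    while not reader.eof():
        tag, vr, value = reader.read_element()
        if tag == (0x0002, 0x0010):
            transfer_syntax = value  # type: ignore[assignment]
            continue
        if tag[0] == 0x0002:
            continue
        if transfer_syntax != EXPLICIT_VR_LE:
            raise DicomError(f"unsupported transfer syntax {transfer_syntax}")
        ds[tag] = (vr, value)
    return ds


def ds_values(ds: Dataset, tag: Tag) -> List[float]:
    """Parse a (possibly multi-valued) DS/IS element as floats."""
    vr, value = ds[tag]
    return [float(v) for v in str(value).split("\\") if v != ""]
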