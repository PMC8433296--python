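"""Binary container formats and the self-extraction read procedure.

Two fixed-offset record layouts carry everything the pool stores. Integers
are big-endian (network order).

Data record::

    offset 0  FT   1 byte   file type (0 = data)
    offset 1  FID  4 bytes  file identifier
    offset 5  SM   1 byte   storage method (0 = OF, 1 = CPF, 2 = SPF)
    offset 6  DL/TFID 4 bytes  data length (OF/CPF) or tool FID (SPF)
    offset 10 D    variable data bytes
              TD   variable tool bytes (CPF only; otherwise length 0)

Tool record::

    offset 0  FT   1 byte   file type (1 = tool)
    offset 1  FID  4 bytes  file identifier
    offset 5  TD   variable tool bytes

The three storage-method codes describe how a data record self-extracts:
OF (unprocessed) returns D verbatim; CPF (continuously processed) carries
its full decompression tool inline in TD; SPF (separately processed)
references a shared tool record by TFID.

Stored tools are opaque blobs and are never executed. Actual decompression
is dispatched through a :class:`ToolRegistry` of built-in codecs keyed by
tool FID (and, for inline CPF tools, by the blob's SHA-256), which keeps
the round-trip byte-exact without running foreign binaries.
"""

from __future__ import annotations

import hashlib
import lzma
import zlib
from dataclasses import dataclass, field

from .errors import (
    DanglingToolError,
    FieldRangeError,
    FormatError,
    MissingFileError,
    TruncatedRecordError,
    UnknownToolError,
)

FT_DATA = 0
FT_TOOL = 1

SM_OF = 0   # unprocessed file
SM_CPF = 1  # continuously processed file (tool embedded)
SM_SPF = 2  # separately processed file (tool referenced by FID)

DATA_HEADER_BYTES = 10
TOOL_HEADER_BYTES = 5

_U32_MAX = 2 ** 32 - 1


def _check_u32(value: int, name: str) -> None:
    if not (0 <= value <= _U32_MAX):
        raise FieldRangeError(f"{name}={value} outside 4-byte range")


@dataclass(frozen=True)
class DataFileRecord:
    fid: int
    sm: int
    d: bytes = b""
    td: bytes = b""
    tfid: int | None = None

    def __post_init__(self):
        if self.sm not in (SM_OF, SM_CPF, SM_SPF):
            raise FormatError(f"unknown storage method code {self.sm}")
        if self.sm == SM_SPF:
            if self.tfid is None:
                raise FormatError("SPF record needs a tool FID")
            if self.td:
                raise FormatError("SPF record carries no inline tool bytes")
        else:
            if self.tfid is not None:
                raise FormatError("only SPF records reference a tool FID")
        if self.sm == SM_OF and self.td:
            raise FormatError("OF record carries no tool bytes")


@dataclass(frozen=True)
class ToolFileRecord:
    fid: int
    td: bytes


@dataclass
class ContainerSet:
    """The two record arrays the read procedure searches."""

    datafiles: list[DataFileRecord] = field(default_factory=list)
    toolfiles: list[ToolFileRecord] = field(default_factory=list)


def serialize_data_record(record: DataFileRecord) -> bytes:
    _check_u32(record.fid, "FID")
    offset6 = record.tfid if record.sm == SM_SPF else len(record.d)
    _check_u32(offset6, "DL/TFID")
    return (bytes([FT_DATA])
            + record.fid.to_bytes(4, "big")
            + bytes([record.sm])
            + offset6.to_bytes(4, "big")
            + record.d
            + record.td)


def parse_data_record(buf: bytes) -> DataFileRecord:
    if len(buf) < DATA_HEADER_BYTES:
        raise TruncatedRecordError(
            f"data record needs >= {DATA_HEADER_BYTES} bytes, got {len(buf)}")
    if buf[0] != FT_DATA:
        raise FormatError(f"FT byte {buf[0]} is not a data record")
    fid = int.from_bytes(buf[1:5], "big")
    sm = buf[5]
    val = int.from_bytes(buf[6:10], "big")
    body = buf[DATA_HEADER_BYTES:]
    if sm == SM_OF:
        if len(body) != val:
            raise FormatError(
                f"OF record declares DL={val} but carries {len(body)} bytes")
        return DataFileRecord(fid, SM_OF, d=bytes(body))
    if sm == SM_CPF:
        if len(body) < val:
            raise TruncatedRecordError(
                f"CPF record declares DL={val} but carries {len(body)} bytes")
        return DataFileRecord(fid, SM_CPF, d=bytes(body[:val]),
                              td=bytes(body[val:]))
    if sm == SM_SPF:
        return DataFileRecord(fid, SM_SPF, d=bytes(body), tfid=val)
    raise FormatError(f"unknown storage method code {sm}")


def serialize_tool_record(record: ToolFileRecord) -> bytes:
    _check_u32(record.fid, "FID")
    return bytes([FT_TOOL]) + record.fid.to_bytes(4, "big") + record.td


def parse_tool_record(buf: bytes) -> ToolFileRecord:
    if len(buf) < TOOL_HEADER_BYTES:
        raise TruncatedRecordError(
            f"tool record needs >= {TOOL_HEADER_BYTES} bytes, got {len(buf)}")
    if buf[0] != FT_TOOL:
        raise FormatError(f"FT byte {buf[0]} is not a tool record")
    return ToolFileRecord(int.from_bytes(buf[1:5], "big"),
                          bytes(buf[TOOL_HEADER_BYTES:]))


def split_by_file_type(records: list[bytes]) -> ContainerSet:
    """Sort raw records into datafiles/toolfiles arrays by their FT byte."""
    out = ContainerSet()
    for i, raw in enumerate(records):
        try:
            if not raw:
                raise TruncatedRecordError("empty record")
            if raw[0] == FT_DATA:
                out.datafiles.append(parse_data_record(raw))
            elif raw[0] == FT_TOOL:
                out.toolfiles.append(parse_tool_record(raw))
            else:
                raise FormatError(f"unknown FT byte {raw[0]}")
        except FormatError as exc:
            raise FormatError(f"record {i}: {exc}") from exc
    return out


# --- tool registry ------------------------------------------------------

_BUILTIN_CODECS = {
    "deflate": (zlib.compress, zlib.decompress),
    "lzma": (lzma.compress, lzma.decompress),
}


class ToolRegistry:
    """Dispatch table from stored tools to runnable (de)compressors.

    A tool is registered under its FID together with the registry codec
    name that stands in for it; when the opaque blob is supplied, its
    SHA-256 is indexed as well so an inline CPF tool can be recognised by
    content alone.
    """

    def __init__(self):
        self._by_fid: dict[int, str] = {}
        self._by_sha: dict[str, str] = {}

    def register(self, fid: int, codec_name: str,
                 blob: bytes | None = None) -> None:
        if codec_name not in _BUILTIN_CODECS:
            raise UnknownToolError(
                f"no built-in codec named {codec_name!r}; "
                f"available: {sorted(_BUILTIN_CODECS)}")
        self._by_fid[fid] = codec_name
        if blob is not None:
            self._by_sha[hashlib.sha256(blob).hexdigest()] = codec_name

    def register_sha(self, sha_hex: str, codec_name: str) -> None:
        if codec_name not in _BUILTIN_CODECS:
            raise UnknownToolError(f"no built-in codec named {codec_name!r}")
        self._by_sha[sha_hex] = codec_name

    def codec_names(self) -> dict[int, str]:
        return dict(self._by_fid)

    def sha_names(self) -> dict[str, str]:
        return dict(self._by_sha)

    def _name_for_fid(self, fid: int) -> str:
        try:
            return self._by_fid[fid]
        except KeyError:
            raise UnknownToolError(
                f"tool FID {fid} has no registered codec") from None

    def compress(self, fid: int, data: bytes) -> bytes:
        return _BUILTIN_CODECS[self._name_for_fid(fid)][0](data)

    def decompress(self, fid: int, data: bytes) -> bytes:
        return _BUILTIN_CODECS[self._name_for_fid(fid)][1](data)

    def decompress_with_blob(self, blob: bytes, data: bytes) -> bytes:
        sha = hashlib.sha256(blob).hexdigest()
        name = self._by_sha.get(sha)
        if name is None:
            raise UnknownToolError(
                "inline tool blob matches no registered codec")
        return _BUILTIN_CODECS[name][1](data)


def read_file(fid: int, cset: ContainerSet,
              tool_registry: ToolRegistry) -> bytes:
    """Self-extraction read: locate *fid* and restore its original bytes.

    OF records return D verbatim. CPF records decompress D with the codec
    recognised from the inline tool blob TD. SPF records resolve TFID in
    the toolfiles array and decompress with that tool's registered codec.
    """
    record = next((r for r in cset.datafiles if r.fid == fid), None)
    if record is None:
        raise MissingFileError(f"no data file with FID {fid}")
    if record.sm == SM_OF:
        return record.d
    if record.sm == SM_CPF:
        return tool_registry.decompress_with_blob(record.td, record.d)
    # SPF: traverse the tool files array to find TD
    tool = next((t for t in cset.toolfiles if t.fid == record.tfid), None)
    if tool is None:
        raise DanglingToolError(
            f"data file {fid} references tool FID {record.tfid}, "
            "which is absent from the tool files array")
    try:
        return tool_registry.decompress(tool.fid, record.d)
    except UnknownToolError:
        return tool_registry.decompress_with_blob(tool.td, record.d)
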