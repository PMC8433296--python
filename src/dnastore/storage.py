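"""Write-path planners for the three self-containment strategies.

Each data file is compressed with its assigned tool, packed into a binary
container record, transcoded to nucleotides, and segmented into primer-
flanked fragments. The three methods differ in where the tool lives:

1-1CS (one-to-one continuous storage)
    The full tool blob is embedded in every client file's container (CPF
    records). k files sharing one tool store k tool copies, but a single
    amplification recovers everything.

M-1CI (many-to-one chain indexing)
    Files become SPF records that reference the tool by FID; the tool is
    stored once under its own primer pair, and each file's encoded stream
    ends with a 2*L_p-nt pointer — the literal tool primer sequences — so
    a first sequencing round yields the address of the second.

1-MCI (one-to-many chain indexing)
    Files are SPF records as in M-1CI, but the tool's fragments carry the
    universal forward primer at the head and the reverse primers of all n
    client files at the tail. Selecting with a file's primers plus the
    universal primer amplifies both classes at once, so one sequencing
    round suffices. n is bounded by 0 < n < floor(L_s / L_p).

All write paths return the pool together with a manifest — the index a
hybrid DNA/conventional system keeps on traditional media: per-stream
address widths, true nt lengths, pointer sizes and tool sharing counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .codec import get_codec
from .containers import (
    DataFileRecord,
    SM_CPF,
    SM_OF,
    SM_SPF,
    ToolFileRecord,
    ToolRegistry,
    serialize_data_record,
    serialize_tool_record,
)
from .errors import SharingLimitError
from .fragments import (
    DATA_FLAG,
    ROLE_DATA,
    ROLE_MCI_TOOL,
    TOOL_FLAG,
    layout_for,
    segment,
)
from .pool import Pool
from .primers import PrimerPair

METHOD_1_1CS = "1-1CS"
METHOD_M_1CI = "M-1CI"
METHOD_1_MCI = "1-MCI"
METHODS = (METHOD_1_1CS, METHOD_M_1CI, METHOD_1_MCI)


@dataclass(frozen=True)
class StoredFile:
    """An input data file bound for the pool."""

    fid: int
    name: str
    data: bytes
    tool_fid: int | None = None  # None -> stored unprocessed (OF)


@dataclass(frozen=True)
class ToolBlob:
    """An opaque tool program blob plus the registry codec standing in
    for it."""

    fid: int
    name: str
    blob: bytes
    codec: str = "deflate"


@dataclass
class StorePlan:
    """Primer assignment binding files and tools for one method."""

    method: str
    file_primers: dict[int, PrimerPair]
    tool_primers: dict[int, PrimerPair] = field(default_factory=dict)
    universal: PrimerPair | None = None
    shared_counts: dict[int, int] = field(default_factory=dict)


@dataclass
class StreamInfo:
    """Per-stream index metadata kept on the traditional-storage side."""

    l_addr: int
    nt_length: int       # true stream length before final-fragment padding
    n_fragments: int
    pointer_nt: int = 0  # 2*L_p when a tool-primer pointer is appended
    n_shared: int = 1
    clients: tuple[int, ...] = ()


@dataclass
class PoolManifest:
    method: str
    L_s: int
    L_p: int
    rs_len: int
    codec: str
    files: dict[int, StreamInfo] = field(default_factory=dict)
    tools: dict[int, StreamInfo] = field(default_factory=dict)
    file_tool: dict[int, int | None] = field(default_factory=dict)


@dataclass
class StoreResult:
    pool: Pool
    manifest: PoolManifest
    fasta_records: list[tuple[str, str]] = field(default_factory=list)


@dataclass(frozen=True)
class StorageConfig:
    L_s: int = 220
    L_p: int = 20
    rs_len: int = 0
    codec_name: str = "rot"


def check_sharing_limit(n: int, L_s: int, L_p: int) -> bool:
    """True iff 0 < n < floor(L_s / L_p)."""
    if L_s <= 0 or L_p <= 0:
        raise ValueError("L_s and L_p must be positive")
    return 0 < n < math.floor(L_s / L_p)


def shared_counts(files: list[StoredFile]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for f in files:
        if f.tool_fid is not None:
            counts[f.tool_fid] = counts.get(f.tool_fid, 0) + 1
    return counts


def required_pairs(method: str, n_files: int, n_tools: int) -> int:
    """Primer pairs a plan needs: files, plus per-tool pairs (M-1CI) or
    one universal pair (1-MCI)."""
    if method == METHOD_1_1CS:
        return n_files
    if method == METHOD_M_1CI:
        return n_files + n_tools
    if method == METHOD_1_MCI:
        return n_files + 1
    raise ValueError(f"unknown storage method {method!r}")


def build_plan(method: str, files: list[StoredFile], tools: list[ToolBlob],
               pairs: list[PrimerPair]) -> StorePlan:
    """Assign primer pairs injectively: files first (ascending FID), then
    tools (M-1CI) or the universal pair (1-MCI)."""
    counts = shared_counts(files)
    used_tools = sorted(counts)
    need = required_pairs(method, len(files),
                          len(used_tools) if method == METHOD_M_1CI else
                          len(tools))
    if len(pairs) < need:
        raise ValueError(f"plan needs {need} primer pairs, got {len(pairs)}")
    ordered = sorted(files, key=lambda f: f.fid)
    file_primers = {f.fid: pairs[i] for i, f in enumerate(ordered)}
    tool_primers: dict[int, PrimerPair] = {}
    universal = None
    cursor = len(ordered)
    if method == METHOD_M_1CI:
        for tfid in used_tools:
            tool_primers[tfid] = pairs[cursor]
            cursor += 1
    elif method == METHOD_1_MCI:
        universal = pairs[cursor].as_universal()
    return StorePlan(method, file_primers, tool_primers, universal, counts)


def _tool_map(tools: list[ToolBlob]) -> dict[int, ToolBlob]:
    out = {}
    for t in tools:
        if t.fid in out:
            raise ValueError(f"duplicate tool FID {t.fid}")
        out[t.fid] = t
    return out


def _emit(result: StoreResult, seq: str, layout, head: str,
          tails: list[str], c_flag: str, label: str) -> StreamInfo:
    frags = segment(seq, layout, head, tails, c_flag)
    cls = "data" if c_flag == DATA_FLAG else "tool"
    for frag in frags:
        result.pool.add(frag.to_seq())
        result.fasta_records.append(
            (f"{label}|{cls}|{frag.address}", frag.to_seq()))
    return StreamInfo(layout.L_addr, len(seq), len(frags))


def _data_record(f: StoredFile, method: str,
                 registry: ToolRegistry) -> DataFileRecord:
    if f.tool_fid is None:
        return DataFileRecord(f.fid, SM_OF, d=f.data)
    compressed = registry.compress(f.tool_fid, f.data)
    if method == METHOD_1_1CS:
        return DataFileRecord(f.fid, SM_CPF, d=compressed)  # TD added later
    return DataFileRecord(f.fid, SM_SPF, d=compressed, tfid=f.tool_fid)


def store_1_1cs(files: list[StoredFile], tools: list[ToolBlob],
                plan: StorePlan, config: StorageConfig,
                registry: ToolRegistry) -> StoreResult:
    """Continuous storage: every tool-using file embeds its full tool."""
    codec = get_codec(config.codec_name)
    tool_map = _tool_map(tools)
    result = StoreResult(Pool(), PoolManifest(
        METHOD_1_1CS, config.L_s, config.L_p, config.rs_len,
        config.codec_name))
    for f in sorted(files, key=lambda x: x.fid):
        record = _data_record(f, METHOD_1_1CS, registry)
        if f.tool_fid is not None:
            record = replace(record, td=tool_map[f.tool_fid].blob)
        seq = codec.encode(serialize_data_record(record))
        layout = layout_for(len(seq), config.L_s, config.L_p, ROLE_DATA,
                            rs_len=config.rs_len)
        pair = plan.file_primers[f.fid]
        result.manifest.files[f.fid] = _emit(
            result, seq, layout, pair.forward.sequence,
            [pair.reverse.sequence], DATA_FLAG, f"fid{f.fid}")
        result.manifest.file_tool[f.fid] = f.tool_fid
    return result


def store_m_1ci(files: list[StoredFile], tools: list[ToolBlob],
                plan: StorePlan, config: StorageConfig,
                registry: ToolRegistry) -> StoreResult:
    """Separate storage with a tool-primer pointer at each file's end."""
    codec = get_codec(config.codec_name)
    tool_map = _tool_map(tools)
    result = StoreResult(Pool(), PoolManifest(
        METHOD_M_1CI, config.L_s, config.L_p, config.rs_len,
        config.codec_name))
    counts = shared_counts(files)
    for f in sorted(files, key=lambda x: x.fid):
        record = _data_record(f, METHOD_M_1CI, registry)
        seq = codec.encode(serialize_data_record(record))
        pointer_nt = 0
        if f.tool_fid is not None:
            tp = plan.tool_primers[f.tool_fid]
            seq += tp.forward.sequence + tp.reverse.sequence
            pointer_nt = 2 * config.L_p
        layout = layout_for(len(seq), config.L_s, config.L_p, ROLE_DATA,
                            rs_len=config.rs_len)
        pair = plan.file_primers[f.fid]
        info = _emit(result, seq, layout, pair.forward.sequence,
                     [pair.reverse.sequence], DATA_FLAG, f"fid{f.fid}")
        info.pointer_nt = pointer_nt
        result.manifest.files[f.fid] = info
        result.manifest.file_tool[f.fid] = f.tool_fid
    for tfid in sorted(counts):
        tool = tool_map[tfid]
        seq = codec.encode(serialize_tool_record(
            ToolFileRecord(tool.fid, tool.blob)))
        layout = layout_for(len(seq), config.L_s, config.L_p, ROLE_DATA,
                            rs_len=config.rs_len)
        tp = plan.tool_primers[tfid]
        info = _emit(result, seq, layout, tp.forward.sequence,
                     [tp.reverse.sequence], TOOL_FLAG, f"tool{tfid}")
        info.clients = tuple(sorted(
            f.fid for f in files if f.tool_fid == tfid))
        result.manifest.tools[tfid] = info
    return result


def store_1_mci(files: list[StoredFile], tools: list[ToolBlob],
                plan: StorePlan, config: StorageConfig,
                registry: ToolRegistry) -> StoreResult:
    """Separate storage with reverse pointers: each tool fragment carries
    the universal forward primer and all client reverse primers."""
    codec = get_codec(config.codec_name)
    tool_map = _tool_map(tools)
    result = StoreResult(Pool(), PoolManifest(
        METHOD_1_MCI, config.L_s, config.L_p, config.rs_len,
        config.codec_name))
    counts = shared_counts(files)
    for tfid, n in counts.items():
        if not check_sharing_limit(n, config.L_s, config.L_p):
            raise SharingLimitError(
                f"tool {tfid} is shared by n={n} files, violating "
                f"0 < n < {math.floor(config.L_s / config.L_p)}")
    for f in sorted(files, key=lambda x: x.fid):
        record = _data_record(f, METHOD_1_MCI, registry)
        seq = codec.encode(serialize_data_record(record))
        layout = layout_for(len(seq), config.L_s, config.L_p, ROLE_DATA,
                            rs_len=config.rs_len)
        pair = plan.file_primers[f.fid]
        result.manifest.files[f.fid] = _emit(
            result, seq, layout, pair.forward.sequence,
            [pair.reverse.sequence], DATA_FLAG, f"fid{f.fid}")
        result.manifest.file_tool[f.fid] = f.tool_fid
    for tfid in sorted(counts):
        tool = tool_map[tfid]
        clients = tuple(sorted(
            f.fid for f in files if f.tool_fid == tfid))
        seq = codec.encode(serialize_tool_record(
            ToolFileRecord(tool.fid, tool.blob)))
        layout = layout_for(len(seq), config.L_s, config.L_p,
                            ROLE_MCI_TOOL, n_shared=len(clients),
                            rs_len=config.rs_len)
        tails = [plan.file_primers[c].reverse.sequence for c in clients]
        info = _emit(result, seq, layout,
                     plan.universal.forward.sequence, tails, TOOL_FLAG,
                     f"tool{tfid}")
        info.n_shared = len(clients)
        info.clients = clients
        result.manifest.tools[tfid] = info
    return result


_STORE_FUNCS = {
    METHOD_1_1CS: store_1_1cs,
    METHOD_M_1CI: store_m_1ci,
    METHOD_1_MCI: store_1_mci,
}


def store(method: str, files: list[StoredFile], tools: list[ToolBlob],
          plan: StorePlan, config: StorageConfig,
          registry: ToolRegistry) -> StoreResult:
    try:
        func = _STORE_FUNCS[method]
    except KeyError:
        raise ValueError(f"unknown storage method {method!r}") from None
    if plan.method != method:
        raise ValueError(
            f"plan was built for {plan.method!r}, not {method!r}")
    return func(files, tools, plan, config, registry)


def pool_payload_bits(result: StoreResult, plan: StorePlan) -> int:
    """Binary payload actually stored, counted back out of the pool.

    Every stream is re-selected by its primers, reassembled and decoded;
    container bytes count 8 bits each. The M-1CI tool-primer pointer is
    raw nucleotide sequence rather than coded payload; it is counted one
    unit per nt, matching the convention of the closed-form size models.
    """
    from .fragments import Fragment, FragmentLayout
    from .pool import pcr_select

    manifest = result.manifest
    codec = get_codec(manifest.codec)
    total = 0

    def _stream_seq(head: str, rev: str, layout, nt_length: int,
                    want_tool: bool) -> str:
        from .fragments import assemble
        sub = pcr_select(result.pool, head, rev)
        frags = [Fragment.parse(r, layout) for r in sub
                 if r.startswith(head)]
        data_seq, tool_seq = assemble(
            frags,
            data_nt=None if want_tool else nt_length,
            tool_nt=nt_length if want_tool else None)
        return tool_seq if want_tool else data_seq

    for fid, info in manifest.files.items():
        pair = plan.file_primers[fid]
        layout = FragmentLayout(manifest.L_s, manifest.L_p, info.l_addr,
                                manifest.rs_len, ROLE_DATA)
        seq = _stream_seq(pair.forward.sequence, pair.reverse.sequence,
                          layout, info.nt_length, want_tool=False)
        container_nt = info.nt_length - info.pointer_nt
        total += 8 * len(codec.decode(seq[:container_nt])) + info.pointer_nt
    for tfid, info in manifest.tools.items():
        if manifest.method == METHOD_M_1CI:
            tp = plan.tool_primers[tfid]
            head, rev = tp.forward.sequence, tp.reverse.sequence
            layout = FragmentLayout(manifest.L_s, manifest.L_p,
                                    info.l_addr, manifest.rs_len, ROLE_DATA)
        else:
            head = plan.universal.forward.sequence
            rev = plan.file_primers[info.clients[0]].reverse.sequence
            layout = FragmentLayout(manifest.L_s, manifest.L_p,
                                    info.l_addr, manifest.rs_len,
                                    ROLE_MCI_TOOL, info.n_shared)
        seq = _stream_seq(head, rev, layout, info.nt_length, want_tool=True)
        total += 8 * len(codec.decode(seq))
    return total
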