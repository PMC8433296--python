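"""Seeded synthetic corpora and the end-to-end pipeline runner.

The generator emulates a realistic mixed archive: a handful of data files
of differing sizes and redundancy levels, plus two opaque tool blobs whose
sizes match common compressor executables (a 7z-like program of 194 KB
and a zip-like one of 87 KB). Tool blobs are seeded random bytes; actual
(de)compression is performed by the registry codecs standing in for them
(deflate and LZMA from the runtime).

Redundancy is the knob that controls compressibility: a file with
redundancy r is built from 32-byte blocks where each block is, with
probability r, re-drawn from a small per-file dictionary and otherwise
fresh random bytes. r = 0 yields incompressible uniform noise (measured
r_c ~ 1); r = 0.9 compresses to well under a third of its size.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .containers import ToolRegistry
from .errors import DNAStoreError
from .models import storage_density
from .pool import retrieve
from .primers import PrimerConstraints, generate_primer_library
from .storage import (
    StorageConfig,
    StoredFile,
    StorePlan,
    ToolBlob,
    build_plan,
    pool_payload_bits,
    required_pairs,
    shared_counts,
    store,
)

_BLOCK = 32
_DICT_BLOCKS = 8

TOOL_FID_BASE = 101


@dataclass(frozen=True)
class FileSpec:
    name: str
    size_bytes: int
    redundancy: float = 0.0
    tool: str | None = None  # tool name, or None for unprocessed storage

    def __post_init__(self):
        if self.size_bytes <= 0:
            raise ValueError("size_bytes must be positive")
        if not 0.0 <= self.redundancy <= 1.0:
            raise ValueError("redundancy must lie in [0, 1]")


@dataclass(frozen=True)
class ToolSpec:
    name: str
    size_bytes: int
    codec: str = "deflate"

    def __post_init__(self):
        if self.size_bytes <= 0:
            raise ValueError("size_bytes must be positive")


@dataclass(frozen=True)
class CorpusSpec:
    files: tuple[FileSpec, ...]
    tools: tuple[ToolSpec, ...]
    seed: int = 0


@dataclass
class Corpus:
    files: list[StoredFile]
    tools: list[ToolBlob]
    registry: ToolRegistry
    names: dict[str, int] = field(default_factory=dict)

    def original_bits(self) -> int:
        return 8 * sum(len(f.data) for f in self.files)


def _file_bytes(rng: random.Random, size: int, redundancy: float) -> bytes:
    dictionary = [rng.randbytes(_BLOCK) for _ in range(_DICT_BLOCKS)]
    out = bytearray()
    while len(out) < size:
        if rng.random() < redundancy:
            out += rng.choice(dictionary)
        else:
            out += rng.randbytes(_BLOCK)
    return bytes(out[:size])


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Deterministically materialise a corpus from its spec."""
    master = random.Random(spec.seed)
    registry = ToolRegistry()
    tools: list[ToolBlob] = []
    tool_fids: dict[str, int] = {}
    for i, ts in enumerate(spec.tools):
        rng = random.Random(master.randrange(2 ** 31))
        fid = TOOL_FID_BASE + i
        blob = rng.randbytes(ts.size_bytes)
        tools.append(ToolBlob(fid, ts.name, blob, ts.codec))
        tool_fids[ts.name] = fid
        registry.register(fid, ts.codec, blob)
    files: list[StoredFile] = []
    names: dict[str, int] = {}
    for i, fs in enumerate(spec.files):
        rng = random.Random(master.randrange(2 ** 31))
        fid = i + 1
        if fs.tool is not None and fs.tool not in tool_fids:
            raise ValueError(f"file {fs.name!r} references unknown tool "
                             f"{fs.tool!r}")
        files.append(StoredFile(
            fid, fs.name, _file_bytes(rng, fs.size_bytes, fs.redundancy),
            tool_fids[fs.tool] if fs.tool is not None else None))
        names[fs.name] = fid
    names.update(tool_fids)
    return Corpus(files, tools, registry, names)


def default_corpus_spec(seed: int = 0) -> CorpusSpec:
    """The reference test corpus: five mixed files, two shared tools.

    The tool blobs are 194 KB (7z-like, shared by two files) and 87 KB
    (zip-like, shared by three), so the one-to-many tool fragments carry
    n = 2 and n = 3 client primers respectively. File sizes span 16-64 KB
    with redundancy from 0.9 (highly compressible bitmap-like content)
    down to 0 (incompressible noise).
    """
    return CorpusSpec(
        files=(
            FileSpec("cat.bmp", 64 * 1024, 0.90, "sevenz-like"),
            FileSpec("jane.txt", 48 * 1024, 0.80, "sevenz-like"),
            FileSpec("monalisa.bmp", 40 * 1024, 0.60, "zip-like"),
            FileSpec("leo.jpg", 24 * 1024, 0.20, "zip-like"),
            FileSpec("mix.bin", 16 * 1024, 0.00, "zip-like"),
        ),
        tools=(
            ToolSpec("sevenz-like", 194 * 1024, "lzma"),
            ToolSpec("zip-like", 87 * 1024, "deflate"),
        ),
        seed=seed,
    )


def small_corpus_spec(seed: int = 0, n_files: int = 3,
                      n_tools: int = 1) -> CorpusSpec:
    """A miniature randomized corpus for property tests: files of a few
    hundred bytes, tool blobs under 200 bytes."""
    rng = random.Random(seed)
    tools = tuple(
        ToolSpec(f"tool{i}", rng.randint(40, 180),
                 rng.choice(["deflate", "lzma"]))
        for i in range(n_tools))
    files = tuple(
        FileSpec(f"file{i}", rng.randint(60, 400),
                 round(rng.random(), 3),
                 rng.choice([t.name for t in tools] + [None]))
        for i in range(n_files))
    return CorpusSpec(files=files, tools=tools, seed=rng.randrange(2 ** 31))


def plan_for(corpus: Corpus, method: str, config: StorageConfig,
             seed: int = 0,
             constraints: PrimerConstraints | None = None) -> StorePlan:
    """Design a primer library sized for *corpus* and bind it to a plan."""
    n_pairs = required_pairs(method, len(corpus.files), len(corpus.tools))
    pairs = generate_primer_library(n_pairs, L_p=config.L_p,
                                    constraints=constraints, seed=seed)
    return build_plan(method, corpus.files, corpus.tools, pairs)


def run_end_to_end(spec: CorpusSpec, method: str,
                   config: StorageConfig | None = None,
                   seed: int = 0) -> dict:
    """Store a corpus, retrieve every file, verify byte identity, and
    report sizes, densities and sequencing-round counts.

    Raises :class:`DNAStoreError` with a diff summary if any retrieval is
    not byte-identical to the original.
    """
    config = config or StorageConfig()
    corpus = generate_corpus(spec)
    plan = plan_for(corpus, method, config, seed=seed)
    result = store(method, corpus.files, corpus.tools, plan, config,
                   corpus.registry)
    report: dict = {
        "method": method,
        "seed": seed,
        "n_files": len(corpus.files),
        "n_tools": len(corpus.tools),
        "shared_counts": {str(k): v for k, v in
                          shared_counts(corpus.files).items()},
        "pool_fragments": len(result.pool),
        "pool_bases": result.pool.total_bases,
        "files": {},
    }
    for f in corpus.files:
        out = retrieve(result.pool, f.fid, result.manifest, plan,
                       corpus.registry, seed=seed)
        if out.data != f.data:
            first = next((i for i, (x, y) in
                          enumerate(zip(out.data, f.data)) if x != y),
                         min(len(out.data), len(f.data)))
            raise DNAStoreError(
                f"retrieval mismatch for {f.name} (FID {f.fid}): "
                f"lengths {len(out.data)} vs {len(f.data)}, first "
                f"difference at byte {first}")
        report["files"][f.name] = {
            "fid": f.fid,
            "bytes": len(f.data),
            "tool_fid": f.tool_fid,
            "sequencing_rounds": out.sequencing_rounds,
            "fragments_sequenced": out.fragments_sequenced,
            "verified": True,
        }
    payload_bits = pool_payload_bits(result, plan)
    original_bits = corpus.original_bits()
    report["payload_bits"] = payload_bits
    report["original_bits"] = original_bits
    report["density_bits_per_base"] = storage_density(
        original_bits, result.pool.total_bases)
    return report
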