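"""In-silico oligo pool: PCR-style selection, sequencing, random access.

The pool is an unordered multiset of fragment sequences — deliberately
nothing else. Retrieval may only use sequence content (primer sites, the
direction/class markers, addresses) plus the side-channel index a hybrid
storage system keeps on conventional media (the manifest: layouts, true
stream lengths, primer assignments). Insertion order and any FASTA record
ids are never consulted.

PCR selection is modelled as exact substring co-occurrence of the forward
and reverse sites; one *sequencing round* reads out every fragment of an
amplified sub-pool once, in seeded-random order. Amplification bias, copy
numbers, strand chemistry and read errors are out of scope — the model
covers the digital part of a storage system that assumes amplification
and sequencing succeed.

Round contract per storage method (tool-using files):

* one-to-one continuous (1-1CS): the tool travels inside the file's own
  container, one selection + one round suffice -> 1 round;
* many-to-one chain indexing (M-1CI): round 1 recovers the file and the
  tool-primer pointer appended to it, round 2 recovers the tool -> 2;
* one-to-many chain indexing (1-MCI): file primers plus the universal
  tool primer amplify both classes at once; the class flag separates
  them -> 1 round.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

from .codec import get_codec
from .containers import (
    ContainerSet,
    SM_SPF,
    ToolRegistry,
    parse_data_record,
    parse_tool_record,
    read_file,
)
from .errors import DanglingToolError, MissingFileError
from .fragments import (
    Fragment,
    FragmentLayout,
    ROLE_DATA,
    ROLE_MCI_TOOL,
    assemble,
)


class Pool:
    """Unordered multiset of fragment sequences."""

    __slots__ = ("_fragments",)

    def __init__(self, fragments: Iterable[str] = ()):
        self._fragments = list(fragments)

    def __len__(self) -> int:
        return len(self._fragments)

    def __iter__(self) -> Iterator[str]:
        return iter(self._fragments)

    def add(self, fragment: str) -> None:
        self._fragments.append(fragment)

    def extend(self, fragments: Iterable[str]) -> None:
        self._fragments.extend(fragments)

    def counts(self) -> Counter:
        return Counter(self._fragments)

    @property
    def total_bases(self) -> int:
        return sum(len(f) for f in self._fragments)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pool):
            return NotImplemented
        return self.counts() == other.counts()


@dataclass(frozen=True)
class RetrievalResult:
    data: bytes
    sequencing_rounds: int
    fragments_sequenced: int


def pcr_select(pool: Pool, forward_site: str, reverse_site: str) -> Pool:
    """Sub-pool of fragments carrying both sites as exact substrings."""
    if not forward_site or not reverse_site:
        raise ValueError("selection sites must be non-empty")
    return Pool(f for f in pool
                if forward_site in f and reverse_site in f)


def sequence(pool: Pool, seed: int = 0) -> list[str]:
    """One sequencing pass: every fragment once, seeded-random order."""
    reads = list(pool)
    random.Random(seed).shuffle(reads)
    return reads


def _parse_stream(reads: list[str], head: str,
                  layout: FragmentLayout) -> list[Fragment]:
    """Keep the reads belonging to the stream amplified from *head*."""
    return [Fragment.parse(r, layout) for r in reads if r.startswith(head)]


def retrieve(pool: Pool, fid: int, manifest, plan,
             registry: ToolRegistry, seed: int = 0) -> RetrievalResult:
    """Random-access read of one stored file, counting sequencing rounds.

    *manifest* is the pool's side index (method, layouts, stream lengths)
    and *plan* the primer assignment, both produced by the matching
    ``store_*`` call. Returns the byte-exact original file.
    """
    info = manifest.files.get(fid)
    if info is None:
        raise MissingFileError(f"FID {fid} is not stored in this pool")
    pair = plan.file_primers[fid]
    fwd, rev = pair.forward.sequence, pair.reverse.sequence
    codec = get_codec(manifest.codec)
    data_layout = FragmentLayout(manifest.L_s, manifest.L_p, info.l_addr,
                                 manifest.rs_len, ROLE_DATA)
    rounds = 0
    reads_total = 0

    if manifest.method == "1-MCI":
        uni = plan.universal.forward.sequence
        sub = Pool(f for f in pool
                   if rev in f and (fwd in f or uni in f))
        reads = sequence(sub, seed)
        rounds, reads_total = 1, len(reads)
        data_seq, _ = assemble(_parse_stream(reads, fwd, data_layout),
                               data_nt=info.nt_length)
        record = parse_data_record(codec.decode(data_seq))
        cset = ContainerSet([record], [])
        if record.sm == SM_SPF:
            tinfo = manifest.tools.get(record.tfid)
            if tinfo is None:
                raise DanglingToolError(
                    f"tool FID {record.tfid} missing from manifest")
            tool_layout = FragmentLayout(
                manifest.L_s, manifest.L_p, tinfo.l_addr, manifest.rs_len,
                ROLE_MCI_TOOL, tinfo.n_shared)
            _, tool_seq = assemble(_parse_stream(reads, uni, tool_layout),
                                   tool_nt=tinfo.nt_length)
            cset.toolfiles.append(parse_tool_record(codec.decode(tool_seq)))
        return RetrievalResult(read_file(fid, cset, registry),
                               rounds, reads_total)

    # 1-1CS and M-1CI: round 1 amplifies the file's own fragments
    reads = sequence(pcr_select(pool, fwd, rev), seed)
    rounds, reads_total = 1, len(reads)
    data_seq, _ = assemble(_parse_stream(reads, fwd, data_layout),
                           data_nt=info.nt_length)

    if manifest.method == "M-1CI" and info.pointer_nt:
        pointer = data_seq[-info.pointer_nt:]
        record = parse_data_record(codec.decode(data_seq[:-info.pointer_nt]))
        cset = ContainerSet([record], [])
        if record.sm == SM_SPF:
            tinfo = manifest.tools.get(record.tfid)
            if tinfo is None:
                raise DanglingToolError(
                    f"tool FID {record.tfid} missing from manifest")
            tool_fwd = pointer[:manifest.L_p]
            tool_rev = pointer[manifest.L_p:]
            tool_reads = sequence(pcr_select(pool, tool_fwd, tool_rev),
                                  seed + 1)
            rounds += 1
            reads_total += len(tool_reads)
            tool_layout = FragmentLayout(
                manifest.L_s, manifest.L_p, tinfo.l_addr, manifest.rs_len,
                ROLE_DATA)
            _, tool_seq = assemble(
                _parse_stream(tool_reads, tool_fwd, tool_layout),
                tool_nt=tinfo.nt_length)
            cset.toolfiles.append(parse_tool_record(codec.decode(tool_seq)))
        return RetrievalResult(read_file(fid, cset, registry),
                               rounds, reads_total)

    record = parse_data_record(codec.decode(data_seq))
    cset = ContainerSet([record], [])
    return RetrievalResult(read_file(fid, cset, registry),
                           rounds, reads_total)
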